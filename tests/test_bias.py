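"""Egger regression and Begg rank-correlation tests, funnel coordinates."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from snpmeta import (
    EffectEstimate, SimulationConfig, begg_test, egger_test, fixed_effect_pool,
    funnel_data, effects_from_table, simulate_study_set,
)


def eff(log_or, se):
    return EffectEstimate.from_log_or_se(log_or, se)


def egger_oracle(log_ors, ses):
    """Independent normal-equations solve of the Egger regression."""
    y = np.asarray(log_ors) / np.asarray(ses)
    x = 1.0 / np.asarray(ses)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    t = beta[0] / math.sqrt(cov[0, 0])
    return beta[0], beta[1], float(2 * stats.t.sf(abs(t), len(y) - 2))


class TestEgger:
    def test_three_study_set_matches_normal_equations(self):
        log_ors, ses = [0.1, 0.2, 0.3], [0.1, 0.2, 0.3]
        res = egger_test([eff(l, s) for l, s in zip(log_ors, ses)])
        b0, b1, p = egger_oracle(log_ors, ses)
        assert res.statistic == pytest.approx(b0, abs=1e-10)
        assert res.detail["slope"] == pytest.approx(b1, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_random_sets_match_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 7))
        log_ors = rng.normal(0.2, 0.4, k)
        ses = rng.uniform(0.05, 0.5, k)
        res = egger_test([eff(l, s) for l, s in zip(log_ors, ses)])
        b0, _, p = egger_oracle(log_ors, ses)
        assert res.statistic == pytest.approx(b0, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_shared_log_or_gives_zero_intercept(self):
        res = egger_test([eff(0.25, s) for s in (0.1, 0.2, 0.4, 0.8)])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.detail["slope"] == pytest.approx(0.25, abs=1e-10)
        assert res.p == 1.0

    def test_too_few_studies(self):
        with pytest.raises(ValueError, match="insufficient"):
            egger_test([eff(0.1, 0.1), eff(0.2, 0.2)])

    def test_identical_precisions_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            egger_test([eff(0.1, 0.2), eff(0.2, 0.2), eff(0.3, 0.2)])

    def test_affine_invariance_of_intercept(self):
        rng = np.random.default_rng(5)
        log_ors = rng.normal(0.1, 0.3, 5)
        ses = rng.uniform(0.05, 0.5, 5)
        base = egger_test([eff(l, s) for l, s in zip(log_ors, ses)])
        c = 3.7
        scaled = egger_test([eff(c * l, c * s) for l, s in zip(log_ors, ses)])
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)


class TestBegg:
    def test_two_studies_never_significant(self):
        res = begg_test([eff(0.1, 0.1), eff(0.5, 0.3)])
        assert abs(res.statistic) in (0.0, 1.0)
        assert res.p >= 0.05

    def test_identical_log_ors_complete_ties(self):
        res = begg_test([eff(0.2, s) for s in (0.1, 0.2, 0.3, 0.4)])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_tau_matches_scipy_kendall(self, fixture_effects):
        res = begg_test(fixture_effects, continuity=False)
        fe = fixed_effect_pool(fixture_effects)
        y = np.array([e.log_or for e in fixture_effects])
        v = np.array([e.se_log_or for e in fixture_effects]) ** 2
        t_star = (y - fe.log_or) / np.sqrt(v - fe.se**2)
        ref = stats.kendalltau(t_star, v, method="asymptotic")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_pair_counts_exhaustive(self, fixture_effects):
        res = begg_test(fixture_effects)
        # independent O(k^2) concordant/discordant enumeration on ranks
        fe = fixed_effect_pool(fixture_effects)
        y = np.array([e.log_or for e in fixture_effects])
        v = np.array([e.se_log_or for e in fixture_effects]) ** 2
        t_star = (y - fe.log_or) / np.sqrt(v - fe.se**2)
        pairs = list(itertools.combinations(range(len(y)), 2))
        c = sum((t_star[j] - t_star[i]) * (v[j] - v[i]) > 0 for i, j in pairs)
        d = sum((t_star[j] - t_star[i]) * (v[j] - v[i]) < 0 for i, j in pairs)
        assert (res.detail["concordant"], res.detail["discordant"]) == (c, d)

    def test_monotone_variance_transform_invariance(self, fixture_effects):
        # the rank-correlation score depends on variance ranks only
        from snpmeta.bias import _kendall_s
        rng = np.random.default_rng(3)
        t_star = rng.normal(size=6)
        v = rng.uniform(0.01, 0.3, size=6)
        for transform in (np.sqrt, np.log, lambda x: x**3 + 2 * x):
            assert _kendall_s(t_star, transform(v)) == _kendall_s(t_star, v)

    def test_matches_exact_discrete_null_at_k6(self):
        """Empirical type-I error equals the enumerated permutation null.

        The Begg statistic is discrete: at small k its true size differs
        from the nominal 5%.  The correct calibration check is against the
        exact null rejection rate computed by enumerating all orderings.
        """
        k, alpha = 6, 0.05
        var_s = k * (k - 1) * (2 * k + 5) / 18.0
        reject_scores = 0
        total = 0
        for perm in itertools.permutations(range(k)):
            s = sum(np.sign(perm[j] - perm[i])
                    for i, j in itertools.combinations(range(k), 2))
            p = 2 * stats.norm.sf(max(0, abs(s) - 1) / math.sqrt(var_s))
            reject_scores += p < alpha
            total += 1
        exact_rate = reject_scores / total

        n_sets = 1200
        rej = 0
        for i in range(n_sets):
            cfg = SimulationConfig(true_or=1.3, raf_controls=0.18, n_cases=2000,
                                   n_controls=2000, k_studies=k,
                                   case_control_jitter=0.8, seed=30_000 + i)
            effects = effects_from_table(simulate_study_set(cfg).table)
            rej += begg_test(effects).p < alpha
        mc_se = math.sqrt(exact_rate * (1 - exact_rate) / n_sets)
        assert abs(rej / n_sets - exact_rate) <= 3 * mc_se + 1e-12


class TestFunnel:
    def test_one_point_per_study_with_se_axis(self, fixture_effects):
        pooled = fixed_effect_pool(fixture_effects)
        points, guides = funnel_data(fixture_effects, pooled)
        assert len(points) == 6
        assert [p.y for p in points] == [e.se_log_or for e in fixture_effects]
        assert guides["lower"][0] == pytest.approx(pooled.log_or)

    def test_all_effects_at_pooled_mean_sit_on_center(self):
        effects = [eff(0.3, s) for s in (0.1, 0.2, 0.3)]
        pooled = fixed_effect_pool(effects)
        points, _ = funnel_data(effects, pooled)
        assert all(p.x == pytest.approx(pooled.log_or) for p in points)
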