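# Methods

## Scope and model

`snpmeta` pools *published* study-level allelic odds ratios; it never sees
genotype or allele counts for real studies. Each input row is one
case-control sample set with an OR and a 95% CI, assumed to arise from an
approximately normal log-odds-ratio estimator. All inference is on the
natural-log scale; ORs and intervals are exponentiated only for display.

The standard error is back-transformed from the interval width,
`se = [ln(UL) − ln(LL)] / (2 z)`. `z` defaults to the exact 97.5% normal
quantile 1.959964; a switch (`--zcrit 1.96`, or `z_crit=1.96` in the API)
forces the rounded constant that many older analyses used. The two differ
by <0.002% in `se`, below any reported precision. Because published ORs
and CIs are rounded to two decimals, back-transformed effects carry an
irreducible input-rounding error; reproduction checks therefore compare
outputs only at the precision at which they were originally printed.
Two consequences for the built-in table are worth knowing:

- The subgroup-difference p computes to 0.2010, whereas the original
  report prints 0.21 — the print is not reachable exactly from the
  2-dp-rounded inputs under any variant of the Z-test we tried; agreement
  is at the second decimal within one unit.
- The Asian attributable-risk cell of the original summary table (3.92%)
  does not follow from its own printed inputs (0.12 and 1.33 give 3.81%);
  the pipeline reports what the formula yields.

## Pooling and heterogeneity

Fixed-effect pooling is the inverse-variance weighted mean; the
random-effects model is DerSimonian–Laird (moment estimator from Cochran's
Q, truncated at zero), with plain Wald intervals rather than
Knapp–Hartung — the default of the meta-analysis software generation this
synthesis belongs to, and required to match it. `I²` is Higgins'
`(Q − df)/Q`, truncated below at 0 and reported in percent. Model
selection uses the conventional screen (`p(Q) ≥ 0.1` and `I² ≤ 50%` keeps
fixed effects); both models remain directly callable. A single-row input
is legal everywhere and pools to itself with `Q = 0, df = 0, p(Q) = 1`
(needed because one "subgroup" of the built-in table is a single
aggregated row). Pooling a duplicate-free permutation of the same rows is
exactly invariant; Q is computed against the fixed-effect mean regardless
of the model finally reported.

## Subgroup comparison

Two pooled log effects are compared with
`z = Δ/√(se_a² + se_b²)` (two-sided normal); the statistic is
antisymmetric under swapping the strata, with identical p. For more than
two strata the package supplies a between-subgroup Q
(`Σ w_s (logOR_s − logOR_.)²`, χ² on s − 1 df), which reduces to `z²` for
two strata. The comparison uses each stratum's selected model by default;
a flag forces one model for sensitivity analysis.

## Publication-bias tests

Egger's test regresses the standardized effect `logORᵢ/seᵢ` on precision
`1/seᵢ` (ordinary least squares via statsmodels) and t-tests the intercept
on k − 2 df; it requires k ≥ 3 and a non-degenerate spread of precisions.
A perfect fit (zero residual variance) with a zero intercept is reported
as p = 1 rather than 0/0. Begg's test ranks the deviations from the
fixed-effect pool, standardized by `√(seᵢ² − se_FE²)`, against the
variances, and uses the tie-corrected normal approximation for Kendall's
S; the continuity correction is on by default and switchable, since
whether the original analysis applied it is unknowable. Degenerate rules:
deviations within 1e-12 of zero are treated as exact ties; complete ties
return tau = 0, p = 1 (no evidence of asymmetry); a study variance at or
below the pooled variance gets a floored denominator with a logged
warning.

Both tests are exactly checked against independent oracles (normal-
equations least squares; exhaustive pair counting; R metafor). Their
*size* is checked by simulation — with one caveat worth stating plainly:
the Begg statistic is discrete, so at k = 8 its true size at nominal
α = 0.05 is 0.031 with the continuity correction (0.061 without), by
exhaustive enumeration of the permutation null. A Monte-Carlo band centred
on 0.05 is therefore not attainable for Begg at small k by any correct
implementation; the unit suite instead verifies agreement with the exact
enumerated null rate.

## Attributable risk

The pooled control risk-allele frequency is the control-sample-size
weighted mean of the per-study frequencies, and
`PAR% = f/(f + 1) × 100` with `f = RAF·(OR − 1)` (Levin's formula, using
the allelic OR as the relative-risk approximation — adequate for a
modest-effect, non-rare exposure but still an approximation). Two modes:

- **full** (default for new analyses): unrounded pooled RAF and OR.
- **table**: every input rounded to two decimals before the formula —
  per-study RAFs before weighting and the pooled OR before Levin's
  formula. This matches how published summary tables are computed from
  rounded intermediates; on the built-in table it is what reproduces the
  printed overall (4.63%) and Caucasian (4.36%) cells, and it is also why
  the Asian pooled RAF prints as 0.12 (rounding the one 3-decimal
  frequency, 0.118, to 0.12 tips the weighted mean from 0.1147 to 0.1152).

## Synthetic data

The simulator draws risk-allele counts binomially at the chromosome level
(2 alleles per subject; HWE and allelic independence), with the case
frequency implied by the true allelic OR:
`p_case = OR·q/(1 − q + OR·q)`. Per-study ORs get Woolf log-scale CIs,
with 0.5 added to all four cells when any cell is zero
(Haldane–Anscombe); realized, not specified, control frequencies are
stored, as real studies report observed frequencies. Options: log-uniform
jitter on sample sizes (needed to give Egger's regressor spread),
between-study heterogeneity as a normal spread `tau` on the true log OR,
and a selection rule that suppresses studies with association p above a
threshold (publication-bias emulation; resamples until k survive, erroring
if acceptance falls below 1e-4). One seeded NumPy generator drives
everything; identical configs are bit-reproducible.

What it does *not* emulate: covariate-adjusted ORs (the real studies
report adjusted estimates with unspecified models — the synthesis
arithmetic is identical either way), HWE deviation, genotype-level
sampling, linkage with neighbouring variants, or overlapping control
panels. Passing simulation checks therefore validate the synthesis
arithmetic and calibration, not robustness to confounding or
non-independence in real data.

## Monte-Carlo problem sizes and conditions

Chosen once, as conditions the experiments are defined at: bias-test
calibration uses 5000 sets of k = 8 studies, true OR 1.3, control RAF
0.18, nominal 2000/2000 subjects, size jitter 0.8; coverage uses 1000
sets of k = 16 studies at true OR 1.27, 1000/1100 subjects, jitter 0.5
(the single-study scale of the built-in table); acceptance bands are
±3 Monte-Carlo standard errors. Seeds are fixed constants in the tests.

## Known limitations

- Published-precision inputs bound reproduction accuracy (see above).
- Bias tests on tables whose rows aggregate many sample sets (the
  built-in table's largest row pools 11 sets) are not comparable to
  per-set funnel analyses and are easily over-read at k = 6.
- No meta-regression, trim-and-fill, Peters/Harbord tests, REML or
  Paule–Mandel tau², or Knapp–Hartung intervals; no HWE testing (the
  `hwe_status` flag is carried as metadata only).
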