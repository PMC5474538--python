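study_label,year,design,genotyping_method,n_cases,n_controls,raf_controls,hwe_status,or_allelic,ci_lower,ci_upper,stratum,n_sample_sets
Wu,2010,synthesis of 11 case-control sets,"SNP array, PCR",4580,45269,0.19,in_hwe,1.24,1.17,1.32,Caucasian,11
Figueroa,2011,case-control,TaqMan,815,1141,0.118,in_hwe,1.32,1.09,1.59,Asian,1
Ma,2012,case-control,iPLEX,176,959,0.11,in_hwe,1.64,1.19,2.27,Asian,1
Wang,2013,case-control,TaqMan,1210,1008,0.11,in_hwe,1.31,1.09,1.57,Asian,1
Wang,2014,case-control,TaqMan,1050,1404,0.12,in_hwe,1.24,1.05,1.46,Asian,1
Wang,2015,case-control,TaqMan,363,384,0.11,in_hwe,1.53,1.13,2.08,Asian,1
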