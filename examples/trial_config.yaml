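# Synthetic immunogenicity sub-study: mediated protection, one binary
# baseline covariate, ~10% attack rate over three years of follow-up.
n_vaccine: 300
n_control: 300
covariate_name: subgroup
covariate_prevalence: 0.5
biomarker_name: titer
mu_vaccine: 1.0
mu_control: 0.0
sd_vaccine: 1.0
sd_control: 1.0
beta_t: -0.6931471805599453   # ln(0.5): halving of hazard per unit log2 titer
baseline_rate: 1.0e-4         # events per day at titer 0
horizon: 1095.0               # days
seed: 20240901
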