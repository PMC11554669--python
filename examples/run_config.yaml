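# Immune-correlates + VE analysis of a simulated trial (see trial_config.yaml).
input: examples/trial.csv        # produced by `immunove simulate`
covariates: [subgroup]
biomarkers: [titer]
biomarker_construction: raw
biomarker: titer
adjust_covariates: [subgroup]
model_family: cox
subgroup_covariate: subgroup
alpha: 0.05
n_bootstrap: 500
seed: 1
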