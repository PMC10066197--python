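# Initial path diagram for the observational analysis.
# Diversity at three scales acts on spatial variability of biomass
# (log_cv) directly, through mean biomass (overyielding route), and
# through spatial species covariation (insurance route).  Associations
# among the diversity scales are modeled as correlated errors, not paths.
group: site_id
alpha -> covariation
beta_disp -> covariation
gamma -> covariation
alpha -> mu
beta_disp -> mu
gamma -> mu
alpha -> log_cv
beta_disp -> log_cv
gamma -> log_cv
mu -> log_cv
covariation -> log_cv
alpha ~~ gamma
alpha ~~ beta_disp
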