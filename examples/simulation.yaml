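# Four-arm simulated trial: two large and two small tumor-type groups,
# survival driven by the true log regrowth rate.
output_dir: out
seed: 1
simulate:
  cohort:
    groups:
      - {label: NSCLC, n_patients: 120, mu_log_ks: -3.91, mu_log_kg: -5.52, mu_log_sld0: 4.01}
      - {label: MTC, n_patients: 90, mu_log_ks: -3.69, mu_log_kg: -6.21, mu_log_sld0: 3.81}
      - {label: OTHER_FUS, n_patients: 28, mu_log_ks: -3.91, mu_log_kg: -5.12, mu_log_sld0: 4.01}
      - {label: OTHER_ALT, n_patients: 20, mu_log_ks: -3.91, mu_log_kg: -5.12, mu_log_sld0: 4.01}
    omega2_log_ks: 0.25
    omega2_log_kg: 0.25
    omega2_log_sld0: 0.1
    sigma_sld_mm: 4.0
    visit_schedule_days: [0, 21, 42, 63, 105, 168, 252, 365]
    dropout_prob_per_visit: 0.05
  survival:
    family: lognormal
    intercept: 0.48    # centers median OS near 300 days at mu_log_kg ~ -5.8
    beta: {log_kg: -0.9}
    scale: 0.6
    admin_censor_day: 2000.0
    random_censor_rate: 0.0005
tgi:
  max_iter: 30
parametric:
  covariates: [logKG, ALBU, NLR, ECOG, SLD0, liver_met, n_tumor_sites, race_asian, sex]
  alpha: 0.01
ml:
  n_rounds: 200
  learning_rate: 0.1
  max_depth: 3
  min_samples_leaf: 30
  k_neighbors: 30
  n_bootstrap: 200
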