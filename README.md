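# tgios

Tumor-dynamics metrics and overall-survival (OS) prediction for multi-tumor-type
oncology trial cohorts, as a tested, fully synthetic-data-driven pipeline:

1. **`tgios.synthetic_trial`** — seeded cohort simulator: biexponential tumor-size
   (SLD) trajectories with log-normal inter-individual variability and additive
   normal residual error, baseline covariates, and AFT survival outcomes whose
   hazard depends on the true log tumor-regrowth rate.
2. **`tgios.tgi_dynamics`** — biexponential tumor-growth-inhibition (TGI) model
   `SLD(t) = SLD0·(e^{-KS·t} + e^{KG·t} - 1)`, closed-form time-to-tumor-growth
   `TTG = ln(KS/KG)/(KS+KG)`, the evaluability filter (baseline + ≥1
   post-baseline measurement), empirical-Bayes individual/population fitting,
   and goodness-of-fit summaries.
3. **`tgios.parametric_os`** — Kaplan–Meier estimation, univariate Cox screening
   (Breslow ties, Newton–Raphson), parametric AFT survival regression over
   exponential/Weibull/lognormal/loglogistic families with AIC family selection,
   likelihood-ratio backward stepwise elimination, and per-patient survival curves.
4. **`tgios.ml_os`** — tumor-type-agnostic gradient-boosted survival model:
   11 fixed features (KS, KG, TTG + 8 baseline covariates; tumor type is never
   an input), an AFT-objective tree ensemble, per-patient curves via
   Kaplan–Meier over terminal-leaf co-occurrence neighbors on a 401-point grid
   (0–2000 days, step 5), and bootstrap 95% prediction intervals for pooled
   subgroup survival.
5. **`tgios.explain`** — exact path-dependent tree-Shapley attributions of the
   ensemble risk margin (local accuracy to machine precision), per-subgroup
   feature rankings, and beeswarm summary plots.
6. **`tgios.evaluation`** — log(KG)-quartile and tumor-type KM stratification,
   pairwise Wilcoxon rank-sum tests with Holm adjustment, band-vs-observed-KM
   coverage reports, and Harrell's concordance index.
7. **`tgios.cli_io`** / **`tgios.cli`** — config handling, CSV schema
   validation, and the end-to-end orchestrated run with a hashed manifest.

Missing TGI features (non-evaluable patients) are passed to the tree learner's
native missing-value routing — no imputation. All randomness is seed-driven;
reruns with the same config are bit-identical.

## CLI

```bash
# end-to-end: simulate -> fit TGI -> both OS models -> explain -> evaluate
tgios run-all --config examples/simulation.yaml --out out/ --seed 1

# stage by stage
tgios simulate        --config examples/simulation.yaml --out data/
tgios fit-tgi         --data data/ --out out/
tgios fit-os-parametric --data data/ --tgi-metrics out/tgi_metrics.csv --out out/
tgios fit-os-ml       --data data/ --tgi-metrics out/tgi_metrics.csv --out out/ --bootstrap-b 200
tgios explain         --data data/ --tgi-metrics out/tgi_metrics.csv --out out/
tgios evaluate        --data data/ --tgi-metrics out/tgi_metrics.csv --out out/
```

The config is YAML or JSON with either a `simulate:` block (cohort + survival
generator settings) or an `inputs:` block pointing at three CSVs
(`longitudinal.csv`: patient_id, time_days, sld_mm; `baseline.csv`: patient_id,
tumor_type + covariates; `survival.csv`: patient_id, time_days, event).
See `examples/simulation.yaml`.

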