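# btxrisk

Occupational risk analysis for long-term co-exposure to benzene, toluene
and xylenes (BTX) based on hematological effects, built for occupational
epidemiologists and risk assessors. The package covers the full chain from
workplace air monitoring to health-based exposure guidance:

1. **Cumulative exposure (CE).** Below-LOD air samples are substituted at
   LOD/2, workplace mean 8h-TWA concentrations are averaged over the
   monitoring period, and each worker's CE is `work years × mean 8h-TWA`
   (mg/m³ × year). `ln CE` is the regression dose metric.
2. **Hematological-damage endpoint.** Nine hemogram parameters are tracked
   at baseline and follow-up; the decline is baseline − follow-up. A worker
   is a case when ≥2 parameters sit below the adult reference lower limits
   at follow-up (MPV excluded), or ≥2 parameters declined beyond the
   sex-specific 95th percentile.
3. **Association models.** Paired t-tests on the change, covariate-adjusted
   OLS of decline on ln CE, stratified analyses and interaction (effect
   modification) tests.
4. **WQS mixture regression.** A from-scratch generalized weighted
   quantile sum estimator: quartile-scored analytes, simplex weights
   `w ≥ 0, Σw = 1` estimated by B = 100 bootstrap likelihood maximizations
   on a 40% training split, index effect validated on the 60% holdout.
5. **Benchmark-dose suite.** The eight dichotomous dose–response families
   (Logistic, Probit, Log-Logistic, Log-Probit, Multistage 1°/2°, Weibull,
   Gamma, Dichotomous Hill) fit by binomial maximum likelihood on CE dose
   groups; extra risk `(P(d) − P(0))/(1 − P(0))`; BMD at BMR = 10%; BMDL as
   the one-sided 95% profile-likelihood lower bound (χ²₁(0.90)/2 cutoff);
   EPA-style selection (GOF p > 0.1, BMD ≤ max dose, BMD/BMDL < 3, lowest
   AIC); 8h-TWA reference exposure level `REL = BMDL / 40 working years`.

A calibrated synthetic-cohort generator (`btxrisk.cohort`) reproduces the
statistical structure of a petrochemical-worker follow-up cohort —
marginals, exposure rank correlations, dose–decline effect sizes and a
known damage mechanism — so every stage is testable by parameter recovery
without access to any worker-level data.

## Worked example

`examples/benchmark_dose.py` simulates 2000 workers whose damage mechanism
is a one-stage multistage model with a known BMD, groups them into 8 CE
dose groups, fits the suite and derives the REL:

```
true BMD at 10% extra risk: 0.351 mg/m3 x year
8 dose groups, sizes [250, 250, 250, 250, 250, 250, 250, 250]
  multistage1       AIC  2295.64  gof_p 0.267  BMD 0.318  BMDL 0.246
  probit            AIC  2296.51  gof_p 0.209  BMD 0.487  BMDL 0.430
  ...
best model: multistage1; BMD 0.318, BMDL 0.246 mg/m3 x year
8h-TWA REL = BMDL/40 = 0.0061 mg/m3 (0.0019 ppm)
```

The generating family is recovered as the best model, the estimated BMD
(0.318) sits near the truth (0.351), and the BMDL stays below it — the
behavior the one-sided 95% bound is designed to have. Each script in
`examples/` demonstrates one capability (cohort simulation, exposure
metrics, the damage endpoint, association models, WQS, the full pipeline)
and prints what its numbers mean.

A thin CLI wraps the same library:

```bash
btxrisk simulate --n-workers 1054 --seed 1 --out synth/
btxrisk all --seed 1 --out run/
btxrisk rel --bmdl 1.559 --analyte benzene   # -> REL = 0.0390 mg/m3
```

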