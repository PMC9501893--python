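# Methods

This note documents the models, estimators, numerical choices and known
limitations of `btxrisk`, in the order the pipeline runs them.

## Exposure metrics

Ambient workplace air samples carry an analyte (benzene, toluene or
xylene), an 8h time-weighted-average concentration in mg/m³, and an LOD
flag. Censored values are substituted at LOD/2, the standard simple
imputation for lightly censored occupational monitoring data; with default
LODs of 0.01/0.02/0.02 mg/m³ this is a small perturbation relative to the
workplace means. Cumulative exposure is

    CE = work years × mean 8h-TWA      [mg/m³ × year]

with the mean taken per (workplace, analyte) over the monitoring period.
Eligibility requires ≥1 work year, and the mean TWA is at least LOD/2 > 0,
so CE > 0 and `ln CE` is always defined; this is asserted at construction.

**Quantile scoring.** Cut-points are linear-interpolation empirical
quantiles at i/q (quartiles by default). A value exactly equal to a
cut-point goes to the *lower* group, so ties always share a score and the
scoring is invariant under strictly increasing transforms. For WQS the
cut-points are computed on whatever set is passed (the training split in
the standard flow).

**Dose groups.** Workers sorted by CE are split into `n_groups`
equal-frequency groups; boundaries are pushed forward past ties so equal
CE values never straddle groups; each group's dose is its median CE. The
target band of 70–200 workers per group is checked and, when the cohort
size makes it infeasible, the equal-frequency split is kept with a logged
warning rather than failing — group counts and interval endpoints are
always written out so the grouping is auditable.

## Hematological-damage endpoint

Nine parameters: WBC, neutrophils, monocytes, lymphocytes (10⁹/L), RBC
(10¹²/L), hemoglobin (g/L), hematocrit (%), platelets (10⁹/L), MPV (fL).
Decline = baseline − follow-up (positive = worse). A worker is a case iff

* **criterion 1:** ≥2 parameters below the sex-specific lower reference
  limit at follow-up. MPV is excluded — it has no reference interval in
  the national standard the limits derive from (WS/T 405-2012). The
  shipped limits are that standard's published values and are plain
  configuration: any `ReferenceLimits` table can be substituted.
* **criterion 2:** ≥2 parameters whose decline exceeds the 95th percentile
  of the same-sex decline distribution. MPV *is* included here (it has a
  decline even without a reference interval); this inclusion is an
  interpretive choice, documented as such.

Percentiles use linear interpolation between order statistics; sex strata
below 20 workers are refused because the empirical 95th percentile would
be too unstable to define case status. By construction roughly 5% of each
sex exceeds any single criterion-2 threshold; with independent parameters
the ≥2-parameter rate is ≈ 1 − 0.95⁹ − 9·0.05·0.95⁸ ≈ 7%, which the test
suite verifies on synthetic data.

## Association models

All continuous-outcome inference is OLS (statsmodels), α = 0.05 two-sided,
no multiple-testing correction — a deliberate mirror of conventional
occupational-cohort practice for this design. The exposure coefficient β
is the extra decline per unit ln(mg/m³ × year). Stratified analyses refit
the model within strata (dropping stratum-constant covariates) and test
effect modification by the Wald test of a ln CE × stratum product term in
the pooled model (joint F when the stratifier has >2 levels). Group
comparisons of decline use OLS with group indicators, reporting adjusted
means at covariate means. Baseline-level strata use tertiles with the same
quantile rule as everywhere else. Rank-deficient designs are rejected with
the offending columns named.

## WQS regression

For mixture components scored 0..3, the index is `Σ wⱼ qⱼ` with weights on
the simplex. For each of B bootstrap resamples of the training split the
Gaussian likelihood of `outcome ~ β·index + covariates` is maximized over
the weights. Because the coefficient block is profiled out by OLS for
fixed weights, the objective reduces to the residual SSE as a function of
the weights alone; the simplex is handled by a softmax reparameterization
optimized by Nelder-Mead from 5 seeded starts (the likelihood can be flat
in the weights, so multi-start matters more than gradient speed at k = 3).
Failed replicates are dropped with a warning; >50% failures abort.

Aggregation across bootstraps is the arithmetic mean of converged weight
vectors (default), with an optional mode weighting each replicate by the
magnitude of its index t statistic. The aggregated index is then scored on
the validation split (40/60 split, seeded) and its per-quartile effect
estimated by covariate-adjusted OLS. The outcome family is a pluggable
hook with Gaussian the only shipped family, matching the continuous
decline outcomes. A single signed β with nonnegative weights is reported;
there are no separate positive/negative index runs.

**Detectability.** With the cohort-calibrated effect sizes (e.g. 0.012
×10⁹/L monocyte decline per ln CE against a 0.22 residual SD), the
per-quartile index effect is near the detection limit at n ≈ 1000; weight
recovery demonstrations therefore use stronger slopes, and the recovery
test works at n = 2000 with the active component's signal about 3× the
noise SD.

## Benchmark-dose suite

Eight dichotomous families, parameterized with background g ∈ [0,1] and,
where applicable, plateau v ∈ (0,1]:

| family | P(d) |
|---|---|
| Logistic | expit(a + b·d) |
| Probit | Φ(a + b·d) |
| Log-Logistic | g + (1−g)·expit(a + b·ln d) |
| Log-Probit | g + (1−g)·Φ(a + b·ln d) |
| Multistage (1°, 2°) | g + (1−g)·(1 − exp(−Σ bᵢ dⁱ)) |
| Weibull | g + (1−g)·(1 − exp(−b·dᵃ)) |
| Gamma | g + (1−g)·GammaCDF(b·d; a) |
| Dichotomous Hill | g + v(1−g)·expit(a + b·ln d) |

`ln d` is the natural log; log-dose families take P(0) = g as the
continuous limit. Bounds follow common dichotomous-suite conventions:
multistage stage coefficients and log-dose slopes ≥ 0 (enforcing
monotonicity), Logistic/Probit slopes unconstrained, and they are recorded
with each fit. Fitting maximizes the grouped binomial log-likelihood with
L-BFGS-B from 10 seeded starts (heuristic start plus perturbations),
ftol 1e-10; probabilities are clipped at 1e-12 inside the likelihood.
Boundary solutions (e.g. g → 0 with no cases anywhere) are legitimate and
flagged rather than hidden.

**Extra risk and BMD.** Extra risk is (P(d) − P(0))/(1 − P(0)); the BMD
solves extra risk = BMR (default 0.10) in closed form for all families
except Logistic/Probit, which use Brent root-finding to 1e-8 relative
tolerance. A plateau below the BMR (small-v Dichotomous Hill, or a flat
fit) raises "BMR unreachable" instead of returning an extrapolation.

**Profile-likelihood BMDL.** Each family is reparameterized so one
slope-like parameter is an explicit function of (BMD, BMR) and the
remaining free parameters — closed form in every family (for the 2°
multistage the quadratic share of the benchmark is a free parameter on
[0,1]). The BMDL is the smallest b with profile log-likelihood within
χ²₁(0.90)/2 = 1.352771 of the maximum (the one-sided 95% bound; the
constant is stated here because guidance documents typically leave it
implicit), found by geometric walk-down plus Brent on the profile
deviance, with the inner constrained maximization run from 3 starts. A
dense grid-search oracle over (BMD, background) verifies the profile
within 2% in the test suite.

**GOF and selection.** Pearson χ² = Σ(cases − nP̂)²/[nP̂(1−P̂)] with
df = groups − k and upper-tail p; fitted probabilities of exactly 0/1 are
continuity-guarded at half a count with a logged note. Selection keeps
fits with GOF p > 0.1, BMD ≤ max group dose and BMD/BMDL < 3, then takes
the lowest AIC (AIC = 2k − 2lnL, asserted as an identity). An empty
survivor set returns an explicit "no adequate model", never a fallback.

**REL.** REL = BMDL / working years (default 40, a full working life from
age 20 to the common retirement age of 60). The ppm conversion uses
rel × molar volume / molecular weight with 24.45 L/mol (25 °C, 1 atm) by
default; the convention is an explicit, configurable argument because
published conversions in this area are not always internally consistent,
and the mg/m³ value is the primary output.

## Synthetic cohort generator

The generator emulates a BTX-exposed petrochemical follow-up cohort.
Defaults (all overridable in `CohortSpec`): n = 1054 workers; 77.42% male;
age 39.91 ± 6.57 y; BMI 23.33 ± 3.11; 32.54% smokers (pack-years gamma
among smokers, scaled so the cohort mean is 2.84); 46.77% drinkers; 36.72%
at the first factory site; work years 18.75 ± 7.70 truncated at 1.

* **Exposure.** ln CE is multivariate normal via a Gaussian copula; the
  Pearson copula parameter is 2·sin(π·ρ_s/6) so the *Spearman* correlation
  hits its target (0.47 everywhere by default, inside the observed
  0.440–0.502 band). Marginal medians/IQRs of 0.65 (0.36, 1.03),
  0.84 (0.56, 1.23) and 1.37 (0.71, 2.40) mg/m³ × year give
  (μ, σ) = (ln median, ln(q75/q25)/(2·z₀.₇₅)). Non-positive-definite
  targets after the sin transform raise an error naming the matrix.
* **Hemograms.** Baselines are normals truncated at 0 (truncation is
  logged; at the default calibration it touches ~2% of monocyte draws and
  shifts that mean by < 0.002). Decline = calibrated mean + Σ β·(ln CE − μ)
  + noise, so the expected decline equals the calibrated mean regardless
  of the slopes (the calibrated means are nonzero — e.g. monocytes 0.15,
  hemoglobin 8.34 — so a pure slope-times-dose model would miss them). The
  noise is correlated with baseline at the ρ implied by the baseline,
  decline and follow-up SDs, because repeated measures on one worker are
  strongly dependent; without this the follow-up marginals are far too
  wide and the endpoint incidence roughly doubles. Follow-up is truncated
  at 0 and the decline recomputed, preserving decline = baseline −
  follow-up exactly.
* **Damage mechanism.** Case status is Bernoulli with p = P(CE) under a
  configurable dose–response law applied to one analyte's CE. The default
  (one-stage multistage, g = 0.12, b₁ = 0.05 on benzene) yields ~15%
  incidence and a mechanism BMD of 2.107 mg/m³ × year, comparable to the
  cohort scale. For *coverage* experiments the tests use an identifiable
  mechanism (g = 0.10, b₁ = 0.3, BMD 0.351 well inside the CE range):
  the default slope is shallow enough that at n = 1000 the stage
  coefficient hits its zero bound in ~10% of replicates, where one-sided
  profile bounds are non-regular and nominal coverage is not the expected
  behavior.
* **Randomness.** One RNG stream per table (covariates, exposure,
  hemograms, ambient, damage), derived from the master seed by fixed
  spawn keys, so regenerating one table never perturbs another and equal
  specs give byte-identical output.
* **What it does not emulate.** Covariates are independent of exposure
  (no confounding) by default; there is no seasonal structure, workplace
  clustering beyond shared marginals, loss to follow-up, or measurement
  error in the hemograms. Passing recovery tests therefore demonstrates
  estimator correctness under the assumed data-generating process, not
  robustness to confounding or informative dropout.

## Problem sizes in the shipped tests

Recovery and coverage checks run at 200 replicates of n = 1000 workers
with 8 dose groups (BMD/BMDL), n = 2000 with B = 100 bootstraps (WQS
recovery), 40 replicates at n = 300, B = 10 (WQS null uniformity), and
300–400 replicates of n = 100 (interaction size) — sizes chosen so each
statistical property is measured with useful precision while the whole
suite stays quick to run routinely.

## Known limitations

* The LOD/2 substitution is simple imputation; no censored-likelihood
  alternative is provided.
* The WQS estimator ships only the Gaussian family and the single 40/60
  split (no repeated holdout), and "stability selection" is operationalized
  as mean (or |t|-weighted) aggregation — the literature does not fix a
  formula.
* The BMD stage is group-level only; covariate-adjusted dose–response and
  Bayesian model averaging are out of scope.
* Reference limits and decline thresholds are computed from the same
  cohort being classified; no external-reference mode is provided.
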