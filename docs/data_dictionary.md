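# Data dictionary

All tables are plain CSV with the headers below.

## Ambient samples (`ambient.csv`)

| column | type | meaning |
|---|---|---|
| workplace_id | int | workplace the sample was collected in |
| analyte | str | `benzene`, `toluene` or `xylene` |
| concentration | float | 8h-TWA concentration, mg/m³; empty when below the LOD |
| below_lod | bool | measurement below the limit of detection |
| lod | float | limit of detection for this analyte, mg/m³ |
| period | str | sampling-period label |

## Workers (`workers.csv`)

| column | type | meaning |
|---|---|---|
| worker_id | int | unique worker key |
| workplace_id | int | workplace assignment |
| sex | str | `male` / `female` |
| age | float | years at baseline |
| bmi | float | kg/m² at baseline |
| smoker | int | 1 = smoker |
| pack_years | float | pack-years of smoking (0 for non-smokers) |
| drinker | int | 1 = drinker |
| factory_guangzhou | int | 1 = first factory site |
| work_years | float | years of occupational exposure (≥ 1) |
| damage_case | int | true mechanism-driven case indicator (synthetic cohorts only) |

## Hemograms (`hemograms.csv`)

`baseline_<p>`, `followup_<p>`, `decline_<p>` for each parameter
`p ∈ {wbc, neutrophils, monocytes, lymphocytes, rbc, hemoglobin,
hematocrit, platelets, mpv}`; decline = baseline − follow-up. Units: 10⁹/L
(counts), 10¹²/L (RBC), g/L (hemoglobin), % (hematocrit), fL (MPV).

## Exposure profiles (`exposure.csv`)

`worker_id` plus `ce_<analyte>` (mg/m³ × year), `ln_ce_<analyte>` and,
after the pipeline's exposure stage, `quartile_<analyte>` ∈ {0,1,2,3}.

## Damage calls (`damage_calls.csv`)

| column | meaning |
|---|---|
| worker_id | worker key |
| criterion1_count | parameters below the reference lower limit at follow-up (MPV excluded) |
| criterion2_count | parameters with decline above the sex-specific 95th percentile (MPV included) |
| is_case | criterion1_count ≥ 2 or criterion2_count ≥ 2 |

## Dose groups (`dose_groups.csv`)

`analyte, group, ce_low, ce_high, dose, n, cases` — contiguous CE
intervals `[ce_low, ce_high)` (last group closed), `dose` = median CE of
the group's workers.

## BMD fits (`bmd_fits.csv`)

`analyte, family, loglik, aic, gof_chi2, gof_df, gof_p, bmd, bmdl,
converged` — one row per (analyte, family); `bmd`/`bmdl` empty when the
BMR is unreachable for that fit.

## WQS results (`wqs.csv`)

`outcome, beta, ci_low, ci_high, p_trend, w_benzene, w_toluene, w_xylene,
n_bootstrap, seed` — `beta` is the outcome change per one-quartile
increase of the weighted index; weights sum to 1.

## Association results (`associations.csv`)

`outcome, analyte, beta, ci_low, ci_high, p_trend, mean_decline, paired_t,
paired_p` — `beta` per unit ln(mg/m³ × year), covariate-adjusted.

## Reference limits (YAML/CSV)

Keyed by parameter and sex: `parameter, sex, lower_limit`. MPV must not
appear.
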