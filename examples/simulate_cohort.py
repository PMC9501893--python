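"""Generate a calibrated synthetic worker cohort and summarize it.

The default CohortSpec reproduces the study conditions of a petrochemical
follow-up cohort: 1054 workers, 77% male, ~18.75 mean work years, median
benzene/toluene/xylene cumulative exposures of 0.65/0.84/1.37 mg/m3 x year
with rank correlations ~0.47, and dose-dependent four-year declines in
blood counts.
"""

import numpy as np
from scipy.stats import spearmanr

from btxrisk import CohortSpec, generate_cohort

spec = CohortSpec(seed=1)
workers, hemograms, exposure = generate_cohort(spec)

print(f"workers: {len(workers)}, male fraction {np.mean(workers.sex == 'male'):.3f}")
print(f"median benzene CE: {exposure.ce_benzene.median():.2f} mg/m3 x year")
rho = spearmanr(exposure.ce_benzene, exposure.ce_toluene).statistic
print(f"benzene-toluene CE rank correlation: {rho:.3f}")
print(f"baseline monocytes: {hemograms.baseline_monocytes.mean():.2f} "
      f"+/- {hemograms.baseline_monocytes.std():.2f} x10^9/L")
print(f"mean monocyte decline: {hemograms.decline_monocytes.mean():.3f} x10^9/L")
print(f"true-mechanism damage incidence: {workers.damage_case.mean():.3f}")
print(f"mechanism BMD at 10% extra risk: {spec.true_bmd():.3f} mg/m3 x year")
# Each line mirrors a calibration target: cohort composition, exposure
# medians and correlation, hemogram marginals, and the dose-response
# mechanism that drives the damage outcome.
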