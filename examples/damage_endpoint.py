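"""Classify hematological damage with the two-criteria endpoint.

A worker is a case when at least two parameters sit below the adult
reference lower limits at follow-up (criterion 1, MPV excluded), or at
least two parameters declined more than the sex-specific 95th percentile
(criterion 2, MPV included).
"""

from btxrisk import CohortSpec, classify_damage, decline_thresholds, generate_cohort
from btxrisk.hematology import PARAMETERS

workers, hemograms, _ = generate_cohort(CohortSpec(seed=2))
declines = hemograms[["worker_id"] + [f"decline_{p}" for p in PARAMETERS]]

thresholds = decline_thresholds(declines, workers.sex)
print("95th-percentile decline thresholds (male):")
print(thresholds.loc["male"].round(3).to_string())

calls = classify_damage(hemograms, declines, workers.sex)
print(f"\ncases: {calls.is_case.sum()} / {len(calls)} "
      f"({100 * calls.is_case.mean():.1f}%)")
print(f"  via >=2 below-limit parameters: {(calls.criterion1_count >= 2).sum()}")
print(f"  via >=2 extreme declines:       {(calls.criterion2_count >= 2).sum()}")
# The case indicator is the dichotomous endpoint that the benchmark-dose
# stage models against cumulative exposure.
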