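"""Hemogram declines and the dichotomous hematological-damage endpoint.

Nine parameters are tracked at baseline and follow-up: WBC, neutrophil,
monocyte and lymphocyte counts (10^9/L), RBC counts (10^12/L), hemoglobin
(g/L), hematocrit (%), platelet counts (10^9/L) and mean platelet volume
(MPV, fL).  The decline is baseline minus follow-up, so a positive decline
is a decrease over the follow-up interval.

A worker is a hematological-damage case when either

1. at least two parameters (MPV excluded — it has no reference interval in
   the national standard) sit below the lower limit of the adult normal
   range at follow-up, or
2. at least two parameters (MPV included) declined by more than the 95th
   percentile of the same-sex decline distribution.

The default lower limits ship from the published Chinese adult reference
intervals for blood cell analysis (WS/T 405-2012); they are configuration,
not data, and can be replaced wholesale via :class:`ReferenceLimits`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARAMETERS = (
    "wbc",
    "neutrophils",
    "monocytes",
    "lymphocytes",
    "rbc",
    "hemoglobin",
    "hematocrit",
    "platelets",
    "mpv",
)

#: parameters eligible for the below-lower-limit criterion (no MPV interval)
CRITERION1_PARAMETERS = tuple(p for p in PARAMETERS if p != "mpv")

# Adult reference-interval lower limits (WS/T 405-2012 published values);
# replaceable configuration — the classifier takes any ReferenceLimits.
_DEFAULT_LIMITS = {
    "wbc": {"male": 3.5, "female": 3.5},
    "neutrophils": {"male": 1.8, "female": 1.8},
    "monocytes": {"male": 0.1, "female": 0.1},
    "lymphocytes": {"male": 1.1, "female": 1.1},
    "rbc": {"male": 4.3, "female": 3.8},
    "hemoglobin": {"male": 130.0, "female": 115.0},
    "hematocrit": {"male": 40.0, "female": 35.0},
    "platelets": {"male": 125.0, "female": 125.0},
}


@dataclass(frozen=True)
class ReferenceLimits:
    """Sex-specific lower limits of the normal range, excluding MPV."""

    limits: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_LIMITS.items()})

    def __post_init__(self) -> None:
        if "mpv" in self.limits:
            raise ValueError("MPV has no reference interval and must not carry a limit")
        for param, by_sex in self.limits.items():
            for sex, lim in by_sex.items():
                if lim <= 0:
                    raise ValueError(f"limit for {param}/{sex} must be > 0, got {lim}")

    def lower(self, param: str, sex: str) -> float:
        try:
            return self.limits[param][sex]
        except KeyError as exc:
            raise KeyError(f"no reference lower limit for parameter {param!r}, sex {sex!r}") from exc

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceLimits":
        """Build from a table with columns parameter, sex, lower_limit."""
        limits: dict = {}
        for row in frame.itertuples(index=False):
            limits.setdefault(row.parameter, {})[row.sex] = float(row.lower_limit)
        return cls(limits)

    @classmethod
    def from_yaml(cls, path) -> "ReferenceLimits":
        """Load from YAML: ``parameter: {sex: limit}`` or ``parameter: limit``
        (a bare number applies to both sexes)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        limits = {
            p: (dict(v) if isinstance(v, dict) else {"male": float(v), "female": float(v)})
            for p, v in raw.items()
        }
        return cls(limits)


def compute_decline(pairs: pd.DataFrame) -> pd.DataFrame:
    """Element-wise decline (baseline minus follow-up) for every parameter.

    ``pairs`` must carry ``baseline_<p>`` and ``followup_<p>`` columns for
    every parameter ``p``; the result has ``decline_<p>`` columns alongside
    ``worker_id``.
    """
    out = pd.DataFrame({"worker_id": pairs["worker_id"].to_numpy()})
    for p in PARAMETERS:
        b_col, f_col = f"baseline_{p}", f"followup_{p}"
        for col in (b_col, f_col):
            if col not in pairs.columns:
                raise KeyError(f"missing hemogram column {col!r}")
            if pairs[col].isna().any():
                raise ValueError(f"missing values in {col!r}")
        out[f"decline_{p}"] = pairs[b_col].to_numpy(dtype=float) - pairs[f_col].to_numpy(dtype=float)
    return out


def decline_thresholds(
    declines: pd.DataFrame,
    sex: pd.Series | np.ndarray,
    percentile: float = 95.0,
    min_stratum: int = 20,
) -> pd.DataFrame:
    """Sex-specific decline percentiles (default the 95th) per parameter.

    Uses linear interpolation between order statistics.  Returns a frame
    indexed by sex with one column per parameter.  A sex stratum smaller
    than ``min_stratum`` is refused: the empirical percentile would be too
    unstable to define case status.
    """
    sex = np.asarray(sex)
    rows = {}
    for s in np.unique(sex):
        mask = sex == s
        if mask.sum() < min_stratum:
            raise ValueError(f"sex stratum {s!r} has {int(mask.sum())} workers (< {min_stratum})")
        rows[s] = {
            p: float(np.quantile(declines.loc[mask, f"decline_{p}"], percentile / 100.0, method="linear"))
            for p in PARAMETERS
        }
    return pd.DataFrame(rows).T.rename_axis("sex")


def classify_damage(
    followup: pd.DataFrame,
    declines: pd.DataFrame,
    sex: pd.Series | np.ndarray,
    limits: ReferenceLimits | None = None,
    thresholds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the two-criteria damage definition to every worker.

    ``followup`` needs ``followup_<p>`` columns; ``declines`` is the output
    of :func:`compute_decline`.  ``thresholds`` defaults to the sex-specific
    95th percentiles computed from ``declines`` itself (the cohort defines
    its own extreme-decline cut-offs).  Returns ``worker_id``,
    ``criterion1_count``, ``criterion2_count``, ``is_case``.
    """
    limits = limits or ReferenceLimits()
    if thresholds is None:
        thresholds = decline_thresholds(declines, sex)
    sex = np.asarray(sex)

    n = len(followup)
    c1 = np.zeros(n, dtype=int)
    for p in CRITERION1_PARAMETERS:
        lower = np.array([limits.lower(p, s) for s in sex])
        c1 += (followup[f"followup_{p}"].to_numpy(dtype=float) < lower).astype(int)

    c2 = np.zeros(n, dtype=int)
    for p in PARAMETERS:  # MPV participates: it has a decline
        thr = thresholds[p].loc[sex].to_numpy(dtype=float)
        c2 += (declines[f"decline_{p}"].to_numpy(dtype=float) > thr).astype(int)

    return pd.DataFrame(
        {
            "worker_id": followup["worker_id"].to_numpy(),
            "criterion1_count": c1,
            "criterion2_count": c2,
            "is_case": (c1 >= 2) | (c2 >= 2),
        }
    )
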