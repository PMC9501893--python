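"""Cumulative-exposure metrics for workplace air monitoring data.

Turns ambient 8h-TWA air samples and per-worker work histories into the
dose metrics the downstream analyses consume:

* below-LOD substitution at LOD/2,
* per-(workplace, analyte) mean 8h-TWA concentrations,
* cumulative exposure CE = work years x mean 8h-TWA (mg/m3 x year),
* empirical quantile scores (quartiles by default) for mixture indices,
* contiguous CE dose groups for benchmark-dose estimation.

Ambient sample tables are plain pandas DataFrames with columns
``workplace_id, analyte, concentration, below_lod, lod`` (and optionally a
``period`` label); exposure profiles are DataFrames keyed by ``worker_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANALYTES = ("benzene", "toluene", "xylene")

AMBIENT_COLUMNS = ["workplace_id", "analyte", "concentration", "below_lod", "lod", "period"]


@dataclass(frozen=True)
class DoseGroup:
    """One contiguous CE interval used as a dose group.

    ``dose`` is the median CE of the workers inside the interval; the
    interval is half-open ``[low, high)`` except the last group, which is
    closed at the top.
    """

    analyte: str
    index: int
    low: float
    high: float
    dose: float
    n: int
    cases: int

    def __post_init__(self) -> None:
        if not (0 <= self.cases <= self.n):
            raise ValueError(f"cases ({self.cases}) must lie in [0, n={self.n}]")


def substitute_lod(samples: pd.DataFrame) -> pd.DataFrame:
    """Replace below-LOD concentrations with LOD/2.

    Samples flagged ``below_lod`` get ``concentration = lod / 2``; all other
    rows are returned unchanged.  A flagged sample with a missing or
    non-positive LOD is an error.
    """
    out = samples.copy()
    flagged = out["below_lod"].astype(bool)
    lods = out.loc[flagged, "lod"]
    bad = lods.isna() | (lods <= 0)
    if bad.any():
        raise ValueError(
            f"below-LOD samples without a valid LOD at rows {list(out.index[flagged][bad])}"
        )
    out.loc[flagged, "concentration"] = lods / 2.0
    return out


def workplace_mean_twa(samples: pd.DataFrame) -> pd.DataFrame:
    """Mean 8h-TWA per (workplace, analyte) after LOD substitution.

    Returns a DataFrame with columns ``workplace_id, analyte, mean_twa``.
    Raises if any (workplace, analyte) group would be empty of usable
    concentrations.
    """
    subbed = substitute_lod(samples)
    if subbed["concentration"].isna().any():
        missing = subbed.loc[subbed["concentration"].isna(), ["workplace_id", "analyte"]]
        pairs = sorted(set(map(tuple, missing.itertuples(index=False))))
        raise ValueError(f"missing concentrations for (workplace, analyte) pairs: {pairs}")
    means = (
        subbed.groupby(["workplace_id", "analyte"], sort=True)["concentration"]
        .mean()
        .rename("mean_twa")
        .reset_index()
    )
    return means


def compute_ce(work_years: float, mean_twa: float) -> float:
    """Cumulative exposure: work years x mean 8h-TWA, in mg/m3 x year.

    Eligibility requires at least one year of employment.
    """
    if work_years < 1:
        raise ValueError(f"work_years must be >= 1 (eligibility), got {work_years}")
    if mean_twa < 0:
        raise ValueError(f"mean_twa must be >= 0, got {mean_twa}")
    return work_years * mean_twa


def build_exposure_profiles(workers: pd.DataFrame, mean_twa: pd.DataFrame) -> pd.DataFrame:
    """Per-worker CE and ln-CE for every analyte.

    ``workers`` needs ``worker_id, workplace_id, work_years``.  Returns a
    DataFrame with ``worker_id`` plus ``ce_<analyte>`` and ``ln_ce_<analyte>``
    columns.  CE of exactly zero is impossible under eligibility (work
    years >= 1 and TWA >= LOD/2 > 0) and is asserted here.
    """
    wide = mean_twa.pivot(index="workplace_id", columns="analyte", values="mean_twa")
    missing_wp = set(workers["workplace_id"]) - set(wide.index)
    if missing_wp:
        raise ValueError(f"workplaces without ambient data: {sorted(missing_wp)}")
    out = pd.DataFrame({"worker_id": workers["worker_id"].to_numpy()})
    years = workers["work_years"].to_numpy(dtype=float)
    if (years < 1).any():
        raise ValueError("all workers must have work_years >= 1")
    twa = wide.loc[workers["workplace_id"]]
    for analyte in twa.columns:
        ce = years * twa[analyte].to_numpy(dtype=float)
        if (ce <= 0).any():
            raise ValueError(f"non-positive CE encountered for analyte {analyte!r}")
        out[f"ce_{analyte}"] = ce
        out[f"ln_ce_{analyte}"] = np.log(ce)
    return out


def quantile_score(values, q: int = 4) -> np.ndarray:
    """Score values into ``q`` empirical quantile groups (0 .. q-1).

    Cut-points are linear-interpolation empirical quantiles at i/q for
    i = 1..q-1.  A value exactly equal to a cut-point goes to the lower
    group, so ties always share a score; the scoring is invariant under
    strictly increasing transforms of the input.
    """
    x = np.asarray(values, dtype=float)
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    if x.size < q:
        raise ValueError(f"need at least q={q} values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("quantile scores undefined for a constant vector")
    cuts = np.quantile(x, np.arange(1, q) / q, method="linear")
    # score = number of cut-points strictly below the value
    return (x[:, None] > cuts[None, :]).sum(axis=1).astype(int)


def quantile_cutpoints(values, q: int = 4) -> np.ndarray:
    """The cut-points used by :func:`quantile_score` (for scoring new data)."""
    x = np.asarray(values, dtype=float)
    if q < 2 or x.size < q or np.ptp(x) == 0:
        raise ValueError("invalid input for quantile cut-points")
    return np.quantile(x, np.arange(1, q) / q, method="linear")


def score_with_cutpoints(values, cuts: np.ndarray) -> np.ndarray:
    """Score values against previously computed cut-points (ties go low)."""
    x = np.asarray(values, dtype=float)
    return (x[:, None] > np.asarray(cuts)[None, :]).sum(axis=1).astype(int)


def assign_dose_groups(
    ce,
    cases,
    analyte: str = "",
    n_groups: int = 8,
    min_n: int = 70,
    max_n: int = 200,
) -> list[DoseGroup]:
    """Partition workers into contiguous CE dose groups.

    Workers are sorted by CE and split into ``n_groups`` equal-frequency
    groups; tied CE values never straddle a boundary.  Each group's dose is
    its median CE.  Group sizes should fall in ``[min_n, max_n]``; when the
    cohort size makes that infeasible the equal-frequency split is kept and
    a warning is logged.
    """
    ce = np.asarray(ce, dtype=float)
    cases_arr = np.asarray(cases, dtype=int)
    if n_groups < 2:
        raise ValueError(f"n_groups must be >= 2, got {n_groups}")
    if ce.shape != cases_arr.shape:
        raise ValueError("ce and cases must have the same length")
    n = ce.size
    base = n / n_groups
    if not (min_n <= base <= max_n):
        logger.warning(
            "equal-frequency group size %.1f outside [%d, %d] for n=%d, n_groups=%d; "
            "falling back to plain equal-frequency groups",
            base,
            min_n,
            max_n,
            n,
            n_groups,
        )
    order = np.argsort(ce, kind="stable")
    ce_sorted = ce[order]
    cases_sorted = cases_arr[order]
    # nominal equal-frequency boundaries, then push each forward past ties
    bounds = [round(i * n / n_groups) for i in range(1, n_groups)]
    adj: list[int] = []
    prev = 0
    for b in bounds:
        while b < n and ce_sorted[b] == ce_sorted[b - 1]:
            b += 1
        if b <= prev or b >= n:
            continue
        adj.append(b)
        prev = b
    edges = [0, *adj, n]
    groups: list[DoseGroup] = []
    for gi in range(len(edges) - 1):
        lo, hi = edges[gi], edges[gi + 1]
        chunk = ce_sorted[lo:hi]
        groups.append(
            DoseGroup(
                analyte=analyte,
                index=gi,
                low=float(chunk[0]),
                high=float(ce_sorted[hi] if hi < n else chunk[-1]),
                dose=float(np.median(chunk)),
                n=hi - lo,
                cases=int(cases_sorted[lo:hi].sum()),
            )
        )
    return groups


def dose_groups_frame(groups: list[DoseGroup]) -> pd.DataFrame:
    """Tabular view of a dose-group list (one row per group)."""
    return pd.DataFrame(
        {
            "analyte": [g.analyte for g in groups],
            "group": [g.index for g in groups],
            "ce_low": [g.low for g in groups],
            "ce_high": [g.high for g in groups],
            "dose": [g.dose for g in groups],
            "n": [g.n for g in groups],
            "cases": [g.cases for g in groups],
        }
    )
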