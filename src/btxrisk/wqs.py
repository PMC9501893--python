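"""Generalized weighted-quantile-sum (WQS) regression for a 3-component mixture.

The WQS index collapses correlated, quantile-scored exposures into a single
weighted sum, ``index_i = sum_j w_j q_ij`` with weights on the simplex
(w_j >= 0, sum w_j = 1).  Weights are estimated on a training split by
bootstrap stability selection: for each of B bootstrap resamples the
Gaussian likelihood of ``outcome ~ beta * index + covariates`` is maximized
over the simplex (softmax reparameterization, multi-start), and the
converged weight vectors are aggregated.  The aggregated index is then
scored on the held-out validation split and its per-quartile effect
estimated by covariate-adjusted OLS.

The outcome family is pluggable; the Gaussian family (continuous declines)
is the one shipped and the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WQSFit:
    """Validated WQS regression result for one outcome."""

    outcome: str
    components: tuple[str, ...]
    weights: np.ndarray
    beta: float
    ci95: tuple[float, float]
    p_trend: float
    n_bootstrap: int
    n_converged: int
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must be on the simplex, got {w}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def split_train_validation(ids, train_fraction: float = 0.4, seed: int = 0):
    """Random disjoint, exhaustive train/validation split of worker ids.

    The training set has floor(train_fraction * n) members; determinism is
    guaranteed by the seed.
    """
    if not (0 < train_fraction < 1):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    ids = np.asarray(ids)
    if ids.size < 10:
        raise ValueError(f"need at least 10 ids to split, got {ids.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    n_train = int(np.floor(train_fraction * ids.size))
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]


def _design(covariates: np.ndarray | None, index: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(index), index]
    if covariates is not None and covariates.size:
        cols.append(np.asarray(covariates, dtype=float))
    return np.column_stack(cols)


def _profile_sse(theta: np.ndarray, scores: np.ndarray, y: np.ndarray, cov: np.ndarray | None) -> float:
    """Residual SSE after OLS on the index implied by softmax weights.

    Maximizing the Gaussian likelihood over (beta, covariate coefficients,
    sigma) for fixed weights is equivalent to minimizing this SSE.
    """
    w = _softmax(theta)
    X = _design(cov, scores @ w)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = np.exp(theta - theta.max())
    return z / z.sum()


def fit_bootstrap_weights(
    scores: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    n_starts: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap stability selection of simplex weights on the training split.

    For each resample the profiled Gaussian likelihood is maximized over the
    weight simplex via a softmax reparameterization with ``n_starts`` seeded
    Nelder-Mead starts.  Returns the (B_converged, k) weight matrix and the
    per-replicate index t statistics (used by the optional magnitude-weighted
    aggregation).  Replicates whose optimizer fails are dropped with a
    warning; more than 50% failures is an error.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    n, k = scores.shape
    rng = np.random.default_rng(seed)
    weights, tstats = [], []
    failures = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        sb, yb = scores[idx], y[idx]
        cb = None if covariates is None else np.asarray(covariates, dtype=float)[idx]
        best = None
        for _ in range(n_starts):
            theta0 = rng.normal(0, 1, size=k)
            res = optimize.minimize(
                _profile_sse, theta0, args=(sb, yb, cb), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            failures += 1
            logger.warning("bootstrap replicate dropped: optimizer failure")
            continue
        w = _softmax(best.x)
        X = _design(cb, sb @ w)
        ols = sm.OLS(yb, X).fit()
        weights.append(w)
        tstats.append(float(ols.tvalues[1]))
    if failures > n_bootstrap / 2:
        raise RuntimeError(f"{failures}/{n_bootstrap} bootstrap replicates failed")
    return np.array(weights), np.array(tstats)


def aggregate_weights(
    weight_vectors: np.ndarray,
    tstats: np.ndarray | None = None,
    mode: str = "mean",
) -> np.ndarray:
    """Aggregate bootstrap weight vectors to a single simplex point.

    ``mode='mean'`` is the plain arithmetic mean over converged replicates;
    ``mode='tstat'`` weights each replicate by the magnitude of its index
    t statistic, emphasizing replicates where the index carried signal.
    """
    W = np.asarray(weight_vectors, dtype=float)
    if W.ndim != 2 or W.shape[0] < 1:
        raise ValueError("need at least one bootstrap weight vector")
    if mode == "mean":
        w = W.mean(axis=0)
    elif mode == "tstat":
        if tstats is None:
            raise ValueError("tstat aggregation requires the bootstrap t statistics")
        m = np.abs(np.asarray(tstats, dtype=float))
        if m.sum() == 0:
            w = W.mean(axis=0)
        else:
            w = (W * (m / m.sum())[:, None]).sum(axis=0)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return w / w.sum()


def finalize_wqs(
    weight_vectors: np.ndarray,
    validation_scores: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    tstats: np.ndarray | None = None,
    aggregation: str = "mean",
    outcome_name: str = "",
    components: tuple[str, ...] = ("benzene", "toluene", "xylene"),
    train_fraction: float = 0.4,
    seed: int = 0,
) -> WQSFit:
    """Score the aggregated index on the validation split and estimate its effect.

    Fits covariate-adjusted OLS of the outcome on the index; beta is the
    change in outcome per one-quartile increase of the weighted index.
    """
    if np.asarray(validation_scores).shape[0] == 0:
        raise ValueError("validation set is empty")
    w = aggregate_weights(weight_vectors, tstats, aggregation)
    X = _design(None if covariates is None else np.asarray(covariates, dtype=float),
                np.asarray(validation_scores, dtype=float) @ w)
    ols = sm.OLS(np.asarray(outcome, dtype=float), X).fit()
    ci = ols.conf_int()[1]
    return WQSFit(
        outcome=outcome_name,
        components=components,
        weights=w,
        beta=float(ols.params[1]),
        ci95=(float(ci[0]), float(ci[1])),
        p_trend=float(ols.pvalues[1]),
        n_bootstrap=int(np.asarray(weight_vectors).shape[0]),
        n_converged=int(np.asarray(weight_vectors).shape[0]),
        train_fraction=train_fraction,
        seed=seed,
    )


def run_wqs(
    scores: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    n_bootstrap: int = 100,
    train_fraction: float = 0.4,
    seed: int = 0,
    aggregation: str = "mean",
    outcome_name: str = "",
    components: tuple[str, ...] = ("benzene", "toluene", "xylene"),
) -> WQSFit:
    """End-to-end WQS: split, bootstrap weights on train, validate on holdout."""
    n = np.asarray(scores).shape[0]
    train, valid = split_train_validation(np.arange(n), train_fraction, seed)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    W, t = fit_bootstrap_weights(
        np.asarray(scores, dtype=float)[train],
        np.asarray(outcome, dtype=float)[train],
        None if cov is None else cov[train],
        n_bootstrap=n_bootstrap,
        seed=seed + 1,
    )
    return finalize_wqs(
        W,
        np.asarray(scores, dtype=float)[valid],
        np.asarray(outcome, dtype=float)[valid],
        None if cov is None else cov[valid],
        tstats=t,
        aggregation=aggregation,
        outcome_name=outcome_name,
        components=components,
        train_fraction=train_fraction,
        seed=seed,
    )
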