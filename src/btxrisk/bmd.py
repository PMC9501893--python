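"""Dichotomous benchmark-dose estimation.

Implements the standard suite of eight dichotomous dose-response families
(Logistic, Probit, Log-Logistic, Log-Probit, Multistage degree 1 and 2,
Weibull, Gamma, Dichotomous Hill), binomial maximum likelihood on grouped
dose data, Pearson chi-squared goodness of fit, EPA-style model selection,
extra-risk benchmark doses, one-sided 95% profile-likelihood BMDLs, and
derivation of 8h-TWA reference exposure levels from a BMDL and a working
duration.

Conventions
-----------
All families expose a background probability ``P(0)`` and are parameterized
so that ``P(d)`` stays in [0, 1] for every admissible parameter vector.
Extra risk is ``(P(d) - P(0)) / (1 - P(0))``; the BMD is the dose at which
extra risk equals the benchmark response (BMR, default 0.10).  The BMDL is
the smallest BMD value whose profile log-likelihood lies within
``chi2_1(0.90)/2 = 1.352771`` of the unconstrained maximum — the one-sided
95% profile bound.  Parameter bounds follow common dichotomous-suite
conventions: background in [0, 1]; the plateau ``v`` of the Dichotomous
Hill in (0, 1]; slopes of log-dose families and Multistage stage
coefficients are non-negative (which enforces monotonicity); Logistic and
Probit slopes are unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special, stats

from .exposure import DoseGroup

logger = logging.getLogger(__name__)

#: chi2_1(0.90)/2 — profile-likelihood drop for a one-sided 95% bound
PROFILE_CUTOFF = float(stats.chi2.ppf(0.90, df=1) / 2.0)

_PCLIP = 1e-12
_SLOPE_MAX = 1e4
_AB_MAX = 60.0

FAMILIES = (
    "logistic",
    "probit",
    "log_logistic",
    "log_probit",
    "multistage1",
    "multistage2",
    "weibull",
    "gamma",
    "dichotomous_hill",
)

#: molecular weights (g/mol) and the default molar volume (L/mol at 25 C, 1 atm)
MOLECULAR_WEIGHTS = {"benzene": 78.11, "toluene": 92.14, "xylene": 106.17}
MOLAR_VOLUME_25C = 24.45


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted dichotomous dose-response model on grouped data."""

    family: str
    params: tuple[float, ...]
    loglik: float
    k: int
    aic: float
    converged: bool
    bmr: float | None = None
    bmd: float | None = None
    bmdl: float | None = None
    gof_chi2: float | None = None
    gof_df: int | None = None
    gof_p: float | None = None

    def prob(self, dose) -> np.ndarray:
        return response_probability(self.family, self.params, dose)


@dataclass(frozen=True)
class RelResult:
    """An 8h-TWA reference exposure level derived from a BMDL."""

    analyte: str
    bmdl: float
    working_years: float
    rel_mgm3: float
    rel_ppm: float | None
    molar_volume: float | None


# ---------------------------------------------------------------------------
# family definitions
# ---------------------------------------------------------------------------

def _param_spec(family: str) -> list[tuple[str, float, float]]:
    """(name, low, high) for each parameter of a family, in natural space."""
    g = ("background", 0.0, 1.0)
    if family == "logistic":
        return [("intercept", -_AB_MAX, _AB_MAX), ("slope", -_SLOPE_MAX, _SLOPE_MAX)]
    if family == "probit":
        return [("intercept", -_AB_MAX, _AB_MAX), ("slope", -_SLOPE_MAX, _SLOPE_MAX)]
    if family == "log_logistic":
        return [g, ("intercept", -_AB_MAX, _AB_MAX), ("slope", 0.0, 20.0)]
    if family == "log_probit":
        return [g, ("intercept", -_AB_MAX, _AB_MAX), ("slope", 0.0, 20.0)]
    if family == "multistage1":
        return [g, ("slope1", 0.0, _SLOPE_MAX)]
    if family == "multistage2":
        return [g, ("slope1", 0.0, _SLOPE_MAX), ("slope2", 0.0, _SLOPE_MAX)]
    if family == "weibull":
        return [g, ("power", 1e-6, 20.0), ("rate", 0.0, _SLOPE_MAX)]
    if family == "gamma":
        return [g, ("shape", 0.2, 20.0), ("rate", 0.0, _SLOPE_MAX)]
    if family == "dichotomous_hill":
        return [g, ("v", 1e-6, 1.0), ("intercept", -_AB_MAX, _AB_MAX), ("slope", 0.0, 20.0)]
    raise ValueError(f"unknown family {family!r}; choose one of {FAMILIES}")


def n_params(family: str) -> int:
    return len(_param_spec(family))


def _check_params(family: str, params) -> np.ndarray:
    spec = _param_spec(family)
    p = np.asarray(params, dtype=float)
    if p.shape != (len(spec),):
        raise ValueError(f"{family} expects {len(spec)} parameters {[s[0] for s in spec]}, got {p.shape}")
    for (name, lo, hi), val in zip(spec, p):
        if not (lo <= val <= hi):
            raise ValueError(f"{family} parameter {name}={val} outside bound [{lo}, {hi}]")
    return p


def response_probability(family: str, params, dose) -> np.ndarray:
    """P(response | dose) for one of the dichotomous families.

    Dose 0 is handled by the continuous limit for log-dose families
    (P(0) = background).
    """
    p = _check_params(family, params)
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    with np.errstate(divide="ignore", over="ignore"):
        if family == "logistic":
            a, b = p
            out = special.expit(a + b * d)
        elif family == "probit":
            a, b = p
            out = stats.norm.cdf(a + b * d)
        elif family == "log_logistic":
            g, a, b = p
            frac = np.where(d > 0, special.expit(a + b * np.log(np.where(d > 0, d, 1.0))), 0.0)
            out = g + (1 - g) * frac
        elif family == "log_probit":
            g, a, b = p
            frac = np.where(d > 0, stats.norm.cdf(a + b * np.log(np.where(d > 0, d, 1.0))), 0.0)
            out = g + (1 - g) * frac
        elif family == "multistage1":
            g, b1 = p
            out = g + (1 - g) * (1 - np.exp(-b1 * d))
        elif family == "multistage2":
            g, b1, b2 = p
            out = g + (1 - g) * (1 - np.exp(-(b1 * d + b2 * d * d)))
        elif family == "weibull":
            g, a, b = p
            out = g + (1 - g) * (1 - np.exp(-b * np.power(d, a)))
        elif family == "gamma":
            g, a, b = p
            out = g + (1 - g) * special.gammainc(a, b * d)
        elif family == "dichotomous_hill":
            g, v, a, b = p
            frac = np.where(d > 0, special.expit(a + b * np.log(np.where(d > 0, d, 1.0))), 0.0)
            out = g + v * (1 - g) * frac
        else:  # pragma: no cover - guarded by _check_params
            raise ValueError(family)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

def _binom_loglik(family: str, params, doses, n, cases) -> float:
    pr = np.clip(response_probability(family, params, doses), _PCLIP, 1 - _PCLIP)
    return float(np.sum(cases * np.log(pr) + (n - cases) * np.log1p(-pr)))


def _initial_guesses(family: str, doses, n, cases, rng, n_starts: int) -> list[np.ndarray]:
    """Heuristic start plus seeded perturbations, all within bounds."""
    spec = _param_spec(family)
    inc = np.clip(cases / n, 1e-3, 1 - 1e-3)
    g0 = float(inc[np.argmin(doses)])
    dmax = float(np.max(doses))
    # crude slope scale: rise over the dose range
    rise = float(np.clip(inc[np.argmax(doses)] - g0, 1e-3, 0.98))
    base: dict[str, float] = {
        "background": min(g0, 0.9),
        "v": 0.9,
        "intercept": 0.0,
        "slope": 1.0 / max(dmax, 1e-6),
        "slope1": -np.log1p(-rise) / max(dmax, 1e-6),
        "slope2": 1e-3 / max(dmax, 1e-6) ** 2,
        "power": 1.0,
        "shape": 1.0,
        "rate": -np.log1p(-rise) / max(dmax, 1e-6),
    }
    if family in ("logistic", "probit"):
        base["intercept"] = float(special.logit(g0))
        base["slope"] = float((special.logit(inc[np.argmax(doses)]) - special.logit(g0)) / max(dmax, 1e-6))
    if family in ("log_logistic", "log_probit", "dichotomous_hill"):
        base["slope"] = 1.0
        base["intercept"] = -np.log(max(np.median(doses), 1e-6))
    starts = []
    x0 = np.array([np.clip(base[name], lo, hi) for name, lo, hi in spec])
    starts.append(x0)
    for _ in range(n_starts - 1):
        pert = x0 * np.exp(rng.normal(0, 0.7, size=x0.size)) + rng.normal(0, 0.3, size=x0.size)
        starts.append(np.array([np.clip(v, lo, hi) for v, (_, lo, hi) in zip(pert, spec)]))
    return starts


def fit_dichotomous(
    groups: list[DoseGroup],
    family: str,
    n_starts: int = 10,
    seed: int = 0,
) -> DoseResponseFit:
    """Binomial maximum-likelihood fit of one family to grouped dose data.

    Runs a bounded quasi-Newton optimizer from ``n_starts`` seeded starting
    points and keeps the best converged solution (convergence tolerance
    1e-10 on the log-likelihood).  Boundary solutions (e.g. background
    driven to 0 when no group has cases) are legitimate and returned with
    ``converged=True``.
    """
    if len(groups) < 3:
        raise ValueError(f"need >= 3 dose groups, got {len(groups)}")
    doses = np.array([g.dose for g in groups], dtype=float)
    if np.unique(doses).size != doses.size:
        raise ValueError("group doses must be distinct")
    n = np.array([g.n for g in groups], dtype=float)
    cases = np.array([g.cases for g in groups], dtype=float)
    spec = _param_spec(family)
    bounds = [(lo, hi) for _, lo, hi in spec]
    rng = np.random.default_rng(seed)

    def neg(x):
        return -_binom_loglik(family, x, doses, n, cases)

    best = None
    any_ok = False
    for x0 in _initial_guesses(family, doses, n, cases, rng, n_starts):
        try:
            res = optimize.minimize(
                neg, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-10, "maxiter": 2000},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or bool(res.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"{family}: optimizer failed from every start")
    if not any_ok:
        logger.warning("%s: no start reported clean convergence; best objective %.6g", family, best.fun)
    k = len(spec)
    ll = -float(best.fun)
    fit = DoseResponseFit(
        family=family,
        params=tuple(float(v) for v in best.x),
        loglik=ll,
        k=k,
        aic=2 * k - 2 * ll,
        converged=any_ok,
    )
    return fit


# ---------------------------------------------------------------------------
# extra risk, BMD, goodness of fit
# ---------------------------------------------------------------------------

def extra_risk(fit: DoseResponseFit, dose) -> float | np.ndarray:
    """Extra risk (P(d) - P(0)) / (1 - P(0)) under a fitted model."""
    p0 = response_probability(fit.family, fit.params, 0.0)
    if p0 >= 1.0:
        raise ValueError("background probability is 1; extra risk undefined")
    pd_ = response_probability(fit.family, fit.params, dose)
    return (pd_ - p0) / (1.0 - p0)


def _bmd_closed_form(family: str, params, bmr: float) -> float | None:
    """Closed-form BMD where the family admits one; None otherwise."""
    p = np.asarray(params, dtype=float)
    A = -np.log1p(-bmr)
    if family == "multistage1":
        g, b1 = p
        return A / b1 if b1 > 0 else np.inf
    if family == "multistage2":
        g, b1, b2 = p
        if b1 <= 0 and b2 <= 0:
            return np.inf
        if b2 <= 0:
            return A / b1
        return (-b1 + np.sqrt(b1 * b1 + 4 * b2 * A)) / (2 * b2)
    if family == "weibull":
        g, a, b = p
        return (A / b) ** (1.0 / a) if b > 0 else np.inf
    if family == "gamma":
        g, a, b = p
        return float(special.gammaincinv(a, bmr)) / b if b > 0 else np.inf
    if family == "log_logistic":
        g, a, b = p
        if b <= 0:
            return np.inf
        return float(np.exp((special.logit(bmr) - a) / b))
    if family == "log_probit":
        g, a, b = p
        if b <= 0:
            return np.inf
        return float(np.exp((stats.norm.ppf(bmr) - a) / b))
    if family == "dichotomous_hill":
        g, v, a, b = p
        if bmr >= v:
            raise ValueError(f"BMR unreachable: plateau v={v} <= bmr={bmr}")
        if b <= 0:
            return np.inf
        return float(np.exp((special.logit(bmr / v) - a) / b))
    return None


def solve_bmd(fit: DoseResponseFit, bmr: float = 0.10) -> float:
    """Dose at which extra risk equals ``bmr``.

    Uses the family's closed form when available, otherwise bracketed
    root-finding to 1e-8 relative tolerance.  Raises when the model's
    response plateau never reaches the BMR.
    """
    if not (0 < bmr < 1):
        raise ValueError(f"bmr must be in (0, 1), got {bmr}")
    closed = _bmd_closed_form(fit.family, fit.params, bmr)
    if closed is not None:
        if not np.isfinite(closed):
            raise ValueError(f"{fit.family}: flat dose-response, BMR {bmr} unreachable")
        return float(closed)
    # logistic / probit: monotone in dose iff slope > 0
    f = lambda d: float(extra_risk(fit, d)) - bmr
    hi = 1.0
    if f(hi) * f(1e-12) > 0:
        for _ in range(200):
            hi *= 2.0
            if f(hi) > 0 or hi > 1e12:
                break
        if f(hi) <= 0:
            raise ValueError(f"{fit.family}: BMR {bmr} unreachable (extra risk plateaus below it)")
    return float(optimize.brentq(f, 1e-12, hi, rtol=1e-8))


def goodness_of_fit(fit: DoseResponseFit, groups: list[DoseGroup]) -> tuple[float, int, float]:
    """Pearson chi-squared GOF: sum (cases - nP)^2 / [nP(1-P)], df = groups - k."""
    doses = np.array([g.dose for g in groups], dtype=float)
    n = np.array([g.n for g in groups], dtype=float)
    cases = np.array([g.cases for g in groups], dtype=float)
    phat = response_probability(fit.family, fit.params, doses)
    if np.any((phat <= 0) | (phat >= 1)):
        logger.info("%s: fitted probability at 0 or 1 in a group; continuity guard applied", fit.family)
        phat = np.clip(phat, 0.5 / n.max(), 1 - 0.5 / n.max())
    chi2 = float(np.sum((cases - n * phat) ** 2 / (n * phat * (1 - phat))))
    df = len(groups) - fit.k
    if df < 1:
        raise ValueError(f"gof df = {df} < 1 (need more groups than parameters)")
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# profile-likelihood BMDL
# ---------------------------------------------------------------------------

def _profiled_prob(family: str, bmd: float, bmr: float, phi: np.ndarray, doses: np.ndarray) -> np.ndarray:
    """P(dose) with the family reparameterized so its BMD is exactly ``bmd``.

    ``phi`` holds the remaining free parameters; the slope-like parameter is
    reconstructed from (bmd, bmr, phi) in closed form.
    """
    A = -np.log1p(-bmr)
    if family == "multistage1":
        (g,) = phi
        return response_probability(family, (g, A / bmd), doses)
    if family == "multistage2":
        g, t = phi  # t in [0,1]: fraction of A carried by the quadratic stage
        b2 = t * A / bmd**2
        b1 = (A - b2 * bmd**2) / bmd
        return response_probability(family, (g, max(b1, 0.0), b2), doses)
    if family == "weibull":
        g, a = phi
        return response_probability(family, (g, a, A / bmd**a), doses)
    if family == "gamma":
        g, a = phi
        return response_probability(family, (g, a, float(special.gammaincinv(a, bmr)) / bmd), doses)
    if family == "log_logistic":
        g, b = phi
        return response_probability(family, (g, float(special.logit(bmr)) - b * np.log(bmd), b), doses)
    if family == "log_probit":
        g, b = phi
        return response_probability(family, (g, float(stats.norm.ppf(bmr)) - b * np.log(bmd), b), doses)
    if family == "logistic":
        (a,) = phi
        p0 = special.expit(a)
        b = (special.logit(p0 + bmr * (1 - p0)) - a) / bmd
        return response_probability(family, (a, b), doses)
    if family == "probit":
        (a,) = phi
        p0 = stats.norm.cdf(a)
        b = (stats.norm.ppf(p0 + bmr * (1 - p0)) - a) / bmd
        return response_probability(family, (a, b), doses)
    if family == "dichotomous_hill":
        g, v, b = phi
        a = float(special.logit(bmr / v)) - b * np.log(bmd)
        a = float(np.clip(a, -_AB_MAX, _AB_MAX))
        return response_probability(family, (g, v, a, b), doses)
    raise ValueError(f"profile reparameterization not defined for {family!r}")


def _profile_free_spec(family: str, bmr: float) -> list[tuple[str, float, float]]:
    spec = {name: (lo, hi) for name, lo, hi in _param_spec(family)}
    if family == "multistage1":
        names = ["background"]
    elif family == "multistage2":
        return [("background", 0.0, 1.0), ("quad_fraction", 0.0, 1.0)]
    elif family in ("weibull",):
        names = ["background", "power"]
    elif family in ("gamma",):
        names = ["background", "shape"]
    elif family in ("log_logistic", "log_probit"):
        names = ["background", "slope"]
    elif family in ("logistic", "probit"):
        names = ["intercept"]
    elif family == "dichotomous_hill":
        return [
            ("background", 0.0, 1.0),
            ("v", bmr + 1e-6, 1.0),
            ("slope", 1e-6, 20.0),
        ]
    else:
        raise ValueError(family)
    out = []
    for nm in names:
        lo, hi = spec[nm]
        if nm == "slope":
            lo = max(lo, 1e-6)
        out.append((nm, lo, hi))
    return out


def _free_params_from_fit(family: str, fit_params: tuple, bmr: float) -> np.ndarray:
    p = np.asarray(fit_params, dtype=float)
    if family == "multistage1":
        return p[:1]
    if family == "multistage2":
        g, b1, b2 = p
        bmd = _bmd_closed_form(family, p, bmr)
        A = -np.log1p(-bmr)
        t = 0.0 if not np.isfinite(bmd) else float(np.clip(b2 * bmd**2 / A, 0.0, 1.0))
        return np.array([g, t])
    if family in ("weibull", "gamma"):
        return p[:2]
    if family in ("log_logistic", "log_probit"):
        return np.array([p[0], max(p[2], 1e-6)])
    if family in ("logistic", "probit"):
        return p[:1]
    if family == "dichotomous_hill":
        g, v, a, b = p
        return np.array([g, max(v, bmr + 1e-6), max(b, 1e-6)])
    raise ValueError(family)


def _profile_loglik(family, bmd, bmr, doses, n, cases, phi0, bounds) -> float:
    def neg(phi):
        pr = np.clip(_profiled_prob(family, bmd, bmr, phi, doses), _PCLIP, 1 - _PCLIP)
        return -float(np.sum(cases * np.log(pr) + (n - cases) * np.log1p(-pr)))

    best = np.inf
    starts = [phi0]
    mid = np.array([(lo + hi) / 2 if np.isfinite(hi) else lo + 1 for lo, hi in bounds])
    starts.append(mid)
    starts.append(0.5 * (phi0 + mid))
    for x0 in starts:
        x0 = np.array([np.clip(v, lo, hi) for v, (lo, hi) in zip(x0, bounds)])
        try:
            res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": 1e-12, "maxiter": 1000})
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        best = min(best, float(res.fun))
    if not np.isfinite(best):
        raise RuntimeError(f"{family}: constrained optimizer failed at BMD={bmd}")
    return -best


def profile_bmdl(
    fit: DoseResponseFit,
    groups: list[DoseGroup],
    bmr: float = 0.10,
    confidence: float = 0.95,
) -> float:
    """One-sided profile-likelihood lower confidence bound on the BMD.

    Finds the smallest ``b`` such that the log-likelihood maximized subject
    to BMD = ``b`` stays within ``chi2_1(2*confidence - 1)/2`` of the
    unconstrained maximum (1.352771 at 95%), by bisection/Brent on the
    profile deviance.
    """
    cutoff = float(stats.chi2.ppf(2 * confidence - 1, df=1) / 2.0)
    bmd = solve_bmd(fit, bmr)
    doses = np.array([g.dose for g in groups], dtype=float)
    n = np.array([g.n for g in groups], dtype=float)
    cases = np.array([g.cases for g in groups], dtype=float)
    bounds = [(lo, hi) for _, lo, hi in _profile_free_spec(fit.family, bmr)]
    phi0 = _free_params_from_fit(fit.family, fit.params, bmr)
    ll_hat = fit.loglik
    target = ll_hat - cutoff

    def margin(b):
        return _profile_loglik(fit.family, b, bmr, doses, n, cases, phi0, bounds) - target

    # walk down geometrically until the profile falls below the cutoff
    lo = bmd
    m_lo = margin(lo)
    if m_lo < 0:
        # numerical slack: the profile at the MLE BMD should be ~cutoff above target
        logger.warning("%s: profile at BMD already below cutoff (margin %.3g)", fit.family, m_lo)
        return float(bmd)
    hi_b = bmd
    b = bmd
    for _ in range(60):
        b *= 0.7
        m = margin(b)
        if m < 0:
            return float(optimize.brentq(margin, b, hi_b, rtol=1e-6, xtol=1e-12))
        hi_b = b
    logger.warning("%s: profile never crossed the cutoff down to BMD*%.1e; data carry little information",
                   fit.family, (0.7 ** 60))
    return float(b)


# ---------------------------------------------------------------------------
# suite orchestration
# ---------------------------------------------------------------------------

def fit_with_diagnostics(
    groups: list[DoseGroup],
    family: str,
    bmr: float = 0.10,
    confidence: float = 0.95,
    seed: int = 0,
) -> DoseResponseFit:
    """Fit one family and attach GOF, BMD and profile BMDL."""
    fit = fit_dichotomous(groups, family, seed=seed)
    chi2, df, p = goodness_of_fit(fit, groups)
    try:
        bmd = solve_bmd(fit, bmr)
        bmdl = profile_bmdl(replace(fit, gof_chi2=chi2, gof_df=df, gof_p=p), groups, bmr, confidence)
    except (ValueError, RuntimeError) as exc:
        logger.info("%s: BMD unavailable (%s)", family, exc)
        bmd = bmdl = None
    return replace(fit, bmr=bmr, bmd=bmd, bmdl=bmdl, gof_chi2=chi2, gof_df=df, gof_p=p)


def fit_suite(
    groups: list[DoseGroup],
    families: tuple[str, ...] = FAMILIES,
    bmr: float = 0.10,
    confidence: float = 0.95,
    seed: int = 0,
) -> list[DoseResponseFit]:
    """Fit every family in the dichotomous suite to one dose-group table."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_with_diagnostics(groups, fam, bmr, confidence, seed=seed))
        except (ValueError, RuntimeError) as exc:
            logger.warning("%s: fit failed (%s)", fam, exc)
    return fits


def select_best(fits: list[DoseResponseFit], groups: list[DoseGroup]) -> DoseResponseFit | None:
    """EPA-style model selection.

    Keep fits with GOF p > 0.1, BMD no higher than the maximum group dose,
    and BMD/BMDL < 3; among the survivors return the lowest-AIC fit.
    Returns None ("no adequate model") when nothing survives.
    """
    if not fits:
        raise ValueError("no fits supplied")
    max_dose = max(g.dose for g in groups)
    ok = [
        f
        for f in fits
        if f.gof_p is not None
        and f.gof_p > 0.1
        and f.bmd is not None
        and f.bmdl is not None
        and f.bmd <= max_dose
        and f.bmdl > 0
        and f.bmd / f.bmdl < 3
    ]
    if not ok:
        return None
    return min(ok, key=lambda f: f.aic)


def derive_rel(
    bmdl: float,
    analyte: str | None = None,
    working_years: float = 40.0,
    molecular_weight: float | None = None,
    molar_volume: float | None = MOLAR_VOLUME_25C,
) -> RelResult:
    """8h-TWA reference exposure level from a BMDL point of departure.

    ``rel_mgm3 = bmdl / working_years`` (the BMDL is a cumulative exposure
    in mg/m3 x year; 40 years is a full working life).  The ppm conversion
    uses ``rel_ppm = rel_mgm3 * molar_volume / molecular_weight`` with the
    25 C, 1 atm molar volume of 24.45 L/mol by default; pass
    ``molar_volume=None`` to skip it.
    """
    if bmdl <= 0 or working_years <= 0:
        raise ValueError("bmdl and working_years must be positive")
    rel = bmdl / working_years
    mw = molecular_weight
    if mw is None and analyte is not None:
        mw = MOLECULAR_WEIGHTS.get(analyte)
    ppm = None
    if mw is not None and molar_volume is not None:
        ppm = rel * molar_volume / mw
    return RelResult(
        analyte=analyte or "",
        bmdl=float(bmdl),
        working_years=float(working_years),
        rel_mgm3=float(rel),
        rel_ppm=None if ppm is None else float(ppm),
        molar_volume=molar_volume,
    )
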