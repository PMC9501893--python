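"""Benchmark-dose suite: response families, binomial MLE, extra risk,
BMD closed forms, profile-likelihood BMDLs, GOF and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from btxrisk import bmd
from btxrisk.bmd import DoseResponseFit
from conftest import make_groups


def _fit(family, params):
    k = len(params)
    return DoseResponseFit(family=family, params=tuple(params), loglik=0.0, k=k, aic=0.0, converged=True)


#: one admissible parameter-vector strategy per family
_PARAM_STRATEGIES = {
    "logistic": st.tuples(st.floats(-4, 1), st.floats(0.1, 4)),
    "probit": st.tuples(st.floats(-3, 1), st.floats(0.1, 3)),
    "log_logistic": st.tuples(st.floats(0, 0.5), st.floats(-3, 3), st.floats(0.3, 5)),
    "log_probit": st.tuples(st.floats(0, 0.5), st.floats(-2, 2), st.floats(0.3, 4)),
    "multistage1": st.tuples(st.floats(0, 0.5), st.floats(0.01, 5)),
    "multistage2": st.tuples(st.floats(0, 0.5), st.floats(0.0, 3), st.floats(0.01, 3)),
    "weibull": st.tuples(st.floats(0, 0.5), st.floats(0.3, 4), st.floats(0.01, 5)),
    "gamma": st.tuples(st.floats(0, 0.5), st.floats(0.3, 5), st.floats(0.01, 5)),
    "dichotomous_hill": st.tuples(st.floats(0, 0.4), st.floats(0.3, 1), st.floats(-2, 2), st.floats(0.3, 4)),
}


class TestResponseProbability:
    def test_multistage_zero_slopes_is_background(self):
        for g in (0.0, 0.2, 0.9):
            assert bmd.response_probability("multistage1", (g, 0.0), 3.7) == pytest.approx(g)

    def test_probit_at_origin(self):
        assert bmd.response_probability("probit", (0.0, 1.0), 0.0) == pytest.approx(0.5)

    def test_hill_at_unit_dose(self):
        # g=0, v=1, intercept=0, slope=1, dose=1: log(1)=0 so P = expit(0) = 0.5
        assert bmd.response_probability("dichotomous_hill", (0.0, 1.0, 0.0, 1.0), 1.0) == pytest.approx(0.5)

    def test_log_dose_families_at_zero_dose_hit_background(self):
        for fam, params in [("log_logistic", (0.1, 0.0, 1.0)),
                            ("log_probit", (0.1, 0.0, 1.0)),
                            ("dichotomous_hill", (0.1, 0.8, 0.0, 1.0))]:
            assert bmd.response_probability(fam, params, 0.0) == pytest.approx(0.1)

    def test_out_of_bounds_params_named(self):
        with pytest.raises(ValueError, match="background"):
            bmd.response_probability("multistage1", (1.5, 1.0), 1.0)
        with pytest.raises(ValueError, match="slope1"):
            bmd.response_probability("multistage1", (0.1, -1.0), 1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.sampled_from(sorted(_PARAM_STRATEGIES)), st.data())
    def test_probabilities_in_unit_interval_and_monotone(self, family, data):
        params = data.draw(_PARAM_STRATEGIES[family])
        doses = np.linspace(0, 50, 201)
        p = bmd.response_probability(family, params, doses)
        assert np.all((p >= 0) & (p <= 1))
        if family not in ("logistic", "probit"):  # those may have negative slope in general
            assert np.all(np.diff(p) >= -1e-12)


class TestExtraRisk:
    def test_zero_dose_gives_zero(self):
        assert bmd.extra_risk(_fit("multistage1", (0.3, 1.0)), 0.0) == pytest.approx(0.0)

    def test_multistage_extra_risk_independent_of_background(self):
        d = 1.7
        er = [bmd.extra_risk(_fit("multistage1", (g, 0.4)), d) for g in (0.0, 0.3, 0.7)]
        assert er == pytest.approx([1 - np.exp(-0.4 * d)] * 3)

    def test_zero_background(self):
        fit = _fit("logistic", (float(special.logit(1e-9)), 1.0))
        # P(0) ~ 0 so extra risk ~ P(d)
        d = 25.0
        assert bmd.extra_risk(fit, d) == pytest.approx(fit.prob(d), abs=1e-6)


class TestSolveBmd:
    def test_one_stage_closed_form(self):
        fit = _fit("multistage1", (0.05, 1.0))
        assert bmd.solve_bmd(fit, 0.10) == pytest.approx(-np.log(0.9), rel=1e-10)

    def test_doubling_slope_halves_bmd(self):
        b1 = bmd.solve_bmd(_fit("multistage1", (0.1, 0.5)), 0.10)
        b2 = bmd.solve_bmd(_fit("multistage1", (0.1, 1.0)), 0.10)
        assert b1 == pytest.approx(2 * b2, rel=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.sampled_from(sorted(_PARAM_STRATEGIES)), st.data())
    def test_round_trip_all_families(self, family, data):
        params = data.draw(_PARAM_STRATEGIES[family])
        fit = _fit(family, params)
        try:
            d = bmd.solve_bmd(fit, 0.10)
        except ValueError:
            return  # BMR unreachable for this draw (flat or low-plateau model)
        assert d > 0
        assert bmd.extra_risk(fit, d) == pytest.approx(0.10, abs=1e-6)

    def test_low_plateau_hill_unreachable(self):
        fit = _fit("dichotomous_hill", (0.0, 0.05, 0.0, 1.0))
        with pytest.raises(ValueError, match="unreachable"):
            bmd.solve_bmd(fit, 0.10)


class TestFit:
    def test_consistency_with_exact_expected_counts(self):
        """Feeding the model's own expected counts at huge n returns fitted
        probabilities within 0.01 of the group incidences."""
        doses = np.array([0.2, 0.5, 1.0, 1.8, 3.0, 4.5, 6.0, 8.0])
        true = (0.08, 0.35)
        probs = bmd.response_probability("multistage1", true, doses)
        groups = make_groups(probs, 100000, doses)
        fit = bmd.fit_dichotomous(groups, "multistage1", seed=0)
        fitted = fit.prob(doses)
        inc = np.array([g.cases / g.n for g in groups])
        assert np.max(np.abs(fitted - inc)) < 0.01

    def test_parameter_recovery_over_replicates(self):
        doses = np.array([0.1, 0.3, 0.6, 1.0, 1.5, 2.2, 3.0, 4.5])
        g, b1 = 0.05, 0.1
        probs = g + (1 - g) * (1 - np.exp(-b1 * doses))
        rng = np.random.default_rng(10)
        est = []
        for _ in range(30):
            groups = make_groups(probs, 200, doses, rng)
            est.append(bmd.fit_dichotomous(groups, "multistage1", seed=0).params[1])
        est = np.array(est)
        assert abs(est.mean() - b1) < 3 * est.std() / np.sqrt(len(est))

    def test_all_zero_cases_drives_background_to_boundary(self):
        doses = [0.5, 1.0, 2.0, 4.0]
        groups = make_groups([0.0] * 4, 50, doses)
        fit = bmd.fit_dichotomous(groups, "multistage1", seed=0)
        assert fit.params[0] < 1e-4

    def test_too_few_groups_is_error(self):
        groups = make_groups([0.1, 0.2], 50, [1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            bmd.fit_dichotomous(groups, "multistage1")

    def test_aic_identity(self, multistage_groups):
        for fam in ("multistage1", "logistic", "gamma"):
            fit = bmd.fit_dichotomous(multistage_groups, fam, seed=0)
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, rel=1e-12)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        doses = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        params = (0.1, 0.2)
        probs = bmd.response_probability("multistage1", params, doses)
        # observed = expected exactly (n chosen so counts are integral)
        groups = make_groups(probs, 100000, doses)
        fit = _fit("multistage1", params)
        chi2, df, p = bmd.goodness_of_fit(fit, groups)
        assert chi2 < 1e-3  # only count-rounding noise
        assert p > 0.99

    def test_df_is_groups_minus_params(self, multistage_groups):
        fit = bmd.fit_dichotomous(multistage_groups, "multistage1", seed=0)
        _, df, _ = bmd.goodness_of_fit(fit, multistage_groups)
        assert df == 8 - 2

    def test_null_p_roughly_uniform(self):
        doses = np.array([0.2, 0.6, 1.2, 2.0, 3.0, 4.5, 6.5, 9.0])
        probs = bmd.response_probability("multistage1", (0.08, 0.15), doses)
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(120):
            groups = make_groups(probs, 150, doses, rng)
            fit = bmd.fit_dichotomous(groups, "multistage1", seed=0)
            ps.append(bmd.goodness_of_fit(fit, groups)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.005


def grid_bmdl_oracle(groups, bmr=0.10, confidence=0.95, n_bmd=400, n_g=200):
    """Brute-force profile BMDL for the one-stage multistage model.

    Dense grid over candidate BMD values and the free background parameter;
    smallest BMD whose grid-maximized log-likelihood stays within the
    chi-square cutoff of the grid MLE.
    """
    doses = np.array([g.dose for g in groups])
    n = np.array([g.n for g in groups], float)
    cases = np.array([g.cases for g in groups], float)
    A = -np.log1p(-bmr)
    gs = np.linspace(1e-6, 0.5, n_g)

    def ll_for_bmd(b):
        b1 = A / b
        p = gs[:, None] + (1 - gs[:, None]) * (1 - np.exp(-b1 * doses[None, :]))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = (cases * np.log(p) + (n - cases) * np.log1p(-p)).sum(axis=1)
        return ll.max()

    bmds = np.linspace(0.05, 10.0, n_bmd)
    lls = np.array([ll_for_bmd(b) for b in bmds])
    cutoff = lls.max() - stats.chi2.ppf(2 * confidence - 1, 1) / 2
    return bmds[lls >= cutoff].min()


class TestProfileBmdl:
    def test_bmdl_below_bmd(self, multistage_groups):
        fit = bmd.fit_with_diagnostics(multistage_groups, "multistage1", seed=0)
        assert fit.bmdl <= fit.bmd

    def test_matches_grid_oracle_within_2pct(self, multistage_groups):
        fit = bmd.fit_with_diagnostics(multistage_groups, "multistage1", seed=0)
        oracle = grid_bmdl_oracle(multistage_groups)
        assert fit.bmdl == pytest.approx(oracle, rel=0.03)

    def test_more_data_narrows_the_interval(self):
        doses = np.array([0.1, 0.3, 0.6, 1.0, 1.5, 2.2, 3.0, 4.5])
        probs = bmd.response_probability("multistage1", (0.05, 0.1), doses)
        widths = []
        for n_per in (100, 1000):
            groups = make_groups(probs, n_per, doses)  # expected counts, no sampling noise
            fit = bmd.fit_with_diagnostics(groups, "multistage1", seed=0)
            widths.append(fit.bmd - fit.bmdl)
        assert widths[1] < widths[0]

    def test_bmdl_below_bmd_across_families(self, multistage_groups):
        for fam in ("log_logistic", "weibull", "probit", "dichotomous_hill"):
            fit = bmd.fit_with_diagnostics(multistage_groups, fam, seed=0)
            if fit.bmd is not None and fit.bmdl is not None:
                assert fit.bmdl <= fit.bmd * (1 + 1e-9)


class TestSelectBest:
    def _adequate(self, family="multistage1", aic=700.0, bmd_=1.0, bmdl=0.8, gof_p=0.5):
        return DoseResponseFit(family=family, params=(0.1, 1.0), loglik=-aic / 2 + 2,
                               k=2, aic=aic, converged=True, bmr=0.1, bmd=bmd_, bmdl=bmdl,
                               gof_chi2=1.0, gof_df=6, gof_p=gof_p)

    def _groups(self):
        return make_groups([0.1, 0.2, 0.3], 100, [0.5, 1.5, 3.0])

    def test_single_adequate_fit_chosen(self):
        fit = self._adequate()
        assert bmd.select_best([fit], self._groups()) is fit

    def test_lowest_aic_wins(self):
        a = self._adequate(aic=700.0)
        b = self._adequate(family="gamma", aic=705.0)
        assert bmd.select_best([b, a], self._groups()) is a

    def test_all_poor_gof_yields_none(self):
        fits = [self._adequate(gof_p=0.05), self._adequate(family="gamma", gof_p=0.01)]
        assert bmd.select_best(fits, self._groups()) is None

    def test_bmd_above_max_dose_excluded(self):
        fit = self._adequate(bmd_=10.0, bmdl=9.0)
        assert bmd.select_best([fit], self._groups()) is None

    def test_wide_bmd_bmdl_ratio_excluded(self):
        fit = self._adequate(bmd_=3.0, bmdl=0.5)
        assert bmd.select_best([fit], self._groups()) is None


class TestDeriveRel:
    @pytest.mark.parametrize(
        "bmdl,expected",
        [(1.559, 0.0390), (1.325, 0.0331), (2.312, 0.0578)],
    )
    def test_forty_year_division(self, bmdl, expected):
        rel = bmd.derive_rel(bmdl, working_years=40.0)
        assert rel.rel_mgm3 == pytest.approx(expected, abs=5e-5)

    def test_ppm_conversion_convention(self):
        rel = bmd.derive_rel(1.559, analyte="benzene", working_years=40.0)
        assert rel.rel_ppm == pytest.approx(0.038975 * 24.45 / 78.11, rel=1e-9)
        no_ppm = bmd.derive_rel(1.0, working_years=40.0)
        assert no_ppm.rel_ppm is None

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValueError):
            bmd.derive_rel(0.0)
        with pytest.raises(ValueError):
            bmd.derive_rel(1.0, working_years=0.0)
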