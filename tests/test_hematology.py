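"""Hemogram declines and the two-criteria damage classifier."""

import numpy as np
import pandas as pd
import pytest

from btxrisk import hematology
from btxrisk.hematology import PARAMETERS, ReferenceLimits


def _pairs(n=1, **overrides):
    """A hemogram-pair frame with healthy defaults, overridable per column."""
    defaults = {
        "wbc": 6.5, "neutrophils": 3.5, "monocytes": 0.45, "lymphocytes": 2.4,
        "rbc": 5.0, "hemoglobin": 150.0, "hematocrit": 44.0, "platelets": 240.0, "mpv": 9.5,
    }
    data = {"worker_id": np.arange(n)}
    for p in PARAMETERS:
        data[f"baseline_{p}"] = np.full(n, defaults[p])
        data[f"followup_{p}"] = np.full(n, defaults[p])
    df = pd.DataFrame(data)
    for col, val in overrides.items():
        df[col] = val
    return df


class TestComputeDecline:
    def test_identical_stages_give_zero_decline(self):
        out = hematology.compute_decline(_pairs(3))
        assert (out.filter(like="decline_") == 0).all().all()

    def test_observed_cohort_scale_declines(self):
        df = _pairs(1, baseline_hemoglobin=152.10, followup_hemoglobin=143.76,
                    baseline_monocytes=0.47, followup_monocytes=0.32)
        out = hematology.compute_decline(df)
        assert out["decline_hemoglobin"].iloc[0] == pytest.approx(8.34)
        assert out["decline_monocytes"].iloc[0] == pytest.approx(0.15)

    def test_missing_parameter_named_in_error(self):
        df = _pairs(2).drop(columns=["followup_platelets"])
        with pytest.raises(KeyError, match="followup_platelets"):
            hematology.compute_decline(df)


class TestDeclineThresholds:
    def test_linear_interpolation_percentile(self):
        # declines 1..20 in one sex: 95th percentile = 19.05 under interpolation
        df = _pairs(40)
        decl = hematology.compute_decline(df)
        vals = np.concatenate([np.arange(1, 21), np.arange(1, 21)])
        decl["decline_wbc"] = vals
        sex = np.array(["male"] * 20 + ["female"] * 20)
        decl.loc[sex == "male", "decline_wbc"] = np.arange(1, 21)
        thr = hematology.decline_thresholds(decl, sex)
        assert thr.loc["male", "wbc"] == pytest.approx(19.05)

    def test_constant_declines(self):
        decl = hematology.compute_decline(_pairs(40, followup_rbc=4.7))  # decline 0.3 everywhere
        sex = np.array(["male"] * 40)
        thr = hematology.decline_thresholds(decl, sex)
        assert thr.loc["male", "rbc"] == pytest.approx(0.3)

    def test_outlier_raises_threshold(self):
        rng = np.random.default_rng(0)
        decl = hematology.compute_decline(_pairs(40))
        base = rng.normal(0, 1, 40)
        decl["decline_mpv"] = base
        sex = np.array(["female"] * 40)
        t1 = hematology.decline_thresholds(decl, sex).loc["female", "mpv"]
        decl.loc[decl.index[:3], "decline_mpv"] = base.max() + 100  # outliers enter the upper tail
        t2 = hematology.decline_thresholds(decl, sex).loc["female", "mpv"]
        assert t2 > t1

    def test_small_stratum_is_error(self):
        decl = hematology.compute_decline(_pairs(25))
        sex = np.array(["male"] * 19 + ["female"] * 6)
        with pytest.raises(ValueError, match="female"):
            hematology.decline_thresholds(decl, sex)


def _classify(followup_overrides=None, decline_overrides=None, n=50):
    """Classify worker 0 against a background cohort of healthy workers."""
    df = _pairs(n)
    for col, val in (followup_overrides or {}).items():
        df.loc[0, col] = val
    decl = hematology.compute_decline(df)
    # background decline noise so thresholds are finite and below any spike
    rng = np.random.default_rng(1)
    for p in PARAMETERS:
        decl[f"decline_{p}"] = rng.normal(0, 0.01, n)
    for col, val in (decline_overrides or {}).items():
        decl.loc[0, col] = val
    sex = np.array(["male"] * (n // 2) + ["female"] * (n - n // 2))
    return hematology.classify_damage(df, decl, sex).iloc[0]


class TestClassifyDamage:
    def test_two_low_followups_is_case_via_criterion1(self):
        call = _classify({"followup_wbc": 3.0, "followup_hemoglobin": 120.0, "followup_rbc": 4.0})
        assert call.criterion1_count == 3 and call.is_case

    def test_one_low_plus_one_extreme_decline_is_not_a_case(self):
        call = _classify({"followup_wbc": 3.0}, {"decline_mpv": 5.0})
        assert call.criterion1_count == 1 and call.criterion2_count == 1 and not call.is_case

    def test_two_extreme_declines_is_case_via_criterion2(self):
        call = _classify(None, {"decline_mpv": 5.0, "decline_platelets": 50.0})
        assert call.criterion1_count == 0 and call.criterion2_count == 2 and call.is_case

    def test_mpv_excluded_from_criterion1(self):
        # an absurdly low follow-up MPV alone must not count toward criterion 1
        call = _classify({"followup_mpv": 0.01})
        assert call.criterion1_count == 0

    def test_sex_specific_limits(self):
        # hemoglobin 120 is below the male limit (130) but not the female one (115)
        df = _pairs(50)
        df["followup_hemoglobin"] = 120.0
        df["followup_wbc"] = 3.0  # below limit for everyone
        decl = hematology.compute_decline(df)
        rng = np.random.default_rng(2)
        for p in PARAMETERS:
            decl[f"decline_{p}"] = rng.normal(0, 0.01, 50)
        sex = np.array(["male"] * 25 + ["female"] * 25)
        calls = hematology.classify_damage(df, decl, sex)
        assert (calls.loc[:24, "criterion1_count"] == 2).all()
        assert (calls.loc[25:, "criterion1_count"] == 1).all()

    def test_missing_limit_is_error(self):
        limits = ReferenceLimits({"wbc": {"male": 3.5, "female": 3.5}})
        df = _pairs(50)
        decl = hematology.compute_decline(df)
        sex = np.array(["male"] * 25 + ["female"] * 25)
        with pytest.raises(KeyError, match="neutrophils"):
            hematology.classify_damage(df, decl, sex, limits=limits)

    def test_mpv_must_not_carry_a_limit(self):
        with pytest.raises(ValueError, match="MPV"):
            ReferenceLimits({"mpv": {"male": 7.0}})

    def test_limits_load_from_yaml(self, tmp_path):
        path = tmp_path / "limits.yaml"
        path.write_text("wbc: 3.5\nhemoglobin:\n  male: 130\n  female: 115\n")
        lim = ReferenceLimits.from_yaml(path)
        assert lim.lower("wbc", "female") == 3.5
        assert lim.lower("hemoglobin", "male") == 130


class TestCriterion2Prevalence:
    def test_single_parameter_exceedance_near_five_percent(self):
        """The 95th-percentile construction marks ~5% per sex per parameter;
        the >=2-parameter case rate is strictly lower when parameters are
        independent."""
        rng = np.random.default_rng(7)
        n = 4000
        df = _pairs(n)
        decl = hematology.compute_decline(df)
        for p in PARAMETERS:
            decl[f"decline_{p}"] = rng.normal(0, 1, n)
            df[f"followup_{p}"] = 1000.0  # keep criterion 1 silent
        sex = np.array(["male"] * (n // 2) + ["female"] * (n // 2))
        calls = hematology.classify_damage(df, decl, sex)
        thr = hematology.decline_thresholds(decl, sex)
        exceed = (decl["decline_wbc"].to_numpy() > thr["wbc"].loc[sex].to_numpy()).mean()
        assert exceed == pytest.approx(0.05, abs=0.01)
        case_rate = calls["is_case"].mean()
        # binomial(9, 0.05): P(>=2) ~ 0.071; must be well below 9*5% = 45%
        assert 0.02 < case_rate < 0.13
        assert case_rate < 9 * exceed
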