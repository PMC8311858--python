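"""Statistical battery: closed-form oracles, degenerate inputs, FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from connseg.stats import (
    bh_fdr,
    brain_behavior_model,
    change_model,
    independent_group_test,
    paired_change_test,
    per_module_comparisons,
    pretreatment_model,
)


def _covariates(n_hc=6, n_active=6, n_sham=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_hc):
        rows.append(dict(subject_id=f"HC{i:02d}", cohort="HC", arm="none",
                         timepoint="single", age=rng.normal(65, 8),
                         gender="F" if i % 2 else "M",
                         education=rng.normal(16, 2), severity=0.0,
                         motion_rms=rng.uniform(0.05, 0.2),
                         behavior_gain=np.nan))
    for arm, prefix, n in (("active", "TD", n_active), ("sham", "SH", n_sham)):
        for i in range(n):
            rows.append(dict(subject_id=f"{prefix}{i:02d}", cohort="PPA",
                             arm=arm, timepoint="pre",
                             age=rng.normal(66, 7),
                             gender="F" if i % 2 else "M",
                             education=rng.normal(16, 2),
                             severity=rng.uniform(1, 15),
                             motion_rms=rng.uniform(0.05, 0.2),
                             behavior_gain=rng.uniform(20, 80)))
    return pd.DataFrame(rows)


class TestPretreatmentModel:
    def test_planted_severity_slope_recovered(self):
        cov = _covariates(seed=1)
        rng = np.random.default_rng(2)
        values = 0.5 + 0.02 * cov["severity"] + 0.002 * rng.standard_normal(len(cov))
        metrics = pd.DataFrame({"subject_id": cov["subject_id"], "value": values})
        fit_cohort, fit_severity = pretreatment_model(metrics, cov)
        sev = fit_severity.term("severity")
        assert sev["estimate"] == pytest.approx(0.02, abs=0.005)
        assert sev["p"] < 0.01
        # cohort term reflects the mean offset patients carry via severity
        assert fit_cohort.term("PPA")["estimate"] > 0

    def test_missing_covariate_errors_with_subject(self):
        cov = _covariates()
        cov.loc[cov["subject_id"] == "TD01", "age"] = np.nan
        metrics = pd.DataFrame(
            {"subject_id": cov["subject_id"], "value": np.linspace(0, 1, len(cov))}
        )
        with pytest.raises(ValueError, match="TD01"):
            pretreatment_model(metrics, cov)

    def test_constant_outcome_has_zero_slope(self):
        cov = _covariates()
        metrics = pd.DataFrame(
            {"subject_id": cov["subject_id"], "value": 0.4 * np.ones(len(cov))}
        )
        _, fit_severity = pretreatment_model(metrics, cov)
        assert fit_severity.term("severity")["estimate"] == pytest.approx(0.0, abs=1e-12)


class TestChangeModel:
    def test_zero_deltas_give_zero_arm_coefficient(self):
        cov = _covariates()
        patients = cov[cov["cohort"] == "PPA"]
        delta = pd.DataFrame(
            {"subject_id": patients["subject_id"], "value": 0.0}
        )
        fit = change_model(delta, cov)
        assert fit.term("active")["estimate"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_arm_effect_recovered(self):
        cov = _covariates(seed=3)
        patients = cov[cov["cohort"] == "PPA"]
        rng = np.random.default_rng(4)
        effect = np.where(patients["arm"] == "active", -0.2, 0.0)
        delta = pd.DataFrame(
            {
                "subject_id": patients["subject_id"],
                "value": effect + 0.01 * rng.standard_normal(len(patients)),
            }
        )
        fit = change_model(delta, cov)
        arm = fit.term("active")
        assert arm["estimate"] == pytest.approx(-0.2, abs=0.05)
        assert arm["p"] < 0.01

    def test_hc_subject_rejected(self):
        cov = _covariates()
        delta = pd.DataFrame({"subject_id": ["HC00"], "value": [0.1]})
        with pytest.raises(ValueError, match="patients-only"):
            change_model(delta, cov)


class TestTTests:
    def test_no_change_gives_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_change_test(x, x)
        assert res.terms.loc["mean_change", "t"] == 0.0
        assert res.terms.loc["mean_change", "p"] == 1.0

    def test_paired_matches_closed_form(self):
        pre = np.array([10.0, 12.0, 9.0, 11.0, 14.0])
        post = np.array([12.0, 13.0, 9.0, 14.0, 15.0])
        d = post - pre
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        res = paired_change_test(pre, post)
        assert res.terms.loc["mean_change", "t"] == pytest.approx(expected_t)
        assert res.df_resid == 4

    def test_zero_variance_nonzero_difference_flagged_infinite(self):
        res = paired_change_test(np.zeros(4), np.ones(4))
        assert np.isinf(res.terms.loc["mean_change", "t"])

    def test_pooled_df_matches_16_vs_19_pattern(self, rng):
        a, b = rng.standard_normal(16), rng.standard_normal(19)
        res = independent_group_test(a, b)
        assert res.df_resid == 33

    def test_pooled_matches_scipy_student(self, rng):
        from scipy import stats as sps

        a, b = rng.standard_normal(10), rng.standard_normal(14) + 0.5
        res = independent_group_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.terms.loc["mean_difference", "t"] == pytest.approx(ref.statistic)
        assert res.terms.loc["mean_difference", "p"] == pytest.approx(ref.pvalue)

    def test_welch_flag_changes_df(self, rng):
        a = rng.standard_normal(10)
        b = 5 * rng.standard_normal(20)
        assert independent_group_test(a, b, welch=True).df_resid != 28

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a, b = rng.standard_normal(12), rng.standard_normal(15)
            if independent_group_test(a, b).terms.loc["mean_difference", "p"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_too_small_group_errors(self):
        with pytest.raises(ValueError):
            independent_group_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestBrainBehavior:
    def _data(self, slope_active, slope_sham, seed=0, noise=1.0):
        cov = _covariates(seed=seed)
        patients = cov[cov["cohort"] == "PPA"]
        rng = np.random.default_rng(seed + 100)
        delta = rng.standard_normal(len(patients)) * 0.1
        slope = np.where(patients["arm"] == "active", slope_active, slope_sham)
        gain = 50 + slope * delta / 0.1 + noise * rng.standard_normal(len(patients))
        data = pd.DataFrame(
            {
                "subject_id": patients["subject_id"],
                "delta_pc": delta,
                "behavior_gain": gain,
            }
        )
        return data, cov

    def test_opposite_slopes_yield_interaction(self):
        data, cov = self._data(-8.0, 8.0)
        fit = brain_behavior_model(data, cov)
        inter = fit.term("delta_pc:")
        assert inter["p"] < 0.05
        assert inter["estimate"] < 0
        slopes = fit.extra["simple_slopes"]
        assert slopes["active"]["r"] < 0 < slopes["sham"]["r"]

    def test_constant_gain_gives_zero_slopes(self):
        data, cov = self._data(0.0, 0.0, noise=0.0)
        data["behavior_gain"] = 50.0
        fit = brain_behavior_model(data, cov)
        assert fit.term("delta_pc:")["estimate"] == pytest.approx(0.0, abs=1e-10)
        assert fit.extra["simple_slopes"]["active"]["r"] == 0.0


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_step_up(self):
        # p*m/rank = [.05,.05,.05,.05,.05]; cumulative min leaves all .05
        adjusted = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adjusted, 0.05)

    def test_all_equal_ps_stay_equal(self):
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 30)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_fdr(p), ref)

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.random(50)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPerModuleComparisons:
    def test_fdr_applied_to_between_family_only(self, rng):
        modules = ["own", "m1", "m2", "m3"]
        rows = []
        for grp, n, shift in (("pat", 10, 0.5), ("hc", 10, 0.0)):
            for s in range(n):
                for mod in modules:
                    rows.append(
                        dict(subject_id=f"{grp}{s}", module_name=mod,
                             is_own=(mod == "own"),
                             value=rng.standard_normal() + (shift if mod == "m1" else 0))
                    )
        df = pd.DataFrame(rows)
        out = per_module_comparisons(
            df[df["subject_id"].str.startswith("pat")],
            df[df["subject_id"].str.startswith("hc")],
        )
        assert out.loc[out["is_own"], "p_fdr"].isna().all()
        between = out[~out["is_own"]]
        assert np.all(between["p_fdr"] >= between["p"] - 1e-15)
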