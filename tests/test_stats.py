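"""Repeated-measures ANOVA, regressions and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from vtmorph import stats as st
from vtmorph import synthetic as sv


class TestRmAnova:
    def test_missing_cells_listed(self, default_cohort):
        t = default_cohort.table.iloc[:-3]
        with pytest.raises(ValueError, match="missing cells"):
            st.rm_anova(t, "HPA")

    def test_constant_measure_rejected(self, default_cohort):
        t = default_cohort.table.copy()
        t["HPA"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            st.rm_anova(t, "HPA")

    def test_injected_mode_effect_detected(self, default_cohort):
        res = st.rm_anova(default_cohort.table, "HPA")
        assert res["mode"].p < 0.001
        assert res["mode"].df1 == 1
        assert res["mode"].df2 == 12
        assert res["vowel"].df1 == 4

    def test_vowel_effect_detected(self, default_cohort):
        res = st.rm_anova(default_cohort.table, "LH")
        assert res["vowel"].p < 0.01

    def test_reduces_to_paired_t_with_one_vowel(self, default_cohort):
        """With a single vowel level the mode effect F equals the paired
        t-statistic squared."""
        from scipy import stats as sps
        t = default_cohort.table.query("vowel == 'a'")
        res = st.rm_anova(t, "HPA")
        wide = t.pivot_table(index="subject", columns="mode", values="HPA")
        tt = sps.ttest_rel(wide["singing"], wide["speech_like"])
        assert res["mode"].F == pytest.approx(tt.statistic**2, rel=1e-8)
        assert res["mode"].p == pytest.approx(tt.pvalue, rel=1e-8)

    def test_power_for_twenty_percent_widening(self):
        """hpa_scale=1.2 cohorts: the mode effect is significant in at least
        80 percent of seeded replications at the default noise."""
        hits = 0
        for r in range(20):
            c = sv.make_cohort(seed=300 + r, effects={**sv.NEUTRAL_EFFECTS,
                                                      "hpa_scale": 1.2,
                                                      "hpv_scale": 1.153})
            hits += st.rm_anova(c.table, "HPA")["mode"].p < 0.05
        assert hits >= 16


class TestLinreg:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = st.linreg(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_orthogonal_noise_zero_slope(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        xc = x - x.mean()
        y -= (y @ xc) / (xc @ xc) * xc  # orthogonalize against centered x
        res = st.linreg(x, y)
        assert abs(res.slope) < 1e-10
        assert res.r2 < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.linreg(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            st.linreg(np.array([1.0, 2.0]), np.array([3.0, 4.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_matches_normal_equations_oracle(self, seed):
        """OLS agrees with a direct normal-equations solution to 1e-10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(0, 1 + rng.random(), n)
        if np.var(x) < 1e-12:
            return
        y = rng.normal(0, 2, n)
        res = st.linreg(x, y)
        X = np.stack([x, np.ones(n)], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(beta[0], rel=1e-10, abs=1e-10)
        assert res.intercept == pytest.approx(beta[1], rel=1e-10, abs=1e-10)
        assert res.r2 == res.r * res.r

    def test_hpa_times_height_tracks_hpv_in_uniform_limit(self):
        """On near-uniform synthetic hypopharynges the regression of HPV on
        HPA x 9.765 mm approaches slope 1 with r^2 near 1."""
        rng = np.random.default_rng(9)
        hpa = rng.uniform(150, 450, 60)
        hpv = hpa * st.HPV_HEIGHT_MM * (1 + rng.normal(0, 0.01, 60))
        res = st.linreg(hpa * st.HPV_HEIGHT_MM, hpv)
        assert res.slope == pytest.approx(1.0, abs=0.03)
        assert res.r2 > 0.99

    def test_generator_cohort_slope_near_one(self, default_cohort):
        res = st.hpv_height_regression(default_cohort.table)
        assert 0.85 < res.slope < 1.1
        assert res.r2 > 0.9


class TestSummarize:
    def test_reference_delta_hi_summary(self):
        from vtmorph.reference import reference_delta_hi
        c = sv.make_cohort(seed=2)
        s = st.summarize_cohort(c.table, reference_delta_hi())
        assert round(s["delta_hi"]["mean"], 1) == 4.5
        assert s["delta_hi"]["n_negative"] == 3
        assert s["delta_hi"]["n"] == 13

    def test_null_cohort_summary(self):
        c = sv.make_cohort(seed=5, effects=sv.NEUTRAL_EFFECTS)
        s = st.summarize_cohort(c.table)
        for m in ("ELA", "ELV", "HPA", "HPV"):
            assert s["delta_pc"].loc["all", (f"delta_pc_{m}", "mean")] == \
                pytest.approx(0.0, abs=1.0)
        assert s["delta_lh"].loc["all", "mean"] == pytest.approx(0.0, abs=0.5)
        r = s["ratios"]
        assert r.loc["speech_like", "area_ratio_mean"] == pytest.approx(
            r.loc["singing", "area_ratio_mean"], rel=0.02)

    def test_row_order_invariance(self, default_cohort):
        t = default_cohort.table
        shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = st.summarize_cohort(t)
        b = st.summarize_cohort(shuffled)
        pd.testing.assert_frame_equal(a["delta_pc"], b["delta_pc"])
        pd.testing.assert_frame_equal(a["ratios"], b["ratios"])

    def test_study_conditions_aggregates(self, default_cohort):
        """Default cohorts reproduce the injected aggregate effects: +21.9 %
        HPA, +16.8 % HPV, +7.2 % ELV, 8 mm lowering, area ratio dropping
        from about 0.29 to about 0.26."""
        s = st.summarize_cohort(default_cohort.table)
        g = s["delta_pc"].loc["all"]
        assert g[("delta_pc_HPA", "mean")] == pytest.approx(21.9, abs=1.0)
        assert g[("delta_pc_HPV", "mean")] == pytest.approx(16.8, abs=1.0)
        assert g[("delta_pc_ELV", "mean")] == pytest.approx(7.2, abs=1.0)
        assert g[("delta_pc_ELA", "mean")] == pytest.approx(12.1, abs=1.0)
        assert s["delta_lh"].loc["all", "mean"] == pytest.approx(8.0, abs=0.5)
        r = s["ratios"]
        assert r.loc["speech_like", "area_ratio_mean"] == pytest.approx(0.29, abs=0.01)
        assert r.loc["singing", "area_ratio_mean"] == pytest.approx(0.26, abs=0.01)
        assert (r.loc["singing", "volume_ratio_mean"]
                < r.loc["speech_like", "volume_ratio_mean"])


class TestCorrelateGroups:
    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": -np.arange(10.0)})
        res = st.correlate_groups(df, "x", "y", by=None)
        assert res["all"].r == pytest.approx(-1.0)

    def test_independent_columns_small_r(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.standard_normal(500),
                           "y": rng.standard_normal(500)})
        res = st.correlate_groups(df, "x", "y", by=None)["all"]
        assert abs(res.r) < 0.1
        assert res.p > 0.01 or abs(res.r) < 0.1

    def test_small_group_skipped_with_warning(self):
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 2,
                           "x": np.arange(7.0), "y": np.arange(7.0)})
        with pytest.warns(UserWarning, match="skipped"):
            res = st.correlate_groups(df, "x", "y", by="g")
        assert set(res) == {"a"}

    @pytest.mark.parametrize("kappa", [0.02, -0.02])
    def test_injected_coupling_recovered(self, kappa):
        """Cohorts where larynx lowering drives hypopharyngeal widening for
        /o/ and /u/ only show the coupling's correlation for those vowels
        and near-zero elsewhere.  (With delta-LH positive for lowering,
        'greater lowering, wider pharynx' is a positive r; plots with the
        opposite delta-LH sign show it as negative.)"""
        rs = {v: [] for v in "aeiou"}
        for rep in range(6):
            c = sv.make_cohort(seed=700 + rep,
                               heterogeneity={"lowering_sd": 4.0,
                                              "hpa_scale_sd": 0.02},
                               coupling={"vowels": ("o", "u"), "kappa": kappa})
            con = st.mode_contrasts(c.table)
            for v, g in con.groupby("vowel"):
                rs[v].append(st.linreg(g["delta_LH"].to_numpy(),
                                       g["delta_pc_HPA"].to_numpy()).r)
        sign = np.sign(kappa)
        assert sign * np.mean(rs["o"]) > 0.5 and sign * np.mean(rs["u"]) > 0.5
        assert abs(np.mean(rs["a"])) < 0.35 and abs(np.mean(rs["e"])) < 0.35


class TestS1Schema:
    def test_round_trip(self, tmp_path, default_cohort):
        p = tmp_path / "s1.csv"
        default_cohort.table.to_csv(p, index=False)
        df = st.load_s1_table(p)
        pd.testing.assert_frame_equal(df, default_cohort.table)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"subject": [1], "vowel": ["a"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="lacks columns"):
            st.load_s1_table(p)
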