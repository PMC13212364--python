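import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from phenostat import (
    diagnose,
    effect_sizes,
    fit_anova,
    fit_mixed,
    fit_spline,
    growth_summary,
    posthoc_tukey,
    select_model,
    summarize_design,
)
from phenostat.errors import DegenerateDesignError
from phenostat.stats_models import DesignSummary


def two_way(rng, n_per=5, a=2, b=2, effect=0.0, noise=1.0):
    rows = []
    for i in range(a):
        for j in range(b):
            for k in range(n_per):
                rows.append(
                    {"A": f"a{i}", "B": f"b{j}", "value": effect * i + rng.normal(0, noise)}
                )
    return pd.DataFrame(rows)


class TestSummarizeDesign:
    def test_balanced_2x2(self):
        df = two_way(np.random.default_rng(0), n_per=3)
        d = summarize_design(df, ["A", "B"])
        assert d.balanced and d.max_levels == 2 and d.n_obs == 12

    def test_removing_one_observation_unbalances(self):
        df = two_way(np.random.default_rng(0), n_per=3).iloc[1:]
        assert not summarize_design(df, ["A", "B"]).balanced

    def test_max_levels_counts_largest_factor(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"cultivar": [f"c{i}" for i in range(50)] * 2, "treatment": ["T1", "T2"] * 50,
             "value": rng.normal(size=100)}
        )
        assert summarize_design(df, ["cultivar", "treatment"]).max_levels == 50

    def test_single_level_factor_named_in_error(self):
        df = pd.DataFrame({"A": ["x"] * 4, "value": [1, 2, 3, 4]})
        with pytest.raises(DegenerateDesignError, match="A"):
            summarize_design(df, ["A"])


class TestSelectModel:
    @pytest.mark.parametrize(
        "balanced, max_levels, time_series, expected",
        [
            (True, 10, False, "anova"),
            (True, 11, False, "mixed"),
            (False, 2, False, "mixed"),
            (False, 11, False, "mixed"),
            (False, 20, False, "mixed"),
            (True, 25, False, "mixed"),  # high cardinality degrades gracefully
            (True, 2, True, "spline"),
            (False, 50, True, "spline"),
        ],
    )
    def test_selection_rule(self, balanced, max_levels, time_series, expected):
        d = DesignSummary(factors=[("f", max_levels)], balanced=balanced,
                          max_levels=max_levels, n_obs=100)
        assert select_model(d, time_series=time_series) == expected

    def test_user_override_always_wins(self):
        d = DesignSummary(factors=[("f", 15)], balanced=False, max_levels=15, n_obs=100)
        assert select_model(d, override="anova") == "anova"


class TestFitAnova:
    def test_single_factor_hand_computed_f(self):
        df = pd.DataFrame({"g": ["A"] * 3 + ["B"] * 3, "value": [1, 2, 3, 4, 5, 6]})
        res = fit_anova(df, ["g"])
        row = res.terms.iloc[0]
        assert row["F"] == pytest.approx(13.5)
        assert row["df"] == 1

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            df = pd.DataFrame(
                {"g": ["A"] * n + ["B"] * n, "value": rng.normal(0, 1, 2 * n)}
            )
            res = fit_anova(df, ["g"])
            t, p = sps.ttest_ind(df.loc[df.g == "A", "value"], df.loc[df.g == "B", "value"])
            assert res.terms.iloc[0]["F"] == pytest.approx(t**2, rel=1e-9)
            assert res.terms.iloc[0]["p"] == pytest.approx(p, rel=1e-9)

    def test_additive_balanced_design_zero_interaction_ss(self):
        rows = []
        for i, ai in enumerate([0.0, 3.0]):
            for j, bj in enumerate([0.0, 5.0]):
                for r in range(3):
                    rows.append({"A": f"a{i}", "B": f"b{j}", "value": 10 + ai + bj})
        res = fit_anova(pd.DataFrame(rows), ["A", "B"])
        inter = res.terms.set_index("term").loc["A:B", "sum_sq"]
        assert inter == pytest.approx(0.0, abs=1e-16)

    def test_type2_equals_type1_on_balanced_data(self):
        rng = np.random.default_rng(3)
        df = two_way(rng, n_per=6, effect=1.0)
        res = smf.ols("value ~ C(A) * C(B)", data=df).fit()
        t1 = sm.stats.anova_lm(res, typ=1)
        t2 = sm.stats.anova_lm(res, typ=2)
        for term in ["C(A)", "C(B)", "C(A):C(B)"]:
            assert t1.loc[term, "sum_sq"] == pytest.approx(t2.loc[term, "sum_sq"])

    def test_constant_response_degenerate(self):
        df = pd.DataFrame({"g": ["A", "A", "B", "B", "A", "B"], "value": [5.0] * 6})
        with pytest.raises(DegenerateDesignError):
            fit_anova(df, ["g"])

    def test_saturated_design_rejected_before_fit(self):
        df = pd.DataFrame({"g": ["A", "B", "C"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateDesignError, match="saturated"):
            fit_anova(df, ["g"])


class TestEffectSizes:
    def test_single_factor_matches_r_squared(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            df = pd.DataFrame(
                {"g": ["A"] * 15 + ["B"] * 15,
                 "value": np.r_[rng.normal(0, 1, 15), rng.normal(1, 1, 15)]}
            )
            res = fit_anova(df, ["g"])
            assert res.effect_sizes["g"] == pytest.approx(res.fitted.rsquared, rel=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(12)
        df = two_way(rng, n_per=8, effect=2.0)
        res = fit_anova(df, ["A", "B"])
        for v in effect_sizes(res).values():
            assert 0.0 <= v <= 1.0

    def test_unavailable_for_mixed(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {"g": ["A", "B"] * 30, "vtr": [f"p{i % 10}" for i in range(60)],
             "value": rng.normal(0, 1, 60)}
        )
        res = fit_mixed(df, ["g"])
        with pytest.raises(ValueError):
            effect_sizes(res)


class TestDiagnose:
    def test_normality_p_calibrated_under_null(self):
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame({"g": ["A", "B"] * 50, "value": rng.normal(0, 1, 100)})
            res = fit_anova(df, ["g"])
            d = diagnose(res, df)
            rejections += d.normality_p < 0.05
        # rejection rate ~ alpha: binomial(200, 0.05) within 4 sd
        assert abs(rejections / reps - 0.05) < 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_homogeneity_detects_unequal_variances(self):
        rng = np.random.default_rng(22)
        hits = 0
        reps = 40
        for _ in range(reps):
            df = pd.DataFrame(
                {"g": ["A"] * 50 + ["B"] * 50,
                 "value": np.r_[rng.normal(0, 1, 50), rng.normal(0, 5, 50)]}
            )
            res = fit_anova(df, ["g"])
            hits += diagnose(res, df).homogeneity_p < 0.05
        assert hits >= 0.95 * reps

    def test_equal_spread_cells_statistic_zero(self):
        vec = np.array([1.0, 2.0, 3.0, 4.0])
        groups = [vec, vec + 10]
        stat, p = sps.levene(*groups, center="median")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_tiny_sample_reported_unavailable(self):
        df = pd.DataFrame({"g": ["A", "B"], "value": [1.0, 2.0]})
        res = smf.ols("value ~ C(g)", data=df).fit()
        from phenostat.stats_models import ModelResult

        mr = ModelResult(model_type="anova", terms=pd.DataFrame(), factors=["g"], fitted=res)
        d = diagnose(mr, df)
        assert d.normality_p is None


class TestPosthocTukey:
    def test_equal_groups_all_p_near_one(self):
        df = pd.DataFrame(
            {"g": np.repeat(["A", "B", "C"], 10), "value": np.tile(np.arange(10.0), 3)}
        )
        table = posthoc_tukey(df, "g")
        assert len(table) == 3
        assert (table["p_adj"].astype(float) > 0.99).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame(
            {"g": np.repeat(["A", "B", "C"], 20),
             "value": np.r_[rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(10, 1, 20)]}
        )
        t = posthoc_tukey(df, "g").set_index(["level_a", "level_b"])
        assert t.loc[("A", "C"), "p_adj"] < 0.01
        assert t.loc[("B", "C"), "p_adj"] < 0.01
        assert t.loc[("A", "B"), "p_adj"] > 0.05

    def test_pair_count(self):
        rng = np.random.default_rng(32)
        df = pd.DataFrame({"g": np.repeat([f"g{i}" for i in range(5)], 4),
                           "value": rng.normal(size=20)})
        assert len(posthoc_tukey(df, "g")) == 5 * 4 // 2


class TestFitMixed:
    def test_matches_anova_when_random_variance_zero(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame(
            {"g": np.repeat(["A", "B"], 40), "vtr": [f"p{i % 20}" for i in range(80)],
             "value": np.repeat([0.0, 2.0], 40) + rng.normal(0, 1, 80)}
        )
        mixed = fit_mixed(df, ["g"])
        anova = fit_anova(df, ["g"])
        assert mixed.fitted.params["C(g)[T.B]"] == pytest.approx(
            anova.fitted.params["C(g)[T.B]"], abs=0.05
        )

    def test_random_intercept_sd_recovery(self):
        rng = np.random.default_rng(42)
        n_groups, n_per = 100, 5
        g = np.repeat(np.arange(n_groups), n_per)
        y = 10.0 + rng.normal(0, 5, n_groups)[g] + rng.normal(0, 2, len(g))
        df = pd.DataFrame(
            {"value": y, "vtr": [f"p{i}" for i in g],
             "g": np.tile(["A", "B", "C", "D", "E"], n_groups)}
        )
        res = fit_mixed(df, ["g"])
        assert 2.5 <= res.random_sd <= 7.5

    def test_single_group_rejected(self):
        df = pd.DataFrame({"g": ["A", "B"] * 5, "vtr": ["p1"] * 10, "value": range(10)})
        with pytest.raises(DegenerateDesignError):
            fit_mixed(df, ["g"])


def logistic(t, K, r, t0=10.0):
    return K / (1 + np.exp(-r * (t - t0)))


def growth_data(rng, r_by_group, n_plants=40, noise_frac=0.05, K=300.0):
    times = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
    rows = []
    for group, r in r_by_group.items():
        for p in range(n_plants):
            for t in times:
                rows.append(
                    {"group": group, "plant": f"{group}{p}", "t": t,
                     "value": logistic(t, K, r) + rng.normal(0, noise_frac * K)}
                )
    return pd.DataFrame(rows)


class TestFitSpline:
    def test_reproduces_cubic_exactly_with_zero_noise(self):
        t = np.tile(np.linspace(0, 10, 8), 2)
        g = np.repeat(["A", "B"], 8)
        y = 1 + 2 * t - 0.5 * t**2 + 0.03 * t**3 + (g == "B") * 5.0
        df = pd.DataFrame({"t": t, "group": g, "value": y})
        res = fit_spline(df, "t", "group", df=4)
        np.testing.assert_allclose(res.fitted.fittedvalues, y, atol=1e-8)

    def test_interaction_type1_error_near_alpha_under_null(self):
        rng = np.random.default_rng(51)
        reps, rejections = 120, 0
        for _ in range(reps):
            df = growth_data(rng, {"A": 0.35, "B": 0.35}, n_plants=10)
            res = fit_spline(df, "t", "group", df=3)
            p = res.terms.set_index("term").loc["group:time_curve", "p"]
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_detects_different_growth_rates(self):
        rng = np.random.default_rng(52)
        hits = 0
        reps = 20
        for _ in range(reps):
            df = growth_data(rng, {"A": 0.30, "B": 0.45}, n_plants=40)
            res = fit_spline(df, "t", "group", df=3)
            p = res.terms.set_index("term").loc["group:time_curve", "p"]
            hits += p < 0.01
        assert hits >= 0.9 * reps

    def test_too_few_time_points_suggests_anova(self):
        df = pd.DataFrame({"t": [0.0, 1.0, 2.0] * 4, "group": ["A", "B"] * 6,
                           "value": np.arange(12.0)})
        with pytest.raises(DegenerateDesignError, match="ANOVA"):
            fit_spline(df, "t", "group", df=4)


class TestGrowthSummary:
    def _df(self):
        rows = []
        for tp, day, mean in [(1, 0.0, 10.0), (2, 5.0, 20.0), (3, 10.0, 20.0)]:
            for p in range(4):
                rows.append(
                    {"group": "A", "time_point": tp, "value": mean,
                     "timestamp": pd.Timestamp("2026-06-01") + pd.Timedelta(days=day)}
                )
        return pd.DataFrame(rows)

    def test_rates_and_total_gain(self):
        gs = growth_summary(self._df(), "group")
        first = gs.intervals.iloc[0]
        assert first["absolute_rate"] == pytest.approx(2.0)  # 10 -> 20 over 5 days
        assert first["relative_rate"] == pytest.approx(np.log(2) / 5)
        second = gs.intervals.iloc[1]
        assert second["absolute_rate"] == pytest.approx(0.0)
        assert gs.totals.iloc[0]["total_gain"] == pytest.approx(10.0)

    def test_constant_trajectory_zero_rates(self):
        df = self._df()
        df["value"] = 7.0
        gs = growth_summary(df, "group")
        assert (gs.intervals["absolute_rate"] == 0).all()
        assert (gs.totals["total_gain"] == 0).all()

    def test_nonpositive_mean_relative_rate_unavailable(self):
        df = self._df()
        df.loc[df.time_point == 1, "value"] = -5.0
        gs = growth_summary(df, "group")
        assert np.isnan(gs.intervals.iloc[0]["relative_rate"])

    def test_single_time_point_rejected(self):
        df = self._df()
        with pytest.raises(DegenerateDesignError):
            growth_summary(df[df.time_point == 1], "group")
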