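"""Wilcoxon comparisons, age-trend fits, and the two-slope (Zar) test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flyheart.cohortstats import (
    LinearFit,
    benjamini_hochberg,
    compare_slopes,
    fit_age_trend,
    stars,
    summarize_cohort,
    wilcoxon_compare,
)
from flyheart.synth import AgingModel, simulate_cohort

from _oracles import wilcoxon_exact_bruteforce


def records_from(points, metric="hp_ms", condition="c"):
    return pd.DataFrame(
        [
            {"fly_id": f"f{i}", "condition": condition, "age_days": x, metric: y}
            for i, (x, y) in enumerate(points)
        ]
    )


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        _, p, s = wilcoxon_compare([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)
        assert s == ""

    def test_fully_separated_small_groups_exact_p(self):
        """{1,2,3} vs {4,5,6}: the minimal rank-sum has probability 1/20 per tail."""
        _, p, _ = wilcoxon_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_star_thresholds(self):
        assert stars(0.04) == "*"
        assert stars(0.004) == "**"
        assert stars(0.06) == ""
        assert stars(0.05) == ""  # strict inequality

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1, 2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        na=st.integers(2, 5),
        nb=st.integers(2, 5),
        seed=st.integers(0, 10_000),
    )
    def test_exact_branch_equals_full_enumeration(self, na, nb, seed):
        """Exact branch equals the all-assignments oracle for tie-free samples."""
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, na + nb + 1))  # distinct values
        a, b = vals[:na], vals[na:]
        _, p, _ = wilcoxon_compare(a, b)
        assert p == pytest.approx(wilcoxon_exact_bruteforce(a, b), abs=1e-12)


class TestFitAgeTrend:
    def test_collinear_points_exact_line(self):
        fit = fit_age_trend(records_from([(10, 1.0), (30, 3.0), (45, 4.5)]), "hp_ms")
        assert fit.slope == pytest.approx(0.1)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_min_age_filter_excludes_young_flies(self):
        pts = [(3, 99.0), (10, 1.0), (30, 3.0), (45, 4.5)]
        fit = fit_age_trend(records_from(pts), "hp_ms")  # default min_age 10
        assert fit.n == 3
        assert fit.slope == pytest.approx(0.1)

    def test_all_below_min_age_rejected(self):
        with pytest.raises(ValueError):
            fit_age_trend(records_from([(3, 1.0), (5, 2.0), (7, 3.0)]), "hp_ms")

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        x = rng.choice([10, 30, 45, 60], size=40)
        y = 2.0 + 0.5 * x + rng.normal(0, 3, size=40)
        fit = fit_age_trend(records_from(zip(x, y)), "hp_ms")
        res = sm.OLS(y, sm.add_constant(x.astype(float))).fit()
        assert fit.slope == pytest.approx(res.params[1], rel=1e-9)
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-9)
        assert fit.slope_se == pytest.approx(res.bse[1], rel=1e-9)
        assert fit.rss == pytest.approx(res.ssr, rel=1e-9)

    def test_means_mode_fits_group_means(self):
        pts = [(10, 1.0), (10, 3.0), (30, 4.0), (30, 6.0), (45, 7.0), (45, 9.0)]
        fit_means = fit_age_trend(records_from(pts), "hp_ms", means=True)
        fit_flies = fit_age_trend(records_from(pts), "hp_ms")
        assert fit_means.n == 3
        assert fit_means.slope == pytest.approx(fit_flies.slope)  # balanced design
        assert fit_means.rss < fit_flies.rss


class TestCompareSlopes:
    def test_identical_fits_t_zero_p_one(self):
        fit = fit_age_trend(
            records_from([(10, 1.0), (30, 3.2), (45, 4.4), (60, 6.3)]), "hp_ms"
        )
        cmp_res = compare_slopes(fit, fit)
        assert cmp_res.t_stat == pytest.approx(0.0)
        assert cmp_res.p_value == pytest.approx(1.0)

    def test_hand_worked_example(self):
        """A={(0,0),(1,1),(2,2),(3,3)}, B={(0,0),(1,2),(2,3),(3,6)}:
        slopes 1 and 1.9, pooled s^2 = 0.175, t = -3.402 on 4 df."""
        fit_a = fit_age_trend(
            records_from([(0, 0.0), (1, 1.0), (2, 2.0), (3, 3.0)]), "hp_ms", min_age=0
        )
        fit_b = fit_age_trend(
            records_from([(0, 0.0), (1, 2.0), (2, 3.0), (3, 6.0)]), "hp_ms", min_age=0
        )
        assert fit_a.slope == pytest.approx(1.0)
        assert fit_b.slope == pytest.approx(1.9)
        assert fit_b.rss == pytest.approx(0.70)
        res = compare_slopes(fit_a, fit_b)
        assert res.df == 4
        assert res.t_stat == pytest.approx(-3.402, abs=1e-3)
        # independent p evaluation from the t distribution
        from scipy import stats as ss

        assert res.p_value == pytest.approx(2 * ss.t.sf(3.4017, 4), rel=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x = np.tile([10, 30, 45, 60], 5).astype(float)
        fa = fit_age_trend(records_from(zip(x, 1 + 0.3 * x + rng.normal(0, 1, 20))), "hp_ms")
        fb = fit_age_trend(records_from(zip(x, 2 + 0.5 * x + rng.normal(0, 1, 20))), "hp_ms")
        r1 = compare_slopes(fa, fb)
        r2 = compare_slopes(fb, fa)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = np.tile([10, 30, 45, 60], 5).astype(float)
        ya = 1 + 0.3 * x + rng.normal(0, 1, 20)
        yb = 2 + 0.5 * x + rng.normal(0, 1, 20)
        r1 = compare_slopes(
            fit_age_trend(records_from(zip(x, ya)), "hp_ms"),
            fit_age_trend(records_from(zip(x, yb)), "hp_ms"),
        )
        r2 = compare_slopes(
            fit_age_trend(records_from(zip(x, ya + 100)), "hp_ms"),
            fit_age_trend(records_from(zip(x, yb + 100)), "hp_ms"),
        )
        assert r1.t_stat == pytest.approx(r2.t_stat, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_zero_variance_degenerate_cases(self):
        perfect_a = fit_age_trend(records_from([(10, 1.0), (30, 3.0), (45, 4.5)]), "hp_ms")
        perfect_b = fit_age_trend(records_from([(10, 2.0), (30, 6.0), (45, 9.0)]), "hp_ms")
        same = compare_slopes(perfect_a, perfect_a)
        assert same.p_value == 1.0 and not same.degenerate
        diff = compare_slopes(perfect_a, perfect_b)
        assert diff.p_value == 0.0 and diff.degenerate


class TestSummarizeCohort:
    def test_means_and_sems_match_bruteforce_reaggregation(self):
        df = simulate_cohort(seed=4, n_per_group=8, ages=(10, 30))
        summary, _ = summarize_cohort(df)
        for _, row in summary.iterrows():
            grp = df[(df.condition == row.condition) & (df.age_days == row.age_days)]
            vals = grp[row.metric].to_numpy()
            assert row["mean"] == pytest.approx(vals.mean())
            assert row["sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))

    def test_single_fly_group_flags_undefined_sem(self):
        df = simulate_cohort(seed=5, n_per_group=1, ages=(10, 30))
        summary, _ = summarize_cohort(df)
        assert np.isnan(summary["sem"]).all()
        assert (summary["flag"] != "").all()

    def test_planted_group_shift_detected(self):
        model = AgingModel(
            conditions=(
                ("ctl", (("hp_ms", (130.0, 2.0)),)),
                ("mut", (("hp_ms", (180.0, 2.0)),)),  # +50 ms shift
            ),
            noise_sd=(("hp_ms", 15.0),),
        )
        df = simulate_cohort(model, n_per_group=20, ages=(10, 30), seed=6)
        _, tests = summarize_cohort(df, metrics=("hp_ms",), control="ctl")
        vs = tests[tests.comparison == "vs_control"]
        assert (vs.p_value < 5e-3).all()

    def test_benjamini_hochberg_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
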