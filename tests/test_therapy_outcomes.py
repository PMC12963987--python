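import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tatkit.core_io import StudyConfig
from tatkit.therapy_outcomes import (
    GrowthCurve,
    fit_growth,
    growth_auc,
    km_estimate,
    kruskal_dunn,
    normalize_growth,
    pairwise_logrank,
)


def _curve(days, volumes, mouse="m1", group="g"):
    return GrowthCurve(mouse=mouse, group=group, days=days, volumes_mm3=volumes)


class TestNormalizeGrowth:
    def test_day1_anchor(self):
        c = normalize_growth(_curve([1, 5], [50.0, 300.0]))
        assert c.normalized_pct[0] == pytest.approx(100.0)
        assert c.normalized_pct[1] == pytest.approx(600.0)

    def test_constant_volume_is_flat(self):
        c = normalize_growth(_curve([1, 3, 5], [80.0, 80.0, 80.0]))
        np.testing.assert_allclose(c.normalized_pct, 100.0)

    def test_missing_day1_is_error(self):
        with pytest.raises(ValueError, match="day-1"):
            normalize_growth(_curve([0, 2, 4], [50.0, 60.0, 70.0]))

    def test_auc_commutes_with_scaling(self):
        days = [1, 2, 4, 6]
        vols = np.array([60.0, 90.0, 200.0, 500.0])
        auc1 = growth_auc(normalize_growth(_curve(days, vols)))
        auc2 = growth_auc(normalize_growth(_curve(days, vols * 7.5)))
        assert auc1 == pytest.approx(auc2, rel=1e-12)


class TestFitGrowth:
    def test_doubling_time_closed_form(self):
        days = np.arange(1.0, 12.0)
        vols = 67.0 * 2 ** ((days - 1.0) / 2.0)
        fit = fit_growth(_curve(days, vols))
        assert fit.model == "exponential"
        assert fit.k_per_day == pytest.approx(np.log(2) / 2, rel=1e-9)
        assert fit.time_to_sixfold_days == pytest.approx(2 * np.log2(6),
                                                         rel=1e-9)
        assert fit.included

    def test_plateau_below_sixfold_excluded(self):
        days = np.arange(1.0, 20.0)
        y = 400.0 - 300.0 * np.exp(-0.3 * (days - 1.0))
        fit = fit_growth(_curve(days, y))  # volumes proportional to y
        assert fit.model == "one_phase_association"
        assert fit.ymax_pct == pytest.approx(400.0, rel=1e-6)
        assert not fit.included
        assert fit.exclusion_reason == "plateau_below_sixfold"
        assert fit.time_to_sixfold_days is None

    def test_one_phase_above_sixfold_solves_threshold(self):
        days = np.arange(1.0, 25.0)
        ymax, k = 900.0, 0.25
        y = ymax - (ymax - 100.0) * np.exp(-k * (days - 1.0))
        fit = fit_growth(_curve(days, y))
        assert fit.model == "one_phase_association"
        t6 = fit.time_to_sixfold_days
        # plugging back in must give exactly the six-fold level
        assert ymax - (ymax - 100.0) * np.exp(-k * t6) == pytest.approx(600.0,
                                                                       rel=1e-6)

    def test_low_r2_excluded(self):
        rng = np.random.default_rng(17)
        days = np.arange(1.0, 15.0)
        vols = 100.0 + rng.normal(0, 40.0, size=days.shape)
        vols = np.abs(vols) + 5.0
        vols[0] = 100.0
        fit = fit_growth(_curve(days, vols))
        assert not fit.included
        assert fit.exclusion_reason == "r2_below_min"
        assert fit.r2 < 0.5

    def test_nadir_triggers_growth_phase_fit(self):
        days = np.array([1.0, 3.0, 5.0, 7.0, 9.0, 11.0])
        vols = np.array([100.0, 60.0, 40.0, 80.0, 200.0, 500.0])
        fit = fit_growth(_curve(days, vols))
        assert fit.growth_phase_start == pytest.approx(5.0)
        assert fit.model == "exponential"
        assert fit.k_per_day > 0

    def test_nadir_exact_regrowth_recovery(self):
        # clean regrowth at known rate from a 40% nadir
        k = 0.5
        days = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0])
        y = np.where(days <= 3.0, 100.0 * np.exp(-0.45 * (days - 1.0)),
                     100.0 * np.exp(-0.9) * np.exp(k * (days - 3.0)))
        fit = fit_growth(_curve(days, y))
        assert fit.k_per_day == pytest.approx(k, rel=1e-6)
        y0 = 100.0 * np.exp(-0.9)
        expected_t6 = 3.0 - 1.0 + np.log(600.0 / y0) / k
        assert fit.time_to_sixfold_days == pytest.approx(expected_t6, rel=1e-6)

    def test_grid_search_oracle_for_exponential_rate(self):
        """Brute-force grid search over k agrees with the optimizer to
        1e-6 relative on 50 seeded noisy curves."""
        days = np.arange(1.0, 10.0)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            k_true = rng.uniform(0.15, 0.6)
            y = 100.0 * np.exp(k_true * (days - 1.0))
            y = y * rng.lognormal(0, 0.05, size=y.shape)
            y[0] = 100.0
            fit = fit_growth(_curve(days, y))
            if fit.model != "exponential":
                continue

            def sse(k):
                return np.sum((y - 100.0 * np.exp(k * (days - 1.0))) ** 2)

            k_best = fit.k_per_day
            for _ in range(6):
                grid = np.linspace(k_best * 0.99, k_best * 1.01, 201)
                k_best = grid[np.argmin([sse(k) for k in grid])]
            assert fit.k_per_day == pytest.approx(k_best, rel=1e-6)

    def test_time_to_sixfold_scale_free(self):
        days = np.arange(1.0, 10.0)
        vols = 40.0 * np.exp(0.3 * (days - 1.0))
        t6a = fit_growth(_curve(days, vols)).time_to_sixfold_days
        t6b = fit_growth(_curve(days, vols * 123.0)).time_to_sixfold_days
        assert t6a == pytest.approx(t6b, rel=1e-12)


class TestGrowthAuc:
    def test_flat_curve(self):
        days = np.arange(1.0, 11.0)
        c = normalize_growth(_curve(days, np.full(10, 55.0)))
        assert growth_auc(c) == pytest.approx(900.0)

    def test_triangle(self):
        c = normalize_growth(_curve([1.0, 3.0], [50.0, 150.0]))
        assert growth_auc(c) == pytest.approx(400.0)

    def test_dense_exponential_quadrature(self):
        k = 0.25
        days = np.linspace(1.0, 21.0, 4000)
        c = normalize_growth(_curve(days, 10.0 * np.exp(k * (days - 1.0))))
        expected = 100.0 / k * (np.exp(k * 20.0) - 1.0)
        assert growth_auc(c) == pytest.approx(expected, rel=1e-3)

    def test_single_point_is_error(self):
        with pytest.raises(ValueError):
            growth_auc(normalize_growth(_curve([1.0], [10.0])))


def _records(times_a, events_a, times_b=None, events_b=None):
    rows = [{"mouse": f"a{i}", "group": "A", "time_days": t, "event": e}
            for i, (t, e) in enumerate(zip(times_a, events_a))]
    if times_b is not None:
        rows += [{"mouse": f"b{i}", "group": "B", "time_days": t, "event": e}
                 for i, (t, e) in enumerate(zip(times_b, events_b))]
    return pd.DataFrame(rows)


class TestKaplanMeier:
    def test_median_no_censoring(self):
        df = _records([8, 8, 9, 10, 10], [1] * 5)
        assert km_estimate(df, "A")["median_days"] == pytest.approx(9.0)

    def test_all_censored_median_undefined(self):
        df = _records([10, 12, 14], [0, 0, 0])
        est = km_estimate(df, "A")
        assert est["median_days"] is None
        assert np.all(est["survival"] == 1.0)

    def test_hand_computed_product_limit_table(self):
        """Six-subject worked example with censoring, against the
        hand-multiplied product-limit values."""
        df = _records([3, 5, 7, 8, 8, 12], [1, 0, 1, 1, 0, 1])
        est = km_estimate(df, "A")
        surv = dict(zip(est["times"], est["survival"]))
        assert surv[3.0] == pytest.approx(5 / 6)
        assert surv[7.0] == pytest.approx(5 / 6 * 3 / 4)
        assert surv[8.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert surv[12.0] == pytest.approx(0.0)
        assert est["median_days"] == pytest.approx(8.0)

    def test_step_function_monotone_from_one(self):
        rng = np.random.default_rng(21)
        df = _records(rng.exponential(10, 30) + 0.5,
                      rng.integers(0, 2, 30))
        est = km_estimate(df, "A")
        s = est["survival"]
        assert s[0] <= 1.0 + 1e-12
        assert np.all(np.diff(s) <= 1e-12)
        assert est["times"][0] == 0.0 and s[0] == 1.0


class TestPairwiseLogrank:
    @staticmethod
    def _hand_logrank(ta, tb):
        """Independent O-E/V Mantel-Cox computation, no censoring."""
        times = np.sort(np.unique(np.concatenate([ta, tb])))
        o_a = e_a = v = 0.0
        for t in times:
            na = np.sum(ta >= t)
            nb = np.sum(tb >= t)
            n = na + nb
            d = np.sum(ta == t) + np.sum(tb == t)
            if n <= 1 or d == 0:
                continue
            o_a += np.sum(ta == t)
            e_a += d * na / n
            v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        chi2 = (o_a - e_a) ** 2 / v
        return chi2, stats.chi2.sf(chi2, 1)

    def test_hand_oracle_separated_groups(self):
        ta, tb = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        chi2, p = self._hand_logrank(ta, tb)
        df = _records(ta, [1] * 3, tb, [1] * 3)
        out = pairwise_logrank(df, [("A", "B")])
        assert out.loc[0, "chi2"] == pytest.approx(chi2, rel=1e-9)
        assert out.loc[0, "p_raw"] == pytest.approx(p, rel=1e-9)

    def test_group_vs_itself_is_null(self):
        df = _records([3, 5, 8], [1, 1, 1])
        out = pairwise_logrank(df, [("A", "A")])
        assert out.loc[0, "chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_bonferroni_uses_comparison_set_size(self):
        rng = np.random.default_rng(3)
        df = _records(rng.exponential(5, 10) + 0.1, [1] * 10,
                      rng.exponential(15, 10) + 0.1, [1] * 10)
        out = pairwise_logrank(df, [("A", "B"), ("B", "A")], alpha=0.05)
        assert np.all(out["alpha_corrected"] == 0.025)
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(1.0, 2 * out["p_raw"]))

    def test_power_hazard_ratio_three(self):
        """Exponential cohorts with a hazard ratio of 3 and 10 mice per
        group are Bonferroni-significant in the majority of replicates."""
        hits, n_rep = 0, 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = _records(rng.exponential(5, 10) + 1e-3, [1] * 10,
                          rng.exponential(15, 10) + 1e-3, [1] * 10)
            out = pairwise_logrank(df, [("A", "B")], alpha=0.05)
            hits += int(out.loc[0, "significant"])
        assert hits / n_rep > 0.5


class TestKruskalDunn:
    def test_all_tied_is_null(self):
        out = kruskal_dunn({"A": [5.0] * 4, "B": [5.0] * 4})
        assert out["H"] == 0.0
        assert out["p"] == 1.0
        assert out["pairwise"][0]["p_adj"] == 1.0

    def test_two_groups_match_mann_whitney(self):
        """With two tie-free groups the (unadjusted) Dunn z-test equals
        the normal-approximation Mann-Whitney test."""
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 9)
        b = rng.normal(0.8, 1, 11)
        out = kruskal_dunn({"A": a, "B": b})
        mw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        assert out["pairwise"][0]["p_raw"] == pytest.approx(mw.pvalue,
                                                            abs=1e-6)

    def test_null_type_one_error_rate(self):
        """Identical distributions: the Kruskal-Wallis test rejects at
        about the nominal 5% rate."""
        rejections = 0
        n_rep = 2000
        rng = np.random.default_rng(1234)
        for _ in range(n_rep):
            vals = {g: rng.normal(0, 1, 8) for g in ("A", "B", "C")}
            if kruskal_dunn(vals)["p"] < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_rep < 0.07

    def test_power_for_three_sd_shift(self):
        hits, n_rep = 0, 300
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            vals = {"A": rng.normal(0, 1, 8), "B": rng.normal(3.0, 1, 8)}
            out = kruskal_dunn(vals, comparisons=[("A", "B")])
            hits += int(out["pairwise"][0]["p_adj"] < 0.05)
        assert hits / n_rep > 0.95

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"A": [1.0, 2.0]})
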