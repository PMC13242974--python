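"""Statistics battery vs independent oracles (scipy, pingouin, brute force)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octstiff.stats import (analysis_report, cohens_d, icc_two_way_mixed,
                            lsd_posthoc, oneway_anova, pearson,
                            significance_pattern, students_t,
                            synthetic_stiffness_table)


def _random_groups(rng, k=3, nmin=5, nmax=20):
    return [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                       rng.integers(nmin, nmax + 1)) for _ in range(k)]


class TestOnewayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        f, p, _, _ = oneway_anova([[1, 2, 3]] * 3)
        assert f == 0 and p == 1

    def test_hand_expanded_toy(self):
        # groups {1,2},{3,4},{5,6}: SSB = 16, MSB = 8, MSW = 0.5 -> F = 16
        f, p, msw, dfw = oneway_anova([[1, 2], [3, 4], [5, 6]])
        assert f == pytest.approx(16.0)
        assert msw == pytest.approx(0.5)
        assert dfw == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_on_random_inputs(self, seed):
        gs = _random_groups(np.random.default_rng(seed))
        f, p, _, _ = oneway_anova(gs)
        ref = sps.f_oneway(*gs)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        f, pf, _, _ = oneway_anova([x, y])
        t, pt, _ = students_t(x, y)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert pf == pytest.approx(pt, rel=1e-10)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0], [2, 3]])

    def test_null_type_one_error_calibrated(self):
        # 10 000 null replicates of 3 normal groups, n = 14 each
        rng = np.random.default_rng(77)
        rejections = 0
        for _ in range(10_000):
            gs = rng.normal(0, 1, (3, 14))
            _, p, _, _ = oneway_anova(gs)
            rejections += p < 0.05
        assert 0.04 <= rejections / 10_000 <= 0.06


class TestLsdPosthoc:
    def test_identical_pair_not_significant(self):
        gs = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        _, _, msw, dfw = oneway_anova(gs)
        row = lsd_posthoc(gs, msw, dfw).iloc[0]
        assert row["mean_diff"] == 0 and row["p"] == 1

    def test_hand_computed_t(self):
        # {1,2} vs {3,4} with MSW = 0.5, n = 2 each: t = -2 / sqrt(0.5) = -2.828
        gs = [[1, 2], [3, 4]]
        row = lsd_posthoc(gs, 0.5, 4).iloc[0]
        assert row["t"] == pytest.approx(-2 / np.sqrt(0.5), rel=1e-10)

    def test_two_group_lsd_equals_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        _, _, msw, dfw = oneway_anova([x, y])
        row = lsd_posthoc([x, y], msw, dfw).iloc[0]
        t, p, _ = students_t(x, y)
        assert row["t"] == pytest.approx(t, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_all_pairs_enumerated(self, rng):
        gs = _random_groups(rng, k=4)
        _, _, msw, dfw = oneway_anova(gs)
        assert len(lsd_posthoc(gs, msw, dfw)) == 6


class TestStudentsT:
    def test_identical_samples(self):
        t, p, diff = students_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1 and diff == 0

    def test_hand_computed(self):
        t, _, diff = students_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(3 / 2), rel=1e-10)
        assert diff == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_pooled(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(0, 1, 12), r.normal(0.3, 1.4, 15)
        t, p, _ = students_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(88)
        rejections = 0
        for _ in range(10_000):
            x, y = rng.normal(0, 1, 14), rng.normal(0, 1, 14)
            _, p, _ = students_t(x, y)
            rejections += p < 0.05
        assert 0.04 <= rejections / 10_000 <= 0.06


class TestIcc:
    def test_identical_columns_give_unity(self):
        v = np.arange(1.0, 9.0)
        res = icc_two_way_mixed(np.column_stack([v, v, v]))
        assert res.icc_single == pytest.approx(1.0)
        assert res.icc_average == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        m = np.random.default_rng(5).normal(size=(200, 6))
        res = icc_two_way_mixed(m)
        assert abs(res.icc_single) < 0.05

    def test_spearman_brown_step_up(self, rng):
        m = rng.normal(size=(20, 6)) + rng.normal(size=(20, 1))
        res = icc_two_way_mixed(m)
        k, rho = m.shape[1], res.icc_single
        assert res.icc_average == pytest.approx(
            k * rho / (1 + (k - 1) * rho), rel=1e-10)

    def test_single_le_average_when_positive(self, rng):
        m = rng.normal(size=(15, 4)) + 0.8 * rng.normal(size=(15, 1))
        res = icc_two_way_mixed(m)
        assert 0 <= res.icc_single <= res.icc_average

    def test_ci_brackets_estimate(self, rng):
        m = rng.normal(size=(14, 6)) + 0.5 * rng.normal(size=(14, 1))
        res = icc_two_way_mixed(m)
        assert res.ci_single[0] <= res.icc_single <= res.ci_single[1]
        assert res.ci_average[0] <= res.icc_average <= res.ci_average[1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_icc3(self, seed):
        pg = pytest.importorskip("pingouin")
        r = np.random.default_rng(seed)
        m = r.normal(size=(12, 5)) + r.normal(size=(12, 1))
        res = icc_two_way_mixed(m)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 5),
            "rater": np.tile(np.arange(5), 12),
            "score": m.ravel()})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        single = "ICC3" if "ICC3" in ref.index else "ICC(C,1)"
        average = "ICC3k" if "ICC3k" in ref.index else "ICC(C,k)"
        assert res.icc_single == pytest.approx(ref.loc[single, "ICC"], rel=1e-8)
        assert res.icc_average == pytest.approx(ref.loc[average, "ICC"], rel=1e-8)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        np.testing.assert_allclose(res.ci_single, ref.loc[single, ci_col],
                                   atol=1e-2)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(ValueError):
            icc_two_way_mixed(m)


class TestCohensD:
    def test_identical_samples_give_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).cohens_d == 0

    def test_hand_computed(self):
        es = cohens_d([0, 2], [1, 3])
        assert es.cohens_d == pytest.approx(-1 / np.sqrt(2), rel=1e-10)
        assert es.mean_difference == pytest.approx(-1.0)

    def test_large_sample_recovery_of_unit_shift(self):
        r = np.random.default_rng(1)
        es = cohens_d(r.normal(1, 1, 10_000), r.normal(0, 1, 10_000))
        assert 0.95 <= es.cohens_d <= 1.05

    def test_mean_difference_ci_brackets_estimate(self, rng):
        es = cohens_d(rng.normal(0, 1, 14), rng.normal(0.5, 1, 14))
        assert es.ci95[0] <= es.mean_difference <= es.ci95[1]

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        r = np.random.default_rng(3)
        x, y = r.normal(0, 1, 15), r.normal(0.7, 1.2, 12)
        es = cohens_d(x, y)
        assert es.cohens_d == pytest.approx(
            pg.compute_effsize(x, y, eftype="cohen"), rel=1e-10)

    def test_zero_variance_unequal_means_undefined(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1, 1], [2, 2, 2])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed(self):
        r, _ = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy(self, seed):
        g = np.random.default_rng(seed)
        x = g.normal(0, 1, 20)
        y = 0.5 * x + g.normal(0, 1, 20)
        r, p = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])


class TestAnalysisReport:
    def test_report_tables_present_and_flagged(self):
        table = synthetic_stiffness_table(seed=0)
        report = analysis_report(table)
        for key in ("location_ttests", "status_anova", "icc",
                    "effect_by_status", "effect_by_location",
                    "device_correlation"):
            assert not report[key].empty, key
        assert set(report["status_anova"]["sig"]) <= {"", "*", "**"}
        # devices correlate strongly by construction
        assert (report["device_correlation"]["r"] > 0.8).all()

    def test_expected_significance_pattern_reproduced(self):
        report = analysis_report(synthetic_stiffness_table(seed=0))
        assert significance_pattern(report)

    def test_single_status_skips_anova_with_warning(self):
        table = synthetic_stiffness_table(seed=0)
        table = table[table.status == "wound"]
        report = analysis_report(table)
        assert report["status_anova"].empty
        assert report["warnings"]

    def test_duplicate_rows_rejected(self):
        table = synthetic_stiffness_table(seed=0)
        dup = pd.concat([table, table.iloc[[0]]])
        with pytest.raises(ValueError):
            analysis_report(dup)


class TestSyntheticTable:
    def test_schema_and_determinism(self):
        a = synthetic_stiffness_table(seed=4)
        b = synthetic_stiffness_table(seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 14 * 2 * 3 * 2
        assert (a.k_value > 0).all()

    def test_wound_exceeds_normal_on_average(self):
        t = synthetic_stiffness_table(seed=2)
        oct_t = t[t.device == "oct"]
        means = oct_t.groupby("status")["k_value"].mean()
        assert means["wound"] > means["normal"]
        assert means["wound"] > means["after"]
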