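"""Statistical battery: ANOVA+Tukey, chi-squared, Kruskal+Dunn, adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from contactlayouts import (
    CohortSpec,
    ParticipantProfile,
    StudyConfig,
    adjust_pvalues,
    anova_tukey,
    kruskal_dunn,
    pairwise_chi2,
    run_full_analysis,
    simulate_study,
)
from contactlayouts.metrics import SchemaError


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03]) == pytest.approx([0.03])

    def test_bh_worked_example(self):
        # step-up: p_(i) * m / i, cumulative minimum from the largest rank
        adj = adjust_pvalues([0.01, 0.02, 0.03], method="bh")
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_against_direct_step_up(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        # independent step-up computation
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        assert adjust_pvalues(p, "bh") == pytest.approx(expected)

    def test_equal_ps_unchanged_under_bh(self):
        assert adjust_pvalues([0.2, 0.2, 0.2], "bh") == pytest.approx([0.2] * 3)

    def test_bonferroni_and_holm(self):
        assert adjust_pvalues([0.01, 0.4], "bonferroni") == pytest.approx([0.02, 0.8])
        assert adjust_pvalues([0.01, 0.4], "holm") == pytest.approx([0.02, 0.4])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], method="sidak")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.sampled_from(["bh", "holm", "bonferroni"]))
    @settings(max_examples=80, deadline=None)
    def test_adjusted_never_below_raw(self, p, method):
        adj = adjust_pvalues(p, method)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestAnovaTukey:
    def test_identical_groups_degenerate(self):
        omni, pairs = anova_tukey({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1]})
        assert omni.statistic == 0.0
        assert omni.p_raw == 1.0
        assert all(p.p_adjusted == 1.0 for p in pairs)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(1)
        g1 = rng.normal(0.0, 1.0, 50)
        g2 = rng.normal(10.0, 1.0, 50)  # 10 SDs apart
        omni, pairs = anova_tukey({"a": g1, "b": g2})
        assert pairs[0].p_adjusted < 1e-6
        assert pairs[0].significant

    def test_group_order_invariance(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 20) for i, k in enumerate("abc")}
        omni1, _ = anova_tukey(groups)
        omni2, _ = anova_tukey(dict(reversed(list(groups.items()))))
        assert omni1.statistic == pytest.approx(omni2.statistic)
        assert omni1.p_raw == pytest.approx(omni2.p_raw)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(0, 1, 15) for k in "abc"}
        omni, _ = anova_tukey(groups)
        f, p = stats.f_oneway(*groups.values())
        assert omni.statistic == pytest.approx(f)
        assert omni.p_raw == pytest.approx(p)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1, 2, 3]})


class TestPairwiseChi2:
    def test_balanced_table_is_null(self):
        results = pairwise_chi2({"a": (50, 50), "b": (50, 50)})
        assert results[0].statistic == pytest.approx(0.0)
        assert results[0].p_raw == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # [[90,10],[10,90]]: all expected cells 50, chi2 = 4 * 40^2 / 50 = 128
        results = pairwise_chi2({"a": (90, 10), "b": (10, 90)})
        assert results[0].statistic == pytest.approx(128.0)

    def test_row_swap_symmetry(self):
        r1 = pairwise_chi2({"a": (80, 20), "b": (60, 40)})
        r2 = pairwise_chi2({"b": (60, 40), "a": (80, 20)})
        assert r1[0].statistic == pytest.approx(r2[0].statistic)

    def test_zero_margin_not_applicable(self):
        results = pairwise_chi2({"a": (0, 0), "b": (10, 10)})
        assert math.isnan(results[0].statistic)
        assert not results[0].significant
        assert "not applicable" in results[0].note

    def test_three_groups_adjusted_across_pairs(self):
        results = pairwise_chi2({"a": (90, 10), "b": (85, 15), "c": (50, 50)})
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-12


class TestKruskalDunn:
    def test_identical_values_degenerate(self):
        omni, pairs = kruskal_dunn({"a": [2, 2], "b": [2, 2, 2]})
        assert omni.statistic == 0.0
        assert omni.p_raw == 1.0
        assert all(p.p_raw == 1.0 for p in pairs)

    def test_shift_is_detected(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 100),
            "b": rng.normal(0, 1, 100),
            "c": rng.normal(5, 1, 100),
        }
        omni, pairs = kruskal_dunn(groups)
        assert omni.p_raw < 1e-4
        shifted = [p for p in pairs if "c" in p.groups]
        assert all(p.p_adjusted < 1e-4 for p in shifted)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.uniform(0.1, 2.0, 25) for k in "abc"}
        omni1, pairs1 = kruskal_dunn(groups)
        omni2, pairs2 = kruskal_dunn({k: np.log(v) for k, v in groups.items()})
        assert omni1.statistic == pytest.approx(omni2.statistic)
        for p1, p2 in zip(pairs1, pairs2):
            assert p1.statistic == pytest.approx(p2.statistic)

    def test_two_group_dunn_z_matches_kruskal_h(self):
        # with exactly two groups the Dunn z statistic satisfies z^2 = H
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(1, 1, 40)}
        omni, (pair,) = kruskal_dunn(groups)
        assert pair.statistic**2 == pytest.approx(omni.statistic)

    def test_hand_computed_tiny_example(self):
        # groups [1,2], [3,4], [5,6]: mean ranks 1.5, 3.5, 5.5, no ties;
        # var_base = 6*7/12 = 3.5, se = sqrt(3.5) -> z_ab = -2/1.8708 = -1.069
        _, pairs = kruskal_dunn({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        z_ab = next(p for p in pairs if p.groups == ("a", "b"))
        assert z_ab.statistic == pytest.approx(-2 / math.sqrt(3.5))

    def test_tie_correction_matches_scipy_omnibus(self):
        groups = {"a": [1, 1, 2, 3], "b": [2, 2, 3, 3], "c": [1, 3, 3, 4]}
        omni, _ = kruskal_dunn(groups)
        h, p = stats.kruskal(*groups.values())
        assert omni.statistic == pytest.approx(h)
        assert omni.p_raw == pytest.approx(p)


class TestRunFullAnalysis:
    def test_report_structure(self, small_table):
        report = run_full_analysis(small_table)
        expected = {
            "participant_summaries", "participant_exclusions",
            "filter_rt_removals", "consistency_tests", "accuracy_counts",
            "accuracy_tests", "response_time_tests", "response_time_means",
            "learning_curves", "learning_curve_tests", "error_fractions",
            "intersegment_distance_errors", "min_distance_all",
        }
        assert expected <= set(report.tables)
        curves = report.tables["learning_curves"]
        assert (curves.groupby("layout")["rank"].max() == 15).all()

    def test_adjusted_never_below_raw_everywhere(self, small_table):
        report = run_full_analysis(small_table)
        for name, df in report.tables.items():
            if "p_raw" in df.columns:
                ok = df["p_adjusted"].isna() | (df["p_adjusted"] >= df["p_raw"] - 1e-12)
                assert ok.all(), name

    def test_deterministic_given_table(self, small_table):
        r1 = run_full_analysis(small_table)
        r2 = run_full_analysis(small_table)
        for name in r1.tables:
            assert r1.tables[name].equals(r2.tables[name]), name

    def test_empty_table_raises(self, small_table):
        with pytest.raises(SchemaError):
            run_full_analysis(small_table.iloc[0:0])

    def test_accuracy_power_at_study_scale(self):
        cohorts = [
            CohortSpec("circular", 50, ParticipantProfile(p_correct=0.95)),
            CohortSpec("matrix", 50, ParticipantProfile(p_correct=0.75)),
        ]
        table = simulate_study(cohorts, StudyConfig(), seed=8)
        report = run_full_analysis(table)
        acc = report.tables["accuracy_tests"]
        assert acc["significant"].all()

    def test_type_one_error_calibrated_under_null(self):
        """With identical profiles in every layout arm, each test family
        should flag a difference in at most ~alpha of replicates."""
        profile = ParticipantProfile(p_correct=0.85, memory=0.7)
        families = {
            "consistency_tests": 0, "accuracy_tests": 0,
            "response_time_tests": 0, "min_distance_tests": 0,
        }
        n_rep = 40
        for rep in range(n_rep):
            cohorts = [CohortSpec(lay, 12, profile)
                       for lay in ("circular", "half_matrix", "matrix")]
            table = simulate_study(cohorts, StudyConfig(), seed=1000 + rep)
            report = run_full_analysis(table)
            for fam in families:
                if fam not in report.tables:
                    continue
                df = report.tables[fam]
                pairwise = df[df["method"].isin(["tukey_hsd", "chi2_independence", "dunn"])]
                if pairwise["significant"].any():
                    families[fam] += 1
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)
        for fam, hits in families.items():
            assert hits / n_rep <= bound, (fam, hits)

    def test_report_write(self, small_table, tmp_path):
        report = run_full_analysis(small_table)
        report.write(tmp_path / "report", figures=True)
        out = tmp_path / "report"
        assert (out / "summary.txt").exists()
        assert (out / "consistency_tests.csv").exists()
        assert (out / "overview.svg").exists()
        assert (out / "errors.svg").exists()
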