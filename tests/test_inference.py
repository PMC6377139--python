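import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import bh_step_up
from covgraph._util import ValidationError
from covgraph.cohort import ROIVolumeTable, generate_cohort
from covgraph.inference import (
    PermutationConfig,
    bh_fdr,
    compare_global_metric,
    compare_regional_clustering,
    compare_resilience,
    pearson_chi2_2x2,
    permute_group_labels,
    t_test_from_summary,
)
from covgraph.network import DensityGrid

GRID = DensityGrid(0.1, 0.5, 0.1)


def two_group_table(rng, n_c=10, n_p=10, n_rois=8, shift=0.0):
    rows = n_c + n_p
    vols = rng.normal(100, 10, size=(rows, n_rois))
    vols[n_c:] += shift
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(rows)],
        "group": ["control"] * n_c + ["patient"] * n_p,
    })
    rois = [f"R{j}" for j in range(n_rois)]
    df[rois] = vols
    return ROIVolumeTable(df, rois)


class TestPermuteGroupLabels:
    def test_group_sizes_preserved(self, rng):
        t = two_group_table(rng, n_c=33, n_p=35)
        out = permute_group_labels(t, 0)
        counts = out.data["group"].value_counts()
        assert counts["control"] == 33
        assert counts["patient"] == 35

    def test_both_relabelings_reachable_for_1v1(self, rng):
        t = two_group_table(rng, n_c=1, n_p=1)
        seen = set()
        for seed in range(20):
            out = permute_group_labels(t, seed)
            seen.add(tuple(out.data["group"]))
        assert seen == {("control", "patient"), ("patient", "control")}

    def test_same_seed_identical(self, rng):
        t = two_group_table(rng)
        a = permute_group_labels(t, 7)
        b = permute_group_labels(t, 7)
        assert list(a.data["group"]) == list(b.data["group"])

    def test_rows_untouched(self, rng):
        t = two_group_table(rng)
        out = permute_group_labels(t, 3)
        np.testing.assert_array_equal(out.volumes(), t.volumes())


class TestBhFdr:
    def test_worked_example(self):
        flags = bh_fdr([0.001, 0.02, 0.03, 0.2], q=0.05)
        np.testing.assert_array_equal(flags, [True, True, True, False])

    def test_all_ones(self):
        assert not bh_fdr(np.ones(6), q=0.05).any()

    def test_single_small_p(self):
        np.testing.assert_array_equal(bh_fdr([0.04], q=0.05), [True])

    def test_empty(self):
        assert bh_fdr([], q=0.05).shape == (0,)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2], q=0.05)

    def test_matches_exhaustive_definition(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 11))
            p = rng.random(m)
            q = float(rng.choice([0.01, 0.05, 0.1, 0.25]))
            np.testing.assert_array_equal(bh_fdr(p, q), bh_step_up(p, q))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 12)))
            ours = bh_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, ref)


class TestDemographics:
    def test_identical_summaries(self):
        t, p = t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_printed_age_summaries(self):
        # group summaries: 33 at 26.4 +- 7.4 vs 35 at 27.2 +- 6.3
        _, p = t_test_from_summary(26.4, 7.4, 33, 27.2, 6.3, 35)
        assert p == pytest.approx(0.64, abs=0.01)

    def test_matches_scipy_from_stats(self):
        t, p = t_test_from_summary(26.4, 7.4, 33, 27.2, 6.3, 35)
        ref = stats.ttest_ind_from_stats(26.4, 7.4, 33, 27.2, 6.3, 35)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_larger_samples_decrease_p(self):
        _, p1 = t_test_from_summary(10.0, 2.0, 20, 10.5, 2.0, 20)
        _, p2 = t_test_from_summary(10.0, 2.0, 40, 10.5, 2.0, 40)
        assert p2 < p1

    def test_input_guards(self):
        with pytest.raises(ValidationError):
            t_test_from_summary(1.0, 1.0, 1, 2.0, 1.0, 5)
        with pytest.raises(ValidationError):
            t_test_from_summary(1.0, 0.0, 5, 2.0, 1.0, 5)

    def test_chi2_balanced_table(self):
        chi2, p = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_printed_sex_counts(self):
        # 25 women / 8 men vs 26 women / 9 men
        _, p = pearson_chi2_2x2([[25, 8], [26, 9]])
        assert round(p, 2) == 0.89

    def test_matches_scipy_without_correction(self, rng):
        for _ in range(20):
            c = rng.integers(1, 40, size=(2, 2))
            chi2, p = pearson_chi2_2x2(c)
            ref = stats.chi2_contingency(c, correction=False)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_scaling_counts_scales_statistic(self):
        chi2_1, _ = pearson_chi2_2x2([[25, 8], [26, 9]])
        chi2_10, _ = pearson_chi2_2x2([[250, 80], [260, 90]])
        assert chi2_10 == pytest.approx(10 * chi2_1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            pearson_chi2_2x2([[0, 0], [5, 5]])


class TestCompareGlobalMetric:
    def test_identical_groups_give_zero_observed(self, rng):
        vols = rng.normal(100, 10, size=(10, 6))
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(20)],
            "group": ["control"] * 10 + ["patient"] * 10,
        })
        rois = [f"R{j}" for j in range(6)]
        df[rois] = np.vstack([vols, vols])  # same subjects copied into both
        t = ROIVolumeTable(df, rois)
        cfg = PermutationConfig(n_permutations=30, seed=0)
        r = compare_global_metric(t, "clustering", GRID, cfg)
        assert r.observed == pytest.approx(0.0, abs=1e-12)

    def test_p_value_never_zero_and_floor(self, rng):
        t = two_group_table(rng)
        cfg = PermutationConfig(n_permutations=40, seed=1)
        r = compare_global_metric(t, "clustering", GRID, cfg)
        assert 1 / 41 <= r.p_value <= 1.0
        assert len(r.null_sample) == 40

    def test_observed_beating_every_null(self, rng):
        t = two_group_table(rng)
        cfg = PermutationConfig(n_permutations=25, seed=2)
        r = compare_global_metric(t, "clustering", GRID, cfg)
        if (r.null_sample < r.observed).all():
            assert r.p_value == pytest.approx(1 / 26)

    def test_label_exchange_flips_sign_and_two_tailed_invariant(self, rng):
        t = two_group_table(rng, n_c=8, n_p=8)
        swapped = t.with_group_labels(
            ["patient" if g == "control" else "control"
             for g in t.data["group"]])
        cfg = PermutationConfig(n_permutations=60, seed=4, tails="two")
        r1 = compare_global_metric(t, "clustering", GRID, cfg)
        r2 = compare_global_metric(swapped, "clustering", GRID, cfg)
        assert r2.observed == pytest.approx(-r1.observed, rel=1e-9)
        assert r2.p_value == pytest.approx(r1.p_value)

    def test_one_tailed_directions_are_complementary(self, rng):
        t = two_group_table(rng, n_c=8, n_p=8)
        kw = dict(n_permutations=60, seed=4)
        pg = compare_global_metric(
            t, "clustering", GRID,
            PermutationConfig(direction="control_gt_patient", **kw)).p_value
        pl = compare_global_metric(
            t, "clustering", GRID,
            PermutationConfig(direction="patient_gt_control", **kw)).p_value
        # same null sample; counts of >= and <= overlap only on ties
        assert 1.0 + 1 / 61 <= pg + pl <= 1.0 + 2 / 61 + 1e-12

    def test_reproducible_with_seed(self, rng):
        t = two_group_table(rng)
        cfg = PermutationConfig(n_permutations=20, seed=5)
        r1 = compare_global_metric(t, "path_length", GRID, cfg)
        r2 = compare_global_metric(t, "path_length", GRID, cfg)
        np.testing.assert_array_equal(r1.null_sample, r2.null_sample)
        assert r1.p_value == r2.p_value

    def test_per_density_p_values(self, rng):
        t = two_group_table(rng)
        cfg = PermutationConfig(n_permutations=20, seed=6,
                                statistic="per_density_difference")
        r = compare_global_metric(t, "clustering", GRID, cfg)
        assert r.per_density_p is not None
        assert len(r.per_density_p) == len(GRID.values)
        assert np.all((r.per_density_p > 0) & (r.per_density_p <= 1))

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(ValidationError):
            compare_global_metric(two_group_table(rng), "sigma_prime", GRID,
                                  PermutationConfig(n_permutations=10))

    def test_degenerate_relabelings_are_redrawn(self, rng):
        # one ROI is binary-valued: some relabelings make it constant
        vols = rng.normal(100, 10, size=(8, 3))
        vols[:, 0] = [1, 1, 2, 2, 1, 1, 2, 2]  # constant under some relabelings
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "group": ["control"] * 4 + ["patient"] * 4,
        })
        rois = ["R0", "R1", "R2"]
        df[rois] = vols
        t = ROIVolumeTable(df, rois)
        cfg = PermutationConfig(n_permutations=100, seed=3)
        r = compare_global_metric(t, "clustering", DensityGrid(0.3, 0.5, 0.1), cfg)
        assert r.n_redraws > 0          # the all-equal split must have occurred
        assert len(r.null_sample) == 100


class TestCompareResilience:
    def test_identical_groups_zero_observed(self, rng):
        vols = rng.normal(100, 10, size=(8, 6))
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(16)],
            "group": ["control"] * 8 + ["patient"] * 8,
        })
        rois = [f"R{j}" for j in range(6)]
        df[rois] = np.vstack([vols, vols])
        t = ROIVolumeTable(df, rois)
        cfg = PermutationConfig(n_permutations=15, seed=0)
        r = compare_resilience(t, GRID, "targeted_betweenness", cfg)
        assert r.observed == pytest.approx(0.0, abs=1e-12)
        assert r.metric_name == "resilience_targeted_betweenness"

    def test_random_attack_kind_runs(self, rng):
        t = two_group_table(rng, n_c=6, n_p=6, n_rois=6)
        cfg = PermutationConfig(n_permutations=10, seed=1)
        r = compare_resilience(t, GRID, "random", cfg, n_random_sequences=5)
        assert 0 < r.p_value <= 1.0

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValidationError):
            compare_resilience(two_group_table(rng), GRID, "edge_removal",
                               PermutationConfig(n_permutations=10))


class TestCompareRegionalClustering:
    def test_result_shapes_and_flags(self, rng):
        t = two_group_table(rng, n_rois=6)
        cfg = PermutationConfig(n_permutations=30, seed=2,
                                direction="patient_gt_control")
        r = compare_regional_clustering(t, GRID, cfg)
        assert len(r.p_values) == 6
        assert len(r.observed_diffs) == 6
        np.testing.assert_array_equal(r.fdr_significant,
                                      bh_step_up(r.p_values, 0.05))

    def test_too_few_rois_rejected(self, rng):
        t = two_group_table(rng, n_rois=1)
        with pytest.raises(ValidationError):
            compare_regional_clustering(t, GRID,
                                        PermutationConfig(n_permutations=10))

    def test_reproducible(self, rng):
        t = two_group_table(rng, n_rois=5)
        cfg = PermutationConfig(n_permutations=25, seed=8)
        r1 = compare_regional_clustering(t, GRID, cfg)
        r2 = compare_regional_clustering(t, GRID, cfg)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)


def test_permutation_config_validation():
    with pytest.raises(ValidationError):
        PermutationConfig(n_permutations=0)
    with pytest.raises(ValidationError):
        PermutationConfig(tails="three")
    with pytest.raises(ValidationError):
        PermutationConfig(statistic="median_difference")
    with pytest.raises(ValidationError):
        PermutationConfig(direction="sideways")


def test_compare_on_generated_cohort(small_spec):
    table = generate_cohort(small_spec)
    cfg = PermutationConfig(n_permutations=30, seed=9)
    r = compare_global_metric(table, "clustering", GRID, cfg)
    assert 0 < r.p_value <= 1
    assert r.control_curve.shape == r.patient_curve.shape == GRID.values.shape
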