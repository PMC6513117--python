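"""Modularity optimizer: oracle checks, sign contrast, consensus, hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from funcsig import (
    ModularityMatrix,
    benchmark_config,
    co_classification,
    consensus_partition,
    detect_hierarchy,
    detect_modules,
    filter_correlation,
    generate_grouped_oscillators,
    generate_pure_noise,
    hierarchy_labels,
    modularity_score,
    optimize_partition,
    pearson_correlation,
)

from conftest import brute_force_best, iter_partitions

TWO_BLOCK = np.array(
    [
        [1.0, 0.5, -0.5, -0.5],
        [0.5, 1.0, -0.5, -0.5],
        [-0.5, -0.5, 1.0, 0.5],
        [-0.5, -0.5, 0.5, 1.0],
    ]
)


class TestModularityScore:
    def test_zero_matrix_scores_zero_for_any_partition(self):
        b = ModularityMatrix(np.zeros((4, 4)), c_norm=4.0)
        for labels in ([0, 0, 0, 0], [0, 1, 2, 3], [0, 0, 1, 1]):
            assert modularity_score(b, np.array(labels)) == 0.0

    def test_all_in_one_partition_sums_everything(self):
        b = ModularityMatrix(TWO_BLOCK, c_norm=4.0)
        expected = TWO_BLOCK.sum() / 4.0
        assert modularity_score(b, np.zeros(4, dtype=int)) == pytest.approx(expected)

    def test_planted_split_is_exhaustive_argmax(self):
        # brute force over all 15 partitions of 4 elements
        b = ModularityMatrix(TWO_BLOCK, c_norm=4.0)
        scores = {
            tuple(labels): modularity_score(b, labels)
            for labels in iter_partitions(4)
        }
        assert len(scores) == 15
        best = max(scores, key=scores.get)
        assert best == (0, 0, 1, 1)
        assert scores[best] == pytest.approx((4 * 1.0 + 4 * 0.5) / 4.0)  # = 1.5


class TestOptimizePartition:
    def test_recovers_planted_two_block_split(self):
        p = optimize_partition(ModularityMatrix(TWO_BLOCK, c_norm=4.0), seed=0,
                               n_restarts=5)
        assert p.n_modules == 2
        assert p.labels[0] == p.labels[1] and p.labels[2] == p.labels[3]
        assert p.significant

    def test_zero_matrix_flags_no_significant_structure(self):
        p = optimize_partition(ModularityMatrix(np.zeros((6, 6)), c_norm=6.0), seed=0)
        assert p.n_modules == 1 and not p.significant

    def test_all_positive_matrix_yields_single_module(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.1, 1.0, size=(8, 8))
        b = (b + b.T) / 2
        p = optimize_partition(ModularityMatrix(b, c_norm=8.0), seed=1, n_restarts=5)
        assert p.n_modules == 1

    def test_matches_exhaustive_enumeration_on_small_filtered_matrices(self):
        # optimizer vs brute force over all set partitions, n <= 8 here
        # (the full n <= 10 sweep runs in the acceptance suite)
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(5, 9))
            half = n // 2
            cfg = benchmark_config(
                n_groups=2,
                group_sizes=(half, n - half),
                n_timepoints=60,
                group_phase_offsets=(0.0, np.pi),
                noise_sd=0.4,
                seed=int(rng.integers(0, 2**31)),
            )
            rec, _ = generate_grouped_oscillators(cfg)
            filt, _, _ = filter_correlation(pearson_correlation(rec))
            b = ModularityMatrix(filt.c_filtered, c_norm=1.0)
            p = optimize_partition(b, seed=int(rng.integers(0, 2**31)), n_restarts=10)
            best_w, _ = brute_force_best(b.matrix)
            assert p.modularity == pytest.approx(best_w, abs=1e-9)

    def test_returned_q_beats_trivial_partitions(self, detection_with_trend):
        b = detection_with_trend.modularity_matrix
        p = detection_with_trend.partition
        assert p.modularity >= modularity_score(b, np.zeros(b.n, dtype=int)) - 1e-12
        assert p.modularity >= modularity_score(b, np.arange(b.n)) - 1e-12

    def test_sign_contrast_guarantee(self, detection_with_trend, detection_no_trend):
        for res in (detection_with_trend, detection_no_trend):
            b = res.modularity_matrix.matrix
            labels = res.partition.labels
            for m in range(res.partition.n_modules):
                members = np.flatnonzero(labels == m)
                if len(members) > 1:
                    assert b[np.ix_(members, members)].sum() > 0
            for m in range(res.partition.n_modules):
                for m2 in range(m + 1, res.partition.n_modules):
                    between = b[np.ix_(labels == m, labels == m2)].sum()
                    assert between <= 1e-9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        b = TWO_BLOCK + rng.normal(0, 0.01, (4, 4))
        b = (b + b.T) / 2
        perm = np.array([2, 0, 3, 1])
        p1 = optimize_partition(ModularityMatrix(b, 4.0), seed=3, n_restarts=10)
        p2 = optimize_partition(
            ModularityMatrix(b[np.ix_(perm, perm)], 4.0), seed=3, n_restarts=10
        )
        assert adjusted_rand_score(p1.labels[perm], p2.labels) == 1.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_optimum_is_merge_stable_and_within_positive(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        v = rng.normal(size=(n, 2))
        b = v @ v.T  # random rank-2 "filtered" matrix
        p = optimize_partition(ModularityMatrix(b, float(n)), seed=seed, n_restarts=5)
        labels = p.labels
        for m in range(p.n_modules):
            members = np.flatnonzero(labels == m)
            if len(members) > 1:
                assert b[np.ix_(members, members)].sum() > 0
            for m2 in range(m + 1, p.n_modules):
                assert b[np.ix_(labels == m, labels == m2)].sum() <= 1e-9


class TestCoClassification:
    def test_single_run_is_binary(self):
        b = ModularityMatrix(TWO_BLOCK, c_norm=4.0)
        f = co_classification(b, n_runs=1, base_seed=0)
        assert set(np.unique(f.frequencies)) <= {0.0, 1.0}

    def test_unique_optimum_gives_binary_frequencies(self):
        b = ModularityMatrix(TWO_BLOCK, c_norm=4.0)
        f = co_classification(b, n_runs=20, base_seed=0)
        assert f.is_binary
        assert np.all(np.diag(f.frequencies) == 1.0)
        assert np.max(np.abs(f.frequencies - f.frequencies.T)) == 0.0

    def test_benchmark_co_classification_contrast(self, detection_with_trend,
                                                  benchmark_with_trend):
        # scaled-down version of the 1000-run likelihood matrices
        _, gt = benchmark_with_trend
        f = co_classification(detection_with_trend.modularity_matrix,
                              n_runs=30, base_seed=100).frequencies
        same = gt.labels[:, None] == gt.labels[None, :]
        off = ~np.eye(len(gt.labels), dtype=bool)
        assert f[same & off].mean() > 0.95
        assert f[~same].mean() < 0.05


class TestConsensus:
    def test_binary_block_matrix_is_fixed_point(self):
        from funcsig import CoClassificationMatrix

        labels = np.array([0, 0, 0, 1, 1])
        f = (labels[:, None] == labels[None, :]).astype(float)
        p = consensus_partition(CoClassificationMatrix(f, 10), seed=0)
        assert adjusted_rand_score(labels, p.labels) == 1.0

    def test_all_ones_gives_single_module(self):
        from funcsig import CoClassificationMatrix

        f = np.ones((6, 6))
        p = consensus_partition(CoClassificationMatrix(f, 10), seed=0)
        assert p.n_modules == 1

    def test_benchmark_consensus_recovers_planted_groups(
        self, detection_with_trend, benchmark_with_trend
    ):
        _, gt = benchmark_with_trend
        f = co_classification(detection_with_trend.modularity_matrix,
                              n_runs=20, base_seed=7)
        p = consensus_partition(f, seed=3)
        assert adjusted_rand_score(gt.labels, p.labels) == 1.0


class TestHierarchy:
    def test_depth_one_matches_flat_pipeline(self, benchmark_with_trend):
        rec, _ = benchmark_with_trend
        flat = detect_modules(rec, seed=9, n_restarts=10)
        root = detect_hierarchy(rec, 1, seed=9, n_restarts=10)
        assert adjusted_rand_score(flat.partition.labels,
                                   hierarchy_labels(root, 1)) == 1.0
        assert not root.children

    def test_nested_fixture_resolves_both_levels(self, nested_benchmark):
        rec, gt = nested_benchmark
        root = detect_hierarchy(rec, 2, seed=13, n_restarts=10)
        assert adjusted_rand_score(gt.labels, hierarchy_labels(root, 1)) == 1.0
        assert adjusted_rand_score(gt.sub_labels, hierarchy_labels(root, 2)) == 1.0

    def test_pure_noise_root_not_significant_without_children(self):
        rec = generate_pure_noise(60, 900, seed=2)
        root = detect_hierarchy(rec, 3, seed=2, n_restarts=5)
        if not root.partition.significant:
            assert root.partition.n_modules == 1
            assert not root.children
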