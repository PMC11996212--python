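"""Lineage reconstruction: Jaccard distances, single linkage, threshold cuts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers import make_table, overlap_components, partitions_equal, random_sets

from clonetrace.inference import (
    ANY_OVERLAP_THRESHOLD,
    build_distance_matrix,
    cut_any_overlap,
    cut_by_target_count,
    cut_min,
    infer_lineages,
    jaccard_dissimilarity,
    single_linkage_dendrogram,
)
from clonetrace.metrics import fowlkes_mallows


set_strategy = st.frozensets(st.integers(0, 20), min_size=0, max_size=6)


class TestJaccard:
    @pytest.mark.parametrize(
        "X, Y, expected",
        [
            ({7}, {7}, 0.0),
            ({1, 2}, {3, 4}, 1.0),
            ({1, 2}, {2, 3}, 2 / 3),
            ({1}, set(), 1.0),
        ],
    )
    def test_examples(self, X, Y, expected):
        assert jaccard_dissimilarity(X, Y) == pytest.approx(expected)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            jaccard_dissimilarity(set(), set())

    @given(X=set_strategy, Y=set_strategy)
    def test_bounds_symmetry_identity(self, X, Y):
        if not X and not Y:
            return
        d = jaccard_dissimilarity(X, Y)
        assert 0.0 <= d <= 1.0
        assert d == jaccard_dissimilarity(Y, X)
        if X:
            assert jaccard_dissimilarity(X, X) == 0.0
        assert (d == 0.0) == (X == Y)


class TestDistanceMatrix:
    def test_single_cell(self):
        m = build_distance_matrix(make_table([{1, 2}]))
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0.0

    def test_three_cells(self):
        m = build_distance_matrix(make_table([{1}, {1}, {2}]))
        assert m.values[0, 1] == 0.0
        assert m.values[0, 2] == 1.0
        assert m.values[1, 2] == 1.0

    def test_empty_sets_excluded_and_counted(self):
        m = build_distance_matrix(make_table([{1}, set(), {2}, set()]))
        assert m.values.shape == (2, 2)
        assert m.n_excluded == 2

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            build_distance_matrix(make_table([set(), set()]))

    def test_deterministic_cell_order(self):
        table = make_table([{1}, {2}, {3}], generations=[5, 0, 5])
        m = build_distance_matrix(table)
        assert list(m.cells["generation"]) == [0, 5, 5]
        assert list(m.cells["cell_id"]) == [1, 0, 2]

    def test_matches_brute_force(self, rng):
        sets = random_sets(rng, 50, universe=30)
        m = build_distance_matrix(make_table(sets))
        for i in range(50):
            for j in range(50):
                expected = 0.0 if i == j else jaccard_dissimilarity(sets[i], sets[j])
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestDendrogram:
    def test_all_distinct_merges_at_one(self):
        m = build_distance_matrix(make_table([{1}, {2}, {3}]))
        dend = single_linkage_dendrogram(m)
        assert np.allclose(dend.merge_heights(), 1.0)

    def test_chain_merge_heights(self):
        # d(0,1)=1/3, d(1,2)=1/2, d(0,2)=2/3: single linkage merges at 1/3, 1/2
        m = build_distance_matrix(make_table([{1, 2, 3}, {1, 2}, {2}]))
        dend = single_linkage_dendrogram(m)
        assert dend.merge_heights() == pytest.approx([1 / 3, 1 / 2])

    def test_flat_clusters_equal_graph_components(self, rng):
        # single-linkage property: clusters at height h == connected
        # components of the graph with edges {d <= h}
        sets = random_sets(rng, 30, universe=15)
        m = build_distance_matrix(make_table(sets))
        dend = single_linkage_dendrogram(m)
        for h in (0.0, 0.3, 0.6, ANY_OVERLAP_THRESHOLD):
            labels = dend.flat_clusters(h)
            n = len(sets)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if m.values[i, j] <= h:
                        parent[find(i)] = find(j)
            comps = [find(i) for i in range(n)]
            assert partitions_equal(labels, comps)

    def test_cluster_count_monotone_in_threshold(self, rng):
        sets = random_sets(rng, 40, universe=12)
        dend = single_linkage_dendrogram(build_distance_matrix(make_table(sets)))
        counts = [dend.cluster_count(h) for h in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCuts:
    def test_any_overlap_transitive_chain(self):
        table = make_table([{1}, {1, 2}, {2, 3}])
        matrix = build_distance_matrix(table)
        a = cut_any_overlap(single_linkage_dendrogram(matrix), matrix)
        assert a.n_clusters == 1

    def test_any_overlap_separates_disjoint(self):
        table = make_table([{1}, {2}, {3}])
        matrix = build_distance_matrix(table)
        a = cut_any_overlap(single_linkage_dendrogram(matrix), matrix)
        assert a.n_clusters == 3

    def test_any_overlap_component_structure(self):
        table = make_table([{1}, {1, 2}, {3}])
        matrix = build_distance_matrix(table)
        a = cut_any_overlap(single_linkage_dendrogram(matrix), matrix)
        assert a.labels[0] == a.labels[1] != a.labels[2]

    def test_min_d_groups_identical_sets(self):
        table = make_table([{1}, {1}, {2}])
        matrix = build_distance_matrix(table)
        a = cut_min(single_linkage_dendrogram(matrix), matrix)
        assert a.labels[0] == a.labels[1] != a.labels[2]

    def test_min_d_all_distinct_singletons(self):
        table = make_table([{1, 2}, {2, 3}, {3, 4}])
        matrix = build_distance_matrix(table)
        a = cut_min(single_linkage_dendrogram(matrix), matrix)
        assert a.n_clusters == 3

    def test_min_d_partial_overlap_not_merged(self):
        table = make_table([{1, 2}, {1, 2}, {1, 3}])
        matrix = build_distance_matrix(table)
        a = cut_min(single_linkage_dendrogram(matrix), matrix)
        assert a.labels[0] == a.labels[1] != a.labels[2]

    def test_target_count_n_cells_selects_zero_threshold(self, rng):
        sets = random_sets(rng, 12, universe=50)  # large universe: distinct sets
        matrix = build_distance_matrix(make_table(sets))
        a = cut_by_target_count(single_linkage_dendrogram(matrix), matrix, target=12)
        assert a.threshold == 0.0

    def test_target_count_one_selects_largest_merge(self):
        table = make_table([{1, 2}, {2, 3}, {3, 4}])
        matrix = build_distance_matrix(table)
        a = cut_by_target_count(single_linkage_dendrogram(matrix), matrix, target=1)
        assert a.n_clusters == 1

    def test_target_count_recovers_engineered_components(self, rng):
        # 4 disjoint overlap-components of 5 cells each, target=4
        sets = []
        truth = []
        for comp in range(4):
            base = 100 * comp
            for k in range(5):
                sets.append({base, base + k + 1})
                truth.append(comp)
        order = rng.permutation(len(sets))
        sets = [sets[i] for i in order]
        truth = [truth[i] for i in order]
        matrix = build_distance_matrix(make_table(sets))
        a = cut_by_target_count(single_linkage_dendrogram(matrix), matrix, target=4)
        assert a.n_clusters == 4
        # cells end up grouped exactly by engineered component
        reorder = matrix.cells["cell_id"].to_numpy()
        assert partitions_equal(a.labels, [truth[i] for i in reorder])

    def test_target_count_invalid(self, rng):
        matrix = build_distance_matrix(make_table([{1}, {2}]))
        with pytest.raises(ValueError):
            cut_by_target_count(single_linkage_dendrogram(matrix), matrix, target=0)


class TestInferLineages:
    def test_requires_truth_count_for_true_count_strategy(self):
        with pytest.raises(ValueError):
            infer_lineages(make_table([{1}, {2}]), "true_count")

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            infer_lineages(make_table([{1}]), "complete_linkage")

    def test_all_empty_table_errors(self):
        with pytest.raises(ValueError):
            infer_lineages(make_table([set(), set()]), "any_overlap")

    def test_disjoint_sets_recovered_by_all_strategies(self):
        sets = [{1}, {1}, {2, 3}, {2, 3}, {4}]
        truth = [0, 0, 1, 1, 2]
        for strategy in ("any_overlap", "min_d", "true_count"):
            a = infer_lineages(make_table(sets), strategy, truth_count=3)
            assert partitions_equal(a.labels, truth)

    def test_strategies_coincide_at_low_moi_high_complexity(self):
        # at M ~ 0.25 and B/S = 100 the distance matrix is mostly binary, so
        # the three threshold strategies agree almost everywhere
        from clonetrace.experiment import run_pipeline  # noqa: F401  (pipeline pieces below)
        from clonetrace.integration import BarcodePool, integrate_uniform
        from clonetrace.measurement import observe_trajectory
        from clonetrace.metrics import true_propagated_lineages
        from clonetrace.propagation import PropagationConfig, propagate

        S, B, M = 300, 30000, 0.25
        agreements = []
        for rep in range(20):
            rng = np.random.default_rng(np.random.SeedSequence([11, rep]))
            cohort = integrate_uniform(S, BarcodePool.uniform(B), M / B, rng)
            traj = propagate(cohort, PropagationConfig(), rng)
            table = observe_trajectory(traj, 0.1, rng)
            truth = true_propagated_lineages(traj, table)
            labels = {
                s: infer_lineages(table, s, truth_count=truth.n_lineages).labels
                for s in ("any_overlap", "min_d", "true_count")
            }
            pairs = [("any_overlap", "min_d"), ("any_overlap", "true_count"),
                     ("min_d", "true_count")]
            agreements.append(
                min(fowlkes_mallows(labels[a], labels[b]) for a, b in pairs)
            )
        assert np.mean(agreements) >= 0.95
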