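"""FC-matrix assembly, edge partitioning, similarity, and nonrandomness."""

import itertools

import networkx as nx
import numpy as np
import pytest

from copulafc import (
    FCMatrix,
    NetworkAssignment,
    RegionActivity,
    assemble_fc,
    measure_similarity,
    nonrandomness,
    partition_edges,
    pcor,
    subject_similarity,
    threshold_fc,
)


def _random_fc(rng, n=8, region_ids=None):
    a = rng.uniform(0.05, 1.0, size=(n, n))
    values = (a + a.T) / 2
    return FCMatrix(values=values, measure_tag="pcor", region_ids=region_ids)


class TestAssemble:
    def test_identical_regions_give_unit_pcor(self, rng):
        s = rng.normal(size=(3, 40))
        regions = [RegionActivity(s.copy(), region_id=f"r{i}") for i in range(3)]
        fc = assemble_fc(regions, "pcor")
        off = fc.values[np.triu_indices(3, k=1)]
        np.testing.assert_allclose(off, 1.0)
        np.testing.assert_array_equal(fc.values, fc.values.T)

    def test_entries_match_standalone_measure(self, rng):
        regions = [RegionActivity(rng.normal(size=(4, 50)), region_id=f"r{i}") for i in range(5)]
        fc = assemble_fc(regions, "pcor")
        for i, j in [(0, 1), (0, 4), (2, 3), (1, 3), (3, 4)]:
            assert fc.values[i, j] == pytest.approx(pcor(regions[i], regions[j]))

    def test_diagonal_zeroed(self, rng):
        fc = _random_fc(rng)
        np.testing.assert_array_equal(np.diag(fc.values), 0.0)


class TestPartition:
    def test_single_network_all_within(self, rng):
        fc = _random_fc(rng, 4)
        assign = NetworkAssignment({rid: "A" for rid in fc.region_ids})
        edge_class = partition_edges(fc, assign)
        assert len(edge_class.within) == 6 and len(edge_class.between) == 0

    def test_two_by_two_counts(self, rng):
        fc = _random_fc(rng, 4, region_ids=("a1", "a2", "b1", "b2"))
        assign = NetworkAssignment({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        edge_class = partition_edges(fc, assign)
        assert len(edge_class.within) == 2
        assert len(edge_class.between) == 4

    def test_conservation_over_random_assignments(self, rng):
        fc = _random_fc(rng, 9)
        labels = rng.choice(["A", "B", "C"], size=9)
        assign = NetworkAssignment(dict(zip(fc.region_ids, labels)))
        edge_class = partition_edges(fc, assign)
        assert len(edge_class.within) + len(edge_class.between) == 9 * 8 // 2
        assert sum(len(v) for v in edge_class.pair_edges.values()) == 9 * 8 // 2

    def test_unknown_region_rejected(self, rng):
        fc = _random_fc(rng, 3)
        with pytest.raises(KeyError, match="missing"):
            partition_edges(fc, NetworkAssignment({"other": "A"}))


class TestSimilarity:
    def test_self_similarity_is_one(self, rng):
        fc = _random_fc(rng)
        assert measure_similarity(fc, fc) == pytest.approx(1.0)

    def test_monotone_transform_preserves_rank_correlation(self, rng):
        fc = _random_fc(rng)
        transformed = FCMatrix(values=np.sqrt(fc.values), measure_tag="uvmi")
        assert measure_similarity(fc, transformed) == pytest.approx(1.0)

    def test_network_pair_scope_uses_block_entries_only(self, rng):
        ids = ("a1", "a2", "b1", "b2")
        assign = NetworkAssignment({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        fc_a, fc_b = _random_fc(rng, 4, ids), _random_fc(rng, 4, ids)
        block = measure_similarity(fc_a, fc_b, scope=("A", "B"), assign=assign)
        edges = partition_edges(fc_a, assign).pair_edges[("A", "B")]
        from scipy.stats import spearmanr

        a = [fc_a.values[i, j] for i, j in edges]
        b = [fc_b.values[i, j] for i, j in edges]
        assert block == pytest.approx(spearmanr(a, b).statistic)


class TestThreshold:
    def test_zero_fraction_is_identity(self, rng):
        fc = _random_fc(rng)
        np.testing.assert_array_equal(threshold_fc(fc, 0.0).values, fc.values)

    def test_full_fraction_keeps_only_maximum(self, rng):
        fc = _random_fc(rng)
        kept = threshold_fc(fc, 1.0).values
        assert np.count_nonzero(kept) == 2  # the max entry and its mirror
        assert kept.max() == fc.values.max()

    def test_survivors_non_increasing_in_fraction(self, rng):
        fc = _random_fc(rng)
        counts = [np.count_nonzero(threshold_fc(fc, f).values) for f in (0.1, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestNonrandomness:
    def test_complete_graph_total_is_leading_eigenvalue(self):
        for n in (5, 8, 12):
            g = nx.complete_graph(n)
            total, per_edge = nonrandomness(g, k=1)
            assert total == pytest.approx(n - 1, abs=1e-8)
            assert sum(per_edge.values()) == pytest.approx(total, abs=1e-8)

    def test_per_edge_sum_equals_eigenvalue_sum(self, rng):
        for seed in range(10):
            g = nx.gnp_random_graph(25, 0.3, seed=seed)
            if g.number_of_edges() == 0:
                continue
            total, per_edge = nonrandomness(g, k=4)
            lcc = g.subgraph(max(nx.connected_components(g), key=len))
            eigvals = np.sort(np.linalg.eigvalsh(nx.to_numpy_array(lcc)))[::-1]
            assert total == pytest.approx(eigvals[:4].sum(), abs=1e-8)
            assert sum(per_edge.values()) == pytest.approx(total, abs=1e-8)

    def test_between_block_edges_score_lower(self):
        g = nx.planted_partition_graph(2, 20, 0.5, 0.05, seed=1)
        _, per_edge = nonrandomness(g, k=2)
        within, between = [], []
        for (u, v), val in per_edge.items():
            (within if (u < 20) == (v < 20) else between).append(val)
        assert np.mean(between) < np.mean(within)

    def test_agrees_with_networkx_graph_nonrandomness(self):
        """Cross-check the graph-level total against the independent
        networkx implementation of the same spectral statistic."""
        g = nx.planted_partition_graph(2, 12, 0.6, 0.1, seed=3)
        total, _ = nonrandomness(g, k=2)
        nx_total, _ = nx.non_randomness(g, k=2)
        assert total == pytest.approx(nx_total, rel=1e-6)

    def test_density_thresholding_from_weighted_matrix(self, rng):
        fc = _random_fc(rng, 12)
        total, per_edge = nonrandomness(fc, density=0.2, k=2)
        assert len(per_edge) <= round(0.2 * 12 * 11 / 2) and np.isfinite(total)

    def test_empty_graph_rejected(self):
        g = nx.empty_graph(5)
        with pytest.raises(ValueError, match="no edges"):
            nonrandomness(g, k=1)


class TestSubjectSimilarity:
    def test_identical_subjects_all_one(self, rng):
        fc = _random_fc(rng)
        sims = subject_similarity([fc, fc, fc])
        np.testing.assert_allclose(sims, 1.0)

    def test_contrarian_subject_scores_lowest(self, rng):
        base = _random_fc(rng)
        centered = base.values - base.values[np.triu_indices(8, 1)].mean()
        np.fill_diagonal(centered, 0.0)
        flipped = FCMatrix(values=-centered, measure_tag="pcor")
        cohort = [base, base, base, FCMatrix(values=centered + 0.0), flipped]
        sims = subject_similarity(cohort)
        assert np.argmin(sims) == 4

    def test_similarity_rises_as_noise_falls(self, rng):
        backbone = _random_fc(rng, 10).values
        means = []
        for sd in (1.0, 0.3, 0.05):
            fcs = []
            for s in range(6):
                noise = rng.normal(scale=sd, size=backbone.shape)
                noise = (noise + noise.T) / 2
                fcs.append(FCMatrix(values=backbone + noise))
            means.append(subject_similarity(fcs).mean())
        assert means[0] < means[1] < means[2]
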