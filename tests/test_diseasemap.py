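"""Lattice construction, SOM training, map partition, correlations, NJ tree."""

import numpy as np
import pandas as pd
import pytest

from priormap import diseasemap as d
from priormap import synth


class TestLattice:
    @pytest.mark.parametrize("radius", range(1, 11))
    def test_count_law_matches_ring_summation(self, radius):
        lattice = d.build_lattice(radius)
        assert len(lattice) == 1 + 3 * radius * (radius - 1)
        # independent ring summation: 1 + 6 * sum(1..radius-1)
        assert len(lattice) == 1 + 6 * sum(range(1, radius))

    def test_radius_six_has_91_hexagons(self):
        assert len(d.build_lattice(6)) == 91

    def test_radius_one_single_hexagon(self):
        lattice = d.build_lattice(1)
        assert len(lattice) == 1 and lattice.neighbors[0] == ()

    def test_radius_two_center_neighbors(self):
        lattice = d.build_lattice(2)
        assert len(lattice) == 7
        assert len(lattice.neighbors[0]) == 6

    def test_neighbor_relation_symmetric_and_connected(self):
        import networkx as nx

        lattice = d.build_lattice(4)
        g = nx.Graph()
        g.add_nodes_from(range(len(lattice)))
        for i, nbrs in enumerate(lattice.neighbors):
            for j in nbrs:
                assert i in lattice.neighbors[j]
                g.add_edge(i, j)
        assert nx.is_connected(g)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            d.build_lattice(0)


class TestCorrelations:
    def test_identical_columns_rho_one(self):
        m = pd.DataFrame({"A": [1, 2, 3, 4.0], "B": [1, 2, 3, 4.0], "C": [4, 3, 2, 1.0]})
        out = d.rating_correlations(m, "A").set_index("disease_b")
        assert out.loc["B", "spearman_rho"] == pytest.approx(1.0)
        assert out.loc["C", "spearman_rho"] == pytest.approx(-1.0)

    def test_matches_closed_form_rank_formula(self, rng):
        a = rng.permutation(10).astype(float)
        b = rng.permutation(10).astype(float)
        m = pd.DataFrame({"A": a, "B": b})
        out = d.rating_correlations(m, "A")
        dsq = np.sum((pd.Series(a).rank() - pd.Series(b).rank()) ** 2)
        expected = 1 - 6 * dsq / (10 * 99)
        assert out["spearman_rho"].item() == pytest.approx(expected)

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            d.rating_correlations(m, "A")


class TestSom:
    def test_identical_genes_fixed_point(self):
        m = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (30, 1)), columns=list("ABC"))
        codebook = d.train_som(m, d.build_lattice(2), epochs_rough=5, epochs_fine=5)
        np.testing.assert_allclose(codebook.vectors, np.tile([1, 2, 3], (7, 1)), atol=1e-9)

    def test_single_hexagon_gives_column_means(self, rng):
        m = pd.DataFrame(rng.random((40, 3)), columns=list("ABC"))
        codebook = d.train_som(m, d.build_lattice(1), epochs_rough=2, epochs_fine=2)
        np.testing.assert_allclose(codebook.vectors[0], m.mean().to_numpy(), atol=1e-9)

    def test_quantization_error_non_increasing_in_fine_phase(self, rating_fixture):
        matrix, _ = rating_fixture
        lattice = d.build_lattice(4)
        errors = []
        for extra in (0, 20, 60):
            codebook = d.train_som(matrix, lattice, epochs_rough=20, epochs_fine=10 + extra)
            errors.append(d.quantization_error(matrix, codebook))
        assert errors[-1] <= errors[0] + 1e-6

    def test_training_is_deterministic(self, rating_fixture):
        matrix, _ = rating_fixture
        lattice = d.build_lattice(3)
        a = d.train_som(matrix, lattice, 10, 10)
        b = d.train_som(matrix, lattice, 10, 10)
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestPartition:
    def test_constant_codebook_single_cluster(self):
        lattice = d.build_lattice(3)
        codebook = d.Codebook(lattice, np.ones((len(lattice), 2)), ("A", "B"))
        partition = d.partition_map(codebook)
        assert partition.n_clusters == 1

    def test_two_block_codebook_recovers_halves(self):
        lattice = d.build_lattice(3)
        pos = lattice.cartesian()
        left = pos[:, 0] < np.median(pos[:, 0])
        vectors = np.where(left[:, None], [0.0, 0.0], [10.0, 10.0])
        codebook = d.Codebook(lattice, vectors.astype(float), ("A", "B"))
        partition = d.partition_map(codebook, n_clusters=2)
        labels = np.array(partition.cluster_of)
        # the two planted halves map onto the two clusters almost perfectly
        majority_left = np.bincount(labels[left]).argmax()
        majority_right = np.bincount(labels[~left]).argmax()
        assert majority_left != majority_right
        purity = (
            np.mean(labels[left] == majority_left) + np.mean(labels[~left] == majority_right)
        ) / 2
        assert purity > 0.9

    def test_clusters_are_connected_patches(self, rating_fixture):
        import networkx as nx

        matrix, _ = rating_fixture
        lattice = d.build_lattice(5)
        codebook = d.train_som(matrix, lattice, 20, 30)
        partition = d.partition_map(codebook)
        for cluster in range(partition.n_clusters):
            members = [i for i, c in enumerate(partition.cluster_of) if c == cluster]
            g = nx.Graph()
            g.add_nodes_from(members)
            for i in members:
                for j in lattice.neighbors[i]:
                    if j in members:
                        g.add_edge(i, j)
            assert nx.is_connected(g)


class TestAssignment:
    def test_gene_equal_to_codebook_vector_maps_there(self):
        lattice = d.build_lattice(2)
        vectors = np.arange(14, dtype=float).reshape(7, 2)
        codebook = d.Codebook(lattice, vectors, ("A", "B"))
        partition = d.partition_map(codebook)
        m = pd.DataFrame([vectors[3]], columns=["A", "B"], index=["g"])
        out = d.assign_genes(m, codebook, partition)
        assert out["hexagon"].item() == 3

    def test_identical_genes_identical_assignment(self, rating_fixture):
        matrix, _ = rating_fixture
        lattice = d.build_lattice(3)
        codebook = d.train_som(matrix, lattice, 10, 10)
        partition = d.partition_map(codebook)
        twin = pd.concat([matrix.iloc[[0]], matrix.iloc[[0]]])
        out = d.assign_genes(twin, codebook, partition)
        assert out["hexagon"].iloc[0] == out["hexagon"].iloc[1]

    def test_planted_blocks_land_in_distinct_clusters(self, rating_fixture):
        matrix, truth = rating_fixture
        lattice = d.build_lattice(6)
        codebook = d.train_som(matrix, lattice)
        partition = d.partition_map(codebook)
        out = d.assign_genes(matrix, codebook, partition).set_index("gene")
        shared = out.loc[truth.shared_block, "cluster"].mode()[0]
        specific = out.loc[truth.specific_block, "cluster"].mode()[0]
        assert shared != specific

    def test_same_block_genes_closer_on_lattice_than_cross_block(self, rating_fixture):
        matrix, truth = rating_fixture
        lattice = d.build_lattice(6)
        codebook = d.train_som(matrix, lattice)
        partition = d.partition_map(codebook)
        out = d.assign_genes(matrix, codebook, partition).set_index("gene")
        dist = lattice.lattice_distances()
        hs = out.loc[truth.shared_block, "hexagon"].to_numpy()
        hp = out.loc[truth.specific_block, "hexagon"].to_numpy()
        within = np.mean([dist[a, b] for a in hs for b in hs])
        across = np.mean([dist[a, b] for a in hs for b in hp])
        assert within < across


def _additive_distances():
    # 4-taxon tree ((A:1,B:2):1,(C:3,D:4)) -> additive path-length matrix
    path = {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
        ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
    }
    taxa = ["A", "B", "C", "D"]
    m = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for (a, b), v in path.items():
        m.loc[a, b] = m.loc[b, a] = float(v)
    return m


class TestNj:
    def test_additive_tree_recovered_with_branch_lengths(self):
        dist = _additive_distances()
        tree = d.nj_tree(dist)
        # four-point condition oracle: AB|CD is the generating split, and
        # patristic distances on the NJ tree reproduce the input matrix
        tips = {t.name: t for t in tree.tips()}
        for a in dist.index:
            for b in dist.columns:
                if a < b:
                    got = tips[a].distance(tips[b])
                    assert got == pytest.approx(dist.loc[a, b], abs=1e-10)

    def test_three_diseases_star(self):
        m = pd.DataFrame(np.random.default_rng(0).random((20, 3)), columns=list("ABC"))
        tree = d.consensus_nj(m, n_boot=10, seed=0)
        assert tree.newick == "(A,B,C);"

    def test_duplicated_disease_pairs_with_full_support(self, rng):
        n = 300
        base = rng.normal(size=n)
        other = rng.normal(size=(n, 3))
        m = pd.DataFrame(
            {"D": base, "D2": base + 1e-9 * rng.normal(size=n),
             "A": other[:, 0], "B": other[:, 1], "C": other[:, 2]}
        )
        tree = d.consensus_nj(m, n_boot=30, seed=0)
        assert tree.supports.get(frozenset({"D", "D2"})) == pytest.approx(1.0)

    def test_fewer_than_three_diseases_rejected(self):
        m = pd.DataFrame({"A": [1, 2.0], "B": [2, 1.0]})
        with pytest.raises(ValueError):
            d.consensus_nj(m)

    def test_supports_bounded_and_majority(self, rating_fixture):
        matrix, _ = rating_fixture
        tree = d.consensus_nj(matrix, n_boot=30, seed=1)
        for support in tree.supports.values():
            assert 0.5 < support <= 1.0


def test_cluster_enrichment_counts_match_manual_tables():
    universe = {f"g{i}" for i in range(20)}
    cluster = {f"g{i}" for i in range(5)}
    annotation = {"path": {f"g{i}" for i in range(3, 10)}}
    out = d.cluster_enrichment(cluster, annotation, universe)
    row = out.iloc[0]
    assert row["overlap"] == 2  # {g3, g4}
    assert row["set_size"] == 7
    assert row["list_size"] == 5
    assert row["universe_size"] == 20
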