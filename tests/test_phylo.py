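"""Distance computation, NJ additive recovery, bootstrap, Newick round-trip."""

import io

import numpy as np
import pytest

from stressprio.phylo import (
    Alignment, DistanceMatrix, PhyloError, bootstrap, kimura_correct,
    neighbor_joining, pdistance, read_newick, write_newick,
)
from stressprio.synthetic import gen_additive_matrix, gen_alignment

random_tree_metric = gen_additive_matrix


class TestPdistance:
    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDE"])
        assert np.allclose(pdistance(aln).d, 0)

    def test_single_mismatch(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDF"])
        assert pdistance(aln).d[0, 1] == pytest.approx(0.25)

    def test_complete_deletion_drops_gapped_column(self):
        aln = Alignment(["a", "b"], ["A-DE", "ACDF"])
        assert pdistance(aln, "complete").d[0, 1] == pytest.approx(1 / 3)

    def test_pairwise_mode_per_pair_columns(self):
        aln = Alignment(["a", "b", "c"], ["A-DE", "ACDF", "AC-F"])
        D = pdistance(aln, "pairwise")
        assert D.d[0, 1] == pytest.approx(1 / 3)   # cols 1,3,4
        assert D.d[1, 2] == pytest.approx(0.0)     # cols 1,2,4 match
        assert D.d[0, 2] == pytest.approx(0.5)     # cols 1,4

    def test_all_gapped_rejected(self):
        aln = Alignment(["a", "b"], ["A-", "-C"])
        with pytest.raises(PhyloError):
            pdistance(aln, "complete")

    def test_symmetry_and_zero_diagonal(self):
        aln = gen_alignment(seed=3)
        D = pdistance(aln)
        assert np.allclose(D.d, D.d.T)
        assert np.all(np.diag(D.d) == 0)


class TestKimuraCorrect:
    def test_zero_maps_to_zero(self):
        assert kimura_correct(0.0) == 0.0

    def test_quarter_divergence(self):
        assert kimura_correct(0.25) == pytest.approx(-np.log(0.7375), rel=1e-12)

    def test_monotone(self):
        grid = np.linspace(0, 0.7, 50)
        vals = [kimura_correct(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_saturation_raises(self):
        with pytest.raises(PhyloError):
            kimura_correct(0.95)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives this additive matrix
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        recovered = tree.path_length_matrix()
        assert np.allclose(recovered.d, d, atol=1e-12)

    def test_random_additive_matrices_recovered(self):
        """Path metrics of 100 random binary trees (<=8 taxa) round-trip."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            D = random_tree_metric(n, rng)
            tree = neighbor_joining(D)
            recovered = tree.path_length_matrix()
            assert recovered.taxa == D.taxa
            assert np.abs(recovered.d - D.d).max() < 1e-9

    def test_too_few_taxa_rejected(self):
        with pytest.raises(PhyloError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0, 1], [1, 0.]])))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhyloError):
            DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))


class TestBootstrap:
    def test_strong_split_high_support(self):
        """Two tight 3-taxon clusters: central split in >=95% of replicates."""
        aln = gen_alignment(n_per_cluster=3, n_sites=100, within=0.01,
                            between=0.9, seed=21)
        tree = bootstrap(aln, n_reps=200, seed=5)
        central = frozenset({"c1_t1", "c1_t2", "c1_t3"})
        supports = {}
        for node in tree.tree.preorder_node_iter():
            if node.label is not None and not node.is_leaf():
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                supports[side] = int(node.label)
        split = {s: v for s, v in supports.items()
                 if s == central or s == frozenset(tree.taxa) - central}
        assert split and max(split.values()) >= 0.95 * 200

    def test_reproducible_under_fixed_seed(self):
        aln = gen_alignment(seed=9)
        t1 = bootstrap(aln, n_reps=30, seed=11)
        t2 = bootstrap(aln, n_reps=30, seed=11)
        assert write_newick(t1) == write_newick(t2)

    def test_single_replicate_supports_binary(self):
        aln = gen_alignment(seed=4)
        tree = bootstrap(aln, n_reps=1, seed=1)
        labels = [int(n.label) for n in tree.tree.preorder_node_iter()
                  if n.label is not None and not n.is_leaf()]
        assert labels and set(labels) <= {0, 1}

    def test_identical_sequences_star_flag(self):
        aln = Alignment([f"t{i}" for i in range(4)], ["ACDE"] * 4)
        tree = bootstrap(aln, n_reps=5, seed=0)
        assert tree.star


class TestNewick:
    def test_three_taxon_output_parseable(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        text = write_newick(tree)
        back = read_newick(text)
        assert back.taxa == ["A", "B", "C"]

    def test_round_trip_topology_and_lengths(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 8))
            D = random_tree_metric(n, rng)
            tree = neighbor_joining(D)
            back = read_newick(write_newick(tree))
            assert back.bipartitions() == tree.bipartitions()
            assert np.abs(
                back.path_length_matrix().d - tree.path_length_matrix().d
            ).max() < 1e-5

    def test_metacharacter_label_quoted(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.]])
        tree = neighbor_joining(DistanceMatrix(["a b", "c(d)", "E"], d))
        text = write_newick(tree)
        back = read_newick(text)
        assert set(back.taxa) == {"a b", "c(d)", "E"}
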