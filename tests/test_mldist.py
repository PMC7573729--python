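"""ML pairwise distances, neighbor joining, cophenetic, bootstrap."""

import numpy as np
import pytest

from dupdiv import (
    DistanceMatrix,
    RateMixture,
    SubstitutionModel,
    bootstrap_support,
    cophenetic,
    distance_matrix,
    ml_pairwise_distance,
    nj_tree,
)
from dupdiv.alignment import Alignment
from dupdiv.errors import IncompleteMatrixError, InsufficientDataError
from dupdiv.simulate import simulate_family_tree
from dupdiv.trees import to_newick

from conftest import random_additive_matrix, simulate_alignment_on_tree

JC = SubstitutionModel.jc69()


def jc69_closed_form(p_hat):
    return -0.75 * np.log(1 - 4 * p_hat / 3)


class TestMlPairwiseDistance:
    def test_identical_sequences_give_zero(self):
        r = ml_pairwise_distance("ACGTACGT", "ACGTACGT", JC)
        assert r.distance == 0.0 and not r.saturated

    @pytest.mark.parametrize("p_hat", [0.05, 0.1, 0.3, 0.5])
    def test_jc69_matches_closed_form(self, p_hat):
        n = 1000
        nm = int(round(p_hat * n))
        a = "A" * n
        b = "C" * nm + "A" * (n - nm)
        r = ml_pairwise_distance(a, b, JC)
        assert r.distance == pytest.approx(jc69_closed_form(nm / n), abs=1e-4)

    def test_monotone_in_mismatch_fraction(self):
        n = 600
        dists = []
        for nm in (30, 60, 120, 240, 360):
            b = "C" * nm + "A" * (n - nm)
            dists.append(ml_pairwise_distance("A" * n, b, JC).distance)
        assert dists == sorted(dists)

    def test_gap_and_ambiguity_sites_excluded(self):
        # 4 usable sites, 1 mismatch; the gap/N columns must not count
        r1 = ml_pairwise_distance("ACGTA", "ACGTC", JC)
        r2 = ml_pairwise_distance("ACGTA-N", "ACGTCCA", JC)
        assert r2.n_sites == 5
        assert r2.distance == pytest.approx(r1.distance, abs=1e-9)

    def test_all_gap_pair_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            ml_pairwise_distance("--", "AC", JC)

    def test_saturated_pair_flagged(self):
        # mismatch fraction beyond the JC69 support: optimum runs to t_max
        n = 300
        b = "C" * 250 + "A" * 50
        r = ml_pairwise_distance("A" * n, b, JC)
        assert r.saturated

    def test_large_alpha_gamma_approaches_plain_jc69(self):
        mix = RateMixture.discrete_gamma(1e6, 4)
        n, nm = 1000, 200
        b = "C" * nm + "A" * (n - nm)
        with_gamma = ml_pairwise_distance("A" * n, b, JC, mix).distance
        assert with_gamma == pytest.approx(jc69_closed_form(nm / n), abs=1e-4)

    def test_simulation_recovery_jtt_gamma(self):
        # small-scale version of the full recovery study in the acceptance
        # suite: 20 replicates at t=0.5 under JTT+G(alpha=1)
        model = SubstitutionModel.jtt()
        mix = RateMixture.discrete_gamma(1.0, 4)
        from conftest import simulate_pair

        est = []
        for rep in range(20):
            a, b = simulate_pair(0.5, 1000, model, mix, seed=100 + rep,
                                 continuous_gamma_alpha=1.0)
            est.append(ml_pairwise_distance(a, b, model, mix).distance)
        assert np.mean(est) == pytest.approx(0.5, rel=0.08)


class TestDistanceMatrixOp:
    def test_two_sequences(self):
        aln = Alignment(("a", "b"), ("AAAA", "AAAC"), "nucleotide")
        dm = distance_matrix(aln, JC)
        expected = ml_pairwise_distance("AAAA", "AAAC", JC).distance
        assert dm[("a", "b")] == expected

    def test_matches_per_pair_calls(self):
        tree = simulate_family_tree(5, 3.0, 21)
        seqs = simulate_alignment_on_tree(tree, 500, JC, RateMixture(), 22)
        ids = sorted(seqs)
        aln = Alignment(tuple(ids), tuple(seqs[i] for i in ids), "nucleotide")
        dm = distance_matrix(aln, JC)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                single = ml_pairwise_distance(seqs[a], seqs[b], JC)
                if single.saturated:
                    assert dm.mask[dm.index(a), dm.index(b)]
                else:
                    assert dm[(a, b)] == single.distance

    def test_label_equivariance_under_input_order(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "AACC", "ACCC"), "nucleotide")
        rev = Alignment(("c", "b", "a"), ("ACCC", "AACC", "AAAA"), "nucleotide")
        d1, d2 = distance_matrix(aln, JC), distance_matrix(rev, JC)
        for x in "abc":
            for y in "abc":
                if x != y:
                    # swapped pair order transposes the count matrix; the
                    # optimizer then agrees only to its own tolerance
                    assert d1[(x, y)] == pytest.approx(d2[(x, y)], abs=1e-6)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], [[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1, abs=1e-12)
        assert lengths["b"] == pytest.approx(0.2, abs=1e-12)
        assert lengths["c"] == pytest.approx(0.3, abs=1e-12)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:0.1,B:0.2):0.1,(C:0.3,D:0.4))
        labels = ["A", "B", "C", "D"]
        v = np.array(
            [
                [0, 0.3, 0.5, 0.6],
                [0.3, 0, 0.6, 0.7],
                [0.5, 0.6, 0, 0.7],
                [0.6, 0.7, 0.7, 0],
            ]
        )
        dm = DistanceMatrix(labels, v)
        tree = nj_tree(dm)
        back = cophenetic(tree).reorder(labels)
        np.testing.assert_allclose(back.values, v, atol=1e-10)

    def test_additive_round_trip_random_trees(self):
        for seed in range(10):
            n = 4 + seed % 6
            dm, _ = random_additive_matrix(n, 1000 + seed)
            back = cophenetic(nj_tree(dm)).reorder(dm.labels)
            np.testing.assert_allclose(back.values, dm.values, atol=1e-10)

    def test_all_equal_matrix_degenerate_ties(self):
        n = 5
        v = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix([f"t{i}" for i in range(n)], v)
        tree = nj_tree(dm)
        assert len(tree.leaf_nodes()) == n

    def test_label_permutation_invariance(self):
        dm, _ = random_additive_matrix(6, 77)
        perm = np.random.default_rng(0).permutation(6)
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        c1 = cophenetic(nj_tree(dm)).reorder(sorted(dm.labels))
        c2 = cophenetic(nj_tree(dm2)).reorder(sorted(dm.labels))
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        dm, _ = random_additive_matrix(7, 55)
        ours = cophenetic(nj_tree(dm)).reorder(dm.labels)
        sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
        sk_tree = skbio_nj(sk_dm)
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1 :]:
                sk_d = sk_tree.find(a).distance(sk_tree.find(b))
                assert ours[(a, b)] == pytest.approx(sk_d, abs=1e-8)

    def test_masked_matrix_rejected(self):
        v = np.ones((3, 3)) - np.eye(3)
        m = np.zeros((3, 3), bool)
        m[0, 1] = m[1, 0] = True
        with pytest.raises(IncompleteMatrixError):
            nj_tree(DistanceMatrix(list("abc"), v, m))


class TestCophenetic:
    def test_star_tree(self):
        from dupdiv.trees import parse_newick

        d = cophenetic(parse_newick("(a:0.1,b:0.2,c:0.3);"))
        assert d[("a", "b")] == pytest.approx(0.3)
        assert d[("a", "c")] == pytest.approx(0.4)
        assert d[("b", "c")] == pytest.approx(0.5)

    def test_four_point_condition_on_random_trees(self):
        for seed in (1, 2, 3):
            dm, _ = random_additive_matrix(6, 300 + seed)
            v = dm.values
            n = dm.n
            for i, j, k, l in [(0, 1, 2, 3), (1, 2, 3, 4), (0, 2, 3, 5)]:
                sums = sorted(
                    [v[i, j] + v[k, l], v[i, k] + v[j, l], v[i, l] + v[j, k]]
                )
                assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_missing_branch_length_is_tree_error(self):
        from dupdiv.errors import TreeError
        from dupdiv.trees import parse_newick

        with pytest.raises(TreeError):
            cophenetic(parse_newick("(a:0.1,b,c:0.3);"))


class TestBootstrap:
    @pytest.fixture(scope="class")
    def six_taxon_alignment(self):
        tree = simulate_family_tree(6, 1.0, 404)
        seqs = simulate_alignment_on_tree(tree, 800, JC, RateMixture(), 405)
        ids = sorted(seqs)
        return Alignment(tuple(ids), tuple(seqs[i] for i in ids), "nucleotide")

    def test_single_replicate_supports_are_zero_or_one(self, six_taxon_alignment):
        tree = bootstrap_support(six_taxon_alignment, JC, n_boot=1, seed=5)
        sups = [
            n.support
            for n in tree.preorder_node_iter()
            if getattr(n, "support", None) is not None
        ]
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_same_seed_reproducible(self, six_taxon_alignment):
        t1 = bootstrap_support(six_taxon_alignment, JC, n_boot=20, seed=9)
        t2 = bootstrap_support(six_taxon_alignment, JC, n_boot=20, seed=9)
        assert to_newick(t1) == to_newick(t2)

    def test_different_seed_same_topology_similar_supports(self, six_taxon_alignment):
        t1 = bootstrap_support(six_taxon_alignment, JC, n_boot=30, seed=9)
        t2 = bootstrap_support(six_taxon_alignment, JC, n_boot=30, seed=10)
        s1 = sorted(
            n.support for n in t1.preorder_node_iter()
            if getattr(n, "support", None) is not None
        )
        s2 = sorted(
            n.support for n in t2.preorder_node_iter()
            if getattr(n, "support", None) is not None
        )
        assert np.allclose(s1, s2, atol=0.35)
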