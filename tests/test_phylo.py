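"""Neighbor-Joining reconstruction, distances and cluster concordance."""

import numpy as np
import pytest
import skbio

from nitriminer.phylo import (DistanceMatrix, cluster_concordance, nj_tree,
                              pdistance_matrix)
from nitriminer.seqio import ProteinSequence
from nitriminer.synthetic_data import mutate_to_identity

from conftest import random_protein
from oracles import (enumerate_topologies, fits_additively, newick_splits,
                     random_unrooted_tree, splits_of_edges, tree_distances)


def dm(ids, d):
    return DistanceMatrix(tuple(ids), np.asarray(d, dtype=float))


class TestPDistance:
    def test_identical_pair_zero(self, rng):
        s = random_protein(rng, 50)
        seqs = [ProteinSequence(f"s{i}", s) for i in range(2)]
        seqs.append(ProteinSequence("t", random_protein(rng, 50)))
        m = pdistance_matrix(seqs)
        assert m.d[0, 1] == 0.0

    def test_disjoint_residues_distance_one(self):
        seqs = [ProteinSequence("a", "AAAAA"), ProteinSequence("b", "GGGGG"),
                ProteinSequence("c", "AAAGG")]
        m = pdistance_matrix(seqs)
        assert m.d[0, 1] == pytest.approx(1.0)

    def test_requires_three_sequences(self):
        with pytest.raises(ValueError):
            pdistance_matrix([ProteinSequence("a", "AA"),
                              ProteinSequence("b", "AA")])

    def test_symmetric_zero_diagonal(self, rng):
        seqs = [ProteinSequence(f"s{i}", random_protein(rng, 40))
                for i in range(4)]
        m = pdistance_matrix(seqs)
        assert np.allclose(m.d, m.d.T) and np.all(np.diag(m.d) == 0)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        tree = nj_tree(dm("ABC", [[0, d_ab, d_ac], [d_ab, 0, d_bc],
                                  [d_ac, d_bc, 0]]))
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_four_taxon_additive_recovery_with_lengths(self):
        # ((A,B),(C,D)): leaf lengths 0.1..0.4, internal 0.5
        edges = {(0, 4): 0.1, (1, 4): 0.2, (4, 5): 0.5, (2, 5): 0.3,
                 (3, 5): 0.4}
        d = tree_distances(edges, 4)
        tree = nj_tree(dm(["A", "B", "C", "D"], d))
        got = newick_splits(tree.newick(), ["A", "B", "C", "D"], skbio)
        assert got == splits_of_edges(list(edges), 4)
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["D"] == pytest.approx(0.4)

    def test_additive_matrices_recovered_exactly(self, rng):
        """NJ reconstructs the generating topology of additive matrices."""
        for trial in range(20):
            n = int(rng.integers(4, 9))
            edges = random_unrooted_tree(n, rng)
            d = tree_distances(edges, n)
            names = [f"t{i}" for i in range(n)]
            tree = nj_tree(dm(names, d))
            assert newick_splits(tree.newick(), names, skbio) == \
                splits_of_edges(list(edges), n)

    def test_uniqueness_by_bruteforce_enumeration(self, rng):
        """Only the generating topology fits the additive matrix exactly."""
        for trial in range(3):
            n = 6
            edges = random_unrooted_tree(n, rng)
            d = tree_distances(edges, n)
            true_splits = splits_of_edges(list(edges), n)
            exact_fits = []
            for topo in enumerate_topologies(n):
                ok, _ = fits_additively(topo, n, d)
                if ok:
                    exact_fits.append(splits_of_edges(topo, n))
            assert exact_fits == [true_splits]
            names = [f"t{i}" for i in range(n)]
            assert newick_splits(nj_tree(dm(names, d)).newick(), names,
                                 skbio) == true_splits

    def test_agrees_with_skbio_on_random_matrices(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 8))
            x = rng.uniform(0.1, 1.0, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            names = [f"t{i}" for i in range(n)]
            ours = nj_tree(dm(names, d))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(d, names))
            got = newick_splits(ours.newick(), names, skbio)
            want = newick_splits(str(theirs), names, skbio)
            assert got == want

    def test_leaf_permutation_isomorphic(self, rng):
        n = 6
        edges = random_unrooted_tree(n, rng)
        d = tree_distances(edges, n)
        names = [f"t{i}" for i in range(n)]
        perm = rng.permutation(n)
        tree1 = nj_tree(dm(names, d))
        tree2 = nj_tree(dm([names[i] for i in perm], d[np.ix_(perm, perm)]))
        assert newick_splits(tree1.newick(), names, skbio) == \
            newick_splits(tree2.newick(), names, skbio)

    def test_newick_roundtrip(self, rng):
        n = 7
        edges = random_unrooted_tree(n, rng)
        names = [f"t{i}" for i in range(n)]
        tree = nj_tree(dm(names, tree_distances(edges, n)))
        reparsed = skbio.TreeNode.read([tree.newick()])
        assert {t.name for t in reparsed.tips()} == set(names)
        assert newick_splits(str(reparsed), names, skbio) == \
            newick_splits(tree.newick(), names, skbio)

    def test_negative_branch_estimates_clamped(self):
        # a decidedly non-additive matrix that forces a negative NJ estimate
        d = np.array([[0.0, 0.1, 0.6, 0.6],
                      [0.1, 0.0, 0.6, 0.05],
                      [0.6, 0.6, 0.0, 0.7],
                      [0.6, 0.05, 0.7, 0.0]])
        tree = nj_tree(dm(list("ABCD"), d))
        assert tree.clamped_branches >= 1
        for leaf in tree.root.leaves():
            assert leaf.length >= 0

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            nj_tree(dm(["a", "b"], [[0, 1], [1, 0]]))  # n < 3
        with pytest.raises(ValueError):
            dm(list("ab"), [[0, 1], [2, 0]])  # asymmetric


class TestConcordance:
    def _fixture(self, rng):
        # references: one diverged family (mutated copies of an ancestor);
        # queries: close mutated copies of individual references
        ancestor = ProteinSequence("anc", "M" + random_protein(rng, 299))
        refs, queries = [], []
        qlabels, rlabels = {}, {}
        for i, cls in enumerate(["aliphatic", "aliphatic", "aromatic",
                                 "aromatic"]):
            ref = mutate_to_identity(ancestor, 75, seed=50 + i,
                                     name=f"ref{i}_{cls}")
            refs.append(ref)
            rlabels[ref.id] = cls
            q = mutate_to_identity(ref, 90, seed=99 + i, name=f"q{i}")
            queries.append(q)
            qlabels[q.id] = cls
        return refs, queries, rlabels, qlabels

    def test_mutated_copies_concordant(self, rng):
        refs, queries, rlabels, qlabels = self._fixture(rng)
        tree = nj_tree(pdistance_matrix(refs + queries))
        frac, rows = cluster_concordance(tree, qlabels, rlabels)
        assert frac == 1.0
        for row in rows:
            assert row["nearest_reference"] == row["query_id"].replace(
                "q", "ref") + "_" + row["query_label"]

    def test_long_branch_flagged(self, rng):
        refs, queries, rlabels, qlabels = self._fixture(rng)
        outlier = ProteinSequence("q_out", "M" + random_protein(rng, 280))
        qlabels2 = dict(qlabels, q_out="aliphatic")
        tree = nj_tree(pdistance_matrix(refs + queries + [outlier]))
        _, rows = cluster_concordance(tree, qlabels2, rlabels)
        out_row = next(r for r in rows if r["query_id"] == "q_out")
        assert out_row["long_branch"]

    def test_requires_queries_and_references(self, rng):
        refs, queries, rlabels, qlabels = self._fixture(rng)
        tree = nj_tree(pdistance_matrix(refs + queries))
        with pytest.raises(ValueError):
            cluster_concordance(tree, {}, rlabels)
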