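"""Distances, NJ exactness, bootstrap supports, monophyly."""

import dendropy
import numpy as np
import pytest

from orpheus.io import SequenceRecord
from orpheus.phylo import (
    DistanceMatrix,
    bootstrap_support,
    is_monophyletic,
    nj_patristic,
    nj_tree,
    protein_distance,
    root_with_outgroup,
    root_to_tip_lengths,
    tree_from_msa,
)


def _rows(strings, prefix="r"):
    return [SequenceRecord(id=f"{prefix}{i}", seq=s, alphabet="protein")
            for i, s in enumerate(strings)]


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


class TestDistances:
    def test_identical_rows_zero(self):
        dm = protein_distance(_rows(["ACDE" * 10] * 3))
        assert np.allclose(dm.matrix, 0.0)

    def test_poisson_closed_form(self):
        rows = _rows(["A" * 100, "C" * 10 + "A" * 90, "A" * 100])
        dm = protein_distance(rows)
        assert dm.matrix[0, 1] == pytest.approx(-np.log(0.9))

    def test_saturated_pair_flagged_and_capped(self):
        rows = _rows(["A" * 100, "C" * 100, "C" * 10 + "A" * 90])
        dm = protein_distance(rows)
        assert dm.saturated[0, 1]
        assert dm.matrix[0, 1] == pytest.approx(dm.matrix.max())

    def test_no_shared_columns_rejected(self):
        rows = _rows(["AC--", "--DE", "ACDE"])
        with pytest.raises(ValueError, match="shared"):
            protein_distance(rows)


def _random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> patristic matrix."""
    from orpheus.simulate import random_coalescent_tree

    nwk = random_coalescent_tree(n, seed=int(rng.integers(1e6)), total_length=4.0)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    dist = _patristic(tree)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(labels[i], labels[j])
    return labels, D


class TestNeighborJoining:
    @pytest.mark.parametrize("n", [4, 5, 8])
    def test_additive_matrices_recovered_exactly(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            labels, D = _random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix(labels, D))
            dist = _patristic(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    assert dist(labels[i], labels[j]) == pytest.approx(D[i, j], abs=1e-8)

    def test_three_taxon_star(self):
        D = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))

    def test_lean_patristic_agrees_with_tree_builder(self):
        rng = np.random.default_rng(7)
        labels, D = _random_additive_matrix(rng, 10)
        noisy = D + rng.normal(0, 0.01, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        noisy = np.abs(noisy)
        pat = nj_patristic(noisy)
        tree = nj_tree(DistanceMatrix(labels, noisy))
        dist = _patristic(tree)
        for i in range(10):
            for j in range(i + 1, 10):
                assert pat[i, j] == pytest.approx(dist(labels[i], labels[j]), abs=1e-8)

    def test_against_scikit_bio(self):
        """Independent cross-check of the NJ criterion on a random matrix."""
        import io as _io

        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(12)
        labels, D = _random_additive_matrix(rng, 7)
        sk_tree = sk_nj(SkDM(D, ids=labels))
        my_tree = nj_tree(DistanceMatrix(labels, D))
        ns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=str(sk_tree.root_at_midpoint()), schema="newick",
                              taxon_namespace=ns)
        b = dendropy.Tree.get(data=my_tree.as_string(schema="newick"),
                              schema="newick", taxon_namespace=ns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


def _two_cluster_msa(seed=0, n_per=5, width=120, sep=60):
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base1 = rng.choice(aas, width)
    base2 = base1.copy()
    base2[rng.choice(width, sep, replace=False)] = rng.choice(aas, sep)
    msa = []
    for g, base in (("x", base1), ("y", base2)):
        for i in range(n_per):
            s = base.copy()
            jj = rng.choice(width, 6, replace=False)
            s[jj] = rng.choice(aas, 6)
            msa.append(SequenceRecord(id=f"{g}{i}", seq="".join(s),
                                      alphabet="protein"))
    return msa


class TestBootstrap:
    def test_clear_split_high_support(self):
        msa = _two_cluster_msa()
        tree = bootstrap_support(msa, n_reps=100, seed=5, outgroup="y0")
        mono, sup = is_monophyletic(tree, [f"x{i}" for i in range(5)])
        assert mono and sup >= 90

    def test_single_replicate_supports_binary(self):
        msa = _two_cluster_msa(seed=3)
        tree = bootstrap_support(msa, n_reps=1, seed=1)
        sups = [n.support for n in tree.internal_nodes()
                if getattr(n, "support", None) is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_fixed_seed_reproducible(self):
        msa = _two_cluster_msa(seed=4)
        t1 = bootstrap_support(msa, n_reps=30, seed=9)
        t2 = bootstrap_support(msa, n_reps=30, seed=9)
        s1 = sorted(n.support for n in t1.internal_nodes() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.internal_nodes() if hasattr(n, "support"))
        assert s1 == s2

    def test_supports_invariant_to_row_order(self):
        msa = _two_cluster_msa(seed=6)
        t1 = bootstrap_support(msa, n_reps=30, seed=2)
        t2 = bootstrap_support(list(reversed(msa)), n_reps=30, seed=2)
        from orpheus.phylo import _bipartition_keys

        k1 = {k: n.support for n, k in _bipartition_keys(t1).items()}
        k2 = {k: n.support for n, k in _bipartition_keys(t2).items()}
        shared = set(k1) & set(k2)
        assert shared
        for k in shared:
            assert k1[k] == k2[k]


class TestMonophylyAndRooting:
    def test_full_leaf_set_true(self):
        msa = _two_cluster_msa(seed=8)
        tree = tree_from_msa(msa)
        mono, _ = is_monophyletic(tree, [r.id for r in msa])
        assert mono

    def test_subset_split_across_root_false(self):
        msa = _two_cluster_msa(seed=8)
        tree = bootstrap_support(msa, n_reps=10, seed=0, outgroup="y0")
        mono, _ = is_monophyletic(tree, ["x0", "y1"])
        assert not mono

    def test_unknown_taxon_rejected(self):
        msa = _two_cluster_msa(seed=8)
        tree = tree_from_msa(msa)
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(tree, ["nope"])

    def test_outgroup_sister_to_rest(self):
        msa = _two_cluster_msa(seed=2)
        tree = root_with_outgroup(tree_from_msa(msa), "y4")
        kids = tree.seed_node.child_nodes()
        assert len(kids) == 2
        sides = [{l.taxon.label for l in k.leaf_iter()} for k in kids]
        assert {"y4"} in sides

    def test_root_to_tip_lengths_positive(self):
        msa = _two_cluster_msa(seed=2)
        tree = root_with_outgroup(tree_from_msa(msa), "y4")
        rtt = root_to_tip_lengths(tree)
        assert set(rtt) == {r.id for r in msa}
        assert all(v >= 0 for v in rtt.values())
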