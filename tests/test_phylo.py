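import math

import dendropy
import numpy as np
import pytest
from skbio import TreeNode

from oracles import (
    all_unrooted_topologies,
    fit_branch_lengths,
    random_additive,
    topology_splits,
)
from polyploidkit.phylo import (
    DistanceMatrix,
    SaturationError,
    _bipartitions,
    bootstrap_support,
    jc_distance,
    nj_tree,
    rf_metrics,
    unroot,
)

def tree_splits(tree):
    return _bipartitions(unroot(tree))[0]


# ---------------------------------------------------------------------------


class TestJcDistance:
    def test_identical_pair_zero(self):
        dm = jc_distance({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGA"})
        assert dm.d[0, 1] == 0.0

    def test_closed_form_ten_percent(self):
        s1 = "A" * 100
        s2 = "T" * 10 + "A" * 90
        dm = jc_distance({"a": s1, "b": s2, "c": s1})
        want = -0.75 * math.log(1 - 4 / 3 * 0.1)
        assert dm.d[0, 1] == pytest.approx(want, abs=1e-6)
        assert want == pytest.approx(0.107326, abs=1e-6)

    def test_saturation_error(self):
        s1 = "A" * 100
        s2 = "T" * 75 + "A" * 25
        with pytest.raises(SaturationError, match="a,b"):
            jc_distance({"a": s1, "b": s2, "c": s1})

    def test_pairwise_deletion(self):
        dm = jc_distance({"a": "ANAA", "b": "AT-A", "c": "AAAA"})
        # a-b compares positions 0 and 3 only: identical
        assert dm.d[0, 1] == 0.0

    def test_monotone_in_p(self):
        last = -1.0
        base = "A" * 200
        for k in range(0, 140, 10):
            other = "T" * k + "A" * (200 - k)
            d = jc_distance({"a": base, "b": other, "c": base}).d[0, 1]
            assert d > last
            last = d


class TestNjTree:
    def test_three_leaf_closed_form(self):
        mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], mat))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_leaf_additive_exact(self):
        # tree ((A:1,B:2):2,(C:3,D:4)): AB=3 AC=6 AD=7 BC=7 BD=8 CD=7
        labels = ["A", "B", "C", "D"]
        mat = np.array([[0, 3, 6, 7], [3, 0, 7, 8],
                        [6, 7, 0, 7], [7, 8, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(labels, mat))
        splits = tree_splits(tree)
        assert splits == {frozenset({"C", "D"})}
        tt = tree.tip_tip_distances()
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                assert tt[x, y] == pytest.approx(mat[i, j], abs=1e-9)

    def test_recovers_all_additive_topologies(self):
        """For random additive matrices on 4-6 leaves, NJ reproduces the
        generating topology (verified by exhaustive least-squares fit over
        every topology) and the exact path distances."""
        rng = np.random.default_rng(23)
        for n in (4, 5, 6):
            labels = [f"t{i}" for i in range(n)]
            for _ in range(8):
                dm, adj, dmap = random_additive(labels, rng)
                # exhaustive oracle: exactly one topology fits additively
                fits = []
                for cand in all_unrooted_topologies(labels):
                    resid, _ = fit_branch_lengths(cand, labels, dmap)
                    if resid < 1e-8:
                        fits.append(topology_splits(cand, labels))
                assert len(fits) == 1
                tree = nj_tree(dm)
                assert tree_splits(tree) == fits[0]
                tt = tree.tip_tip_distances()
                for i, x in enumerate(labels):
                    for j, y in enumerate(labels):
                        if i != j:
                            assert tt[x, y] == pytest.approx(
                                dm.d[i, j], abs=1e-9)

    def test_agrees_with_skbio_nj(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(7)]
        base = rng.uniform(0.1, 1.0, size=(7, 7))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0)
        ours = nj_tree(DistanceMatrix(labels, mat))
        theirs = skbio_nj(SkbioDM(mat, ids=labels))
        assert tree_splits(ours) == tree_splits(theirs)

    def test_deterministic_under_ties(self):
        mat = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(["d", "c", "b", "a"], mat)
        t1 = nj_tree(dm)
        t2 = nj_tree(dm)
        assert str(t1) == str(t2)

    def test_negative_branch_clamped(self):
        # a matrix known to produce a negative NJ branch estimate
        mat = np.array([[0, 1, 6, 6], [1, 0, 6, 6],
                        [6, 6, 0, 1], [6, 6, 1, 0]], float)
        mat[0, 1] = mat[1, 0] = 8.0  # violates additivity
        tree = nj_tree(DistanceMatrix(list("abcd"), mat))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


class TestRf:
    def test_identical_trees(self):
        t = TreeNode.read(["((a,b)n1,(c,d)n2,e);"])
        rf = rf_metrics(t, t.copy())
        assert (rf.rf, rf.nrf) == (0, 0.0)

    def test_five_leaf_nni_pair(self):
        t1 = TreeNode.read(["((a,b),(c,d),e);"])
        t2 = TreeNode.read(["((a,b),(c,e),d);"])  # one NNI: d <-> e swap
        rf = rf_metrics(t1, t2)
        assert (rf.rf, rf.max_rf, rf.nrf) == (2, 4, 0.5)

    def test_leaf_set_mismatch(self):
        t1 = TreeNode.read(["((a,b),(c,d),e);"])
        t2 = TreeNode.read(["((a,b),(c,d),f);"])
        with pytest.raises(ValueError, match="[ef]"):
            rf_metrics(t1, t2)

    def test_metric_properties_and_dendropy_agreement(self):
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(10)]
        trees = []
        for _ in range(3):
            order = rng.permutation(labels).tolist()
            nwk = "(" + ",".join(
                ["(" * (len(order) - 2) + order[0]]
                + [o + ")" for o in order[1:-1]]) + f",{order[-1]});"
            trees.append(TreeNode.read([nwk]))
        tns = dendropy.TaxonNamespace()
        for ti in trees:
            for tj in trees:
                ours = rf_metrics(ti, tj)
                d1 = dendropy.Tree.get(data=str(ti), schema="newick",
                                       taxon_namespace=tns)
                d2 = dendropy.Tree.get(data=str(tj), schema="newick",
                                       taxon_namespace=tns)
                want = dendropy.calculate.treecompare.symmetric_difference(
                    d1, d2)
                assert ours.rf == want
                assert ours.rf == rf_metrics(tj, ti).rf  # symmetry
        # triangle inequality on the triple
        r01 = rf_metrics(trees[0], trees[1]).rf
        r12 = rf_metrics(trees[1], trees[2]).rf
        r02 = rf_metrics(trees[0], trees[2]).rf
        assert r02 <= r01 + r12

    def test_unresolved_tree_rejected(self):
        t1 = TreeNode.read(["((a,b),(c,d),e);"])
        star = TreeNode.read(["(a,b,c,d,e);"])
        with pytest.raises(ValueError, match="resolved"):
            rf_metrics(t1, star)


def _clean_alignment():
    """Alignment generated on a fixed 6-leaf tree with no homoplasy: each
    internal split gets its own block of diagnostic columns."""
    taxa = ["a", "b", "c", "d", "e", "f"]
    splits = [{"a", "b"}, {"a", "b", "c"}, {"e", "f"}]
    cols = []
    for side in splits:
        for _ in range(20):
            cols.append(["T" if t in side else "A" for t in taxa])
    rng = np.random.default_rng(2)
    for _ in range(40):  # unique (non-conflicting) noise per taxon
        tax = taxa[int(rng.integers(6))]
        cols.append(["C" if t == tax else "A" for t in taxa])
    cols.extend([["A"] * 6] * 120)  # constant sites keep distances far
    # below the Jukes-Cantor saturation bound in every bootstrap replicate
    aln = {t: "".join(col[i] for col in cols) for i, t in enumerate(taxa)}
    return aln


class TestBootstrap:
    def test_clean_signal_full_support(self):
        aln = _clean_alignment()
        tree, completed = bootstrap_support(aln, n_reps=50, seed=3)
        assert completed == 50
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if n.support is not None]
        assert supports and all(s == 50 for s in supports)

    def test_deterministic_and_seed_independent_topology(self):
        aln = _clean_alignment()
        t1, _ = bootstrap_support(aln, n_reps=20, seed=5)
        t2, _ = bootstrap_support(aln, n_reps=20, seed=5)
        assert str(t1) == str(t2)
        t3, _ = bootstrap_support(aln, n_reps=20, seed=99)
        assert tree_splits(t3) == tree_splits(t1)

    def test_zero_reps_point_tree_only(self):
        aln = _clean_alignment()
        tree, completed = bootstrap_support(aln, n_reps=0, seed=0)
        assert completed == 0
        assert all(n.support is None
                   for n in tree.non_tips(include_self=False))

    def test_supports_bounded(self):
        rng = np.random.default_rng(8)
        taxa = [f"t{i}" for i in range(6)]
        base = rng.integers(0, 4, 120)
        aln = {}
        for t in taxa:  # ~10% divergence from a shared base sequence
            c = base.copy()
            hits = rng.random(120) < 0.1
            c[hits] = (c[hits] + rng.integers(1, 4, int(hits.sum()))) % 4
            aln[t] = "".join("ACGT"[i] for i in c)
        tree, completed = bootstrap_support(aln, n_reps=30, seed=1)
        assert completed > 0
        for n in tree.non_tips(include_self=False):
            if n.support is not None:
                assert 0 <= n.support <= completed
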