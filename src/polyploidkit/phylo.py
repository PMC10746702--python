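"""Distance phylogenetics: Jukes–Cantor distances, neighbor joining with
bootstrap, and Robinson–Foulds tree comparison.

Neighbor joining is the Saitou–Nei agglomeration on the Q criterion
(Studier–Keppler form). Negative branch-length estimates are clamped to
zero with the deficit moved to the sibling branch, so path lengths are
preserved; Q ties are broken by the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf), which makes
the output deterministic.

Robinson–Foulds distances are computed over non-trivial bipartitions of
fully resolved unrooted trees; maxRF = 2(n-3) and nRF = RF/maxRF, the
convention under which two 23-taxon trees have maxRF 40.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

log = logging.getLogger("polyploidkit")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or (np.diag(self.d) != 0).any():
            raise ValueError("matrix must be symmetric with zero diagonal")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("entries must be finite and non-negative")


class SaturationError(ValueError):
    pass


def jc_distance(seqs: dict[str, str]) -> DistanceMatrix:
    """Jukes–Cantor distance matrix with pairwise deletion of gap/N sites."""
    labels = list(seqs)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    arrs = [np.frombuffer(seqs[l].encode(), dtype=np.uint8) for l in labels]
    L = arrs[0].size
    if any(a.size != L for a in arrs):
        raise ValueError("sequences must be aligned to equal length")
    good = [(a != ord("N")) & (a != ord("-")) for a in arrs]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            use = good[i] & good[j]
            m = int(use.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            p = float((arrs[i][use] != arrs[j][use]).sum()) / m
            if p >= 0.75:
                raise SaturationError(
                    f"saturated pair {labels[i]},{labels[j]} (p={p:.3f})"
                )
            d[i, j] = d[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; root is a trifurcation)."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=l) for l in dm.labels]
    tags = list(dm.labels)  # smallest leaf label per cluster, for tie-breaks
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], *sorted((tags[active[a]], tags[active[b]])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * d[i, j] + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        new = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = max(
                0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j])
            )
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(0.0, ln)
    order = sorted(range(3), key=lambda x: tags[active[x]])
    root = TreeNode(children=[nodes[active[x]] for x in order])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def unroot(tree: TreeNode) -> TreeNode:
    """Collapse a 2-child root into the unrooted trifurcation form."""
    tree = tree.copy()
    while len(tree.children) == 2:
        internal = next((c for c in tree.children if not c.is_tip()), None)
        if internal is None:
            break  # 2-leaf tree: nothing to do
        other = next(c for c in tree.children if c is not internal)
        other.length = (other.length or 0.0) + (internal.length or 0.0)
        tree.remove(internal)
        for gc in list(internal.children):
            internal.remove(gc)
            tree.append(gc)
    return tree


def _bipartitions(tree: TreeNode) -> tuple[set[frozenset], int]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized to the
    side not containing the reference (smallest) leaf."""
    leaves = sorted(t.name for t in tree.tips())
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")
    all_leaves = frozenset(leaves)
    ref = leaves[0]
    n = len(leaves)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = all_leaves - clade if ref in clade else clade
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits, n


@dataclass
class RFReport:
    rf: int
    max_rf: int
    nrf: float
    n_leaves: int


def rf_metrics(t1: TreeNode, t2: TreeNode, strict: bool = True) -> RFReport:
    """Robinson–Foulds distance, its maximum 2(n-3), and the ratio.

    Trees are compared unrooted; with ``strict`` both trees must be
    fully resolved (n-3 internal splits each).
    """
    u1, u2 = unroot(t1), unroot(t2)
    s1, n1 = _bipartitions(u1)
    s2, n2 = _bipartitions(u2)
    l1 = {t.name for t in u1.tips()}
    l2 = {t.name for t in u2.tips()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    n = n1
    if strict and (len(s1) != n - 3 or len(s2) != n - 3):
        raise ValueError("trees must be fully resolved (binary) for RF")
    rf = len(s1 ^ s2)
    max_rf = 2 * (n - 3)
    nrf = rf / max_rf if max_rf else 0.0
    return RFReport(rf, max_rf, nrf, n)


def bootstrap_support(
    seqs: dict[str, str],
    n_reps: int = 1000,
    seed: int | None = 0,
) -> tuple[TreeNode, int]:
    """NJ point-estimate tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement; each replicate is
    rebuilt with NJ, and every internal bipartition of the point tree is
    annotated (``node.support``) with the number of completed replicates
    containing it. Replicates with a saturated or incomparable pair are
    skipped and logged. Returns (tree, completed replicates).
    """
    point = nj_tree(jc_distance(seqs))
    if n_reps == 0:
        return point, 0
    labels = list(seqs)
    mat = np.array([list(seqs[l]) for l in labels])
    L = mat.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    point_splits, _ = _bipartitions(point)
    completed = 0
    for rep in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = {l: "".join(mat[i, cols]) for i, l in enumerate(labels)}
        try:
            rep_tree = nj_tree(jc_distance(resampled))
        except ValueError as exc:
            log.warning("bootstrap replicate %d skipped: %s", rep, exc)
            continue
        completed += 1
        rep_splits, _ = _bipartitions(rep_tree)
        for s in point_splits & rep_splits:
            counts[s] = counts.get(s, 0) + 1
    for node in point.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        leaves = frozenset(t.name for t in point.tips())
        ref = min(leaves)
        side = leaves - clade if ref in clade else clade
        if 2 <= len(side) <= len(leaves) - 2:
            node.support = counts.get(side, 0)
            node.name = str(node.support)  # serialized as newick node label
    return point, completed


def read_newick(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    return unroot(tree)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
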