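"""Independent reference implementations used only by the test suite.

These deliberately re-derive each quantity from first principles with a
different algorithmic structure than the package (recursive enumeration
instead of lookup tables, O(n^2 L) loops instead of vectorized counts),
so that agreement is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data import CodonTable

_CODE = CodonTable.unambiguous_dna_by_id[1]


def _aa(codon: str) -> str:
    return _CODE.forward_table.get(codon, "*")


def ng86_oracle(pairs: list[tuple[str, str]]) -> dict:
    """NG86 S/N/Sd/Nd/dS/dN by explicit per-codon path enumeration."""
    S = N = Sd = Nd = 0.0
    for c1, c2 in pairs:
        S += (_syn_sites(c1) + _syn_sites(c2)) / 2.0
        N += 3.0 - (_syn_sites(c1) + _syn_sites(c2)) / 2.0
        sd, nd = _pair_counts(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "dS": _jc(pS), "dN": _jc(pN)}


def _jc(p: float):
    if p >= 0.75 - 1e-9:  # same epsilon guard as the package
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _syn_sites(codon: str) -> float:
    count = 0
    for pos in range(3):
        for b in "ACGT":
            if b != codon[pos]:
                if _aa(codon[:pos] + b + codon[pos + 1:]) == _aa(codon):
                    count += 1
    return count / 3.0


def _pair_counts(c1: str, c2: str) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    complete: list[tuple[int, int, bool]] = []

    def recurse(cur, remaining, sd, nd, blocked):
        if not remaining:
            complete.append((sd, nd, blocked))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            hit_stop = _aa(nxt) == "*" and nxt != c2
            step_syn = _aa(cur) == _aa(nxt)
            recurse(nxt, [p for p in remaining if p != pos],
                    sd + step_syn, nd + (not step_syn), blocked or hit_stop)

    recurse(c1, positions, 0, 0, False)
    usable = [p for p in complete if not p[2]] or complete
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def pi_oracle(seqs: list[str]) -> tuple[float, int]:
    """Nucleotide diversity by direct pairwise loops with complete deletion."""
    n = len(seqs)
    L = len(seqs[0])
    usable = [i for i in range(L)
              if all(s[i] not in "N-" for s in seqs)]
    if not usable:
        raise ValueError("no usable sites")
    total = 0.0
    npairs = 0
    for a, b in itertools.combinations(range(n), 2):
        diff = sum(1 for i in usable if seqs[a][i] != seqs[b][i])
        total += diff / len(usable)
        npairs += 1
    return total / npairs, len(usable)


def best_chain_oracle(anchors, orientation: str, max_gap: int,
                      gap_penalty: float) -> float:
    """Maximum chain score by depth-first enumeration of all chains."""
    sign = 1 if orientation == "plus" else -1
    best = 0.0

    def extend(last_idx, score):
        nonlocal best
        best = max(best, score)
        la = anchors[last_idx]
        for j, aj in enumerate(anchors):
            da = aj.rank_a - la.rank_a
            db = sign * (aj.rank_b - la.rank_b)
            if 0 < da <= max_gap and 0 < db <= max_gap:
                extend(j, score + aj.score - gap_penalty * ((da - 1) + (db - 1)))

    for i, a in enumerate(anchors):
        extend(i, a.score)
    return best


def align_score_oracle(p1: str, p2: str, matrix, gap_open=11.0, gap_extend=1.0):
    """Best global affine-gap alignment score by exhaustive enumeration.

    A gap of length L costs gap_open + gap_extend * L. Feasible only for
    short sequences (the alignment count grows like Delannoy numbers).
    """
    best = -math.inf

    def gap_cost(length):
        return gap_open + gap_extend * length

    def recurse(i, j, score, gap_state):
        nonlocal best
        if i == len(p1) and j == len(p2):
            best = max(best, score)
            return
        if i < len(p1) and j < len(p2):
            recurse(i + 1, j + 1, score + matrix[p1[i], p2[j]], None)
        if i < len(p1):  # gap in p2
            extra = gap_cost(1) if gap_state != "del" else gap_extend
            recurse(i + 1, j, score - extra, "del")
        if j < len(p2):  # gap in p1
            extra = gap_cost(1) if gap_state != "ins" else gap_extend
            recurse(i, j + 1, score - extra, "ins")

    recurse(0, 0, 0.0, None)
    return best


def assembly_stats_oracle(lengths: list[int]) -> dict:
    """Definition-based Nx/Lx: scan sorted lengths until the cumulative
    sum first reaches x% of the total."""
    total = sum(lengths)
    out = {"n_contigs": len(lengths), "total_bp": total}
    for x in (50, 90):
        acc = 0
        for k, length in enumerate(sorted(lengths, reverse=True), 1):
            acc += length
            if acc >= total * x / 100.0:
                out[f"N{x}"] = length
                out[f"L{x}"] = k
                break
    return out


# ---------------------------------------------------------------------------
# exhaustive unrooted-topology machinery (neighbor-joining oracle)

import numpy as np

from polyploidkit.phylo import DistanceMatrix as PkDistanceMatrix

def all_unrooted_topologies(labels):
    """Every unrooted binary topology as an adjacency dict, by sequential
    leaf insertion into every edge."""
    a, b, c = labels[:3]
    base = {0: [a, b, c], a: [0], b: [0], c: [0]}
    trees = [(base, 1)]
    for leaf in labels[3:]:
        nxt = []
        for adj, n_int in trees:
            for u, v in list(_edges(adj)):
                new = {k: list(vs) for k, vs in adj.items()}
                w = n_int
                new[u].remove(v)
                new[v].remove(u)
                new[u].append(w)
                new[v].append(w)
                new[w] = [u, v, leaf]
                new[leaf] = [w]
                nxt.append((new, n_int + 1))
        trees = nxt
    return [adj for adj, _ in trees]


def _edges(adj):
    seen = set()
    for u, vs in adj.items():
        for v in vs:
            key = tuple(sorted((repr(u), repr(v))))
            if key not in seen:
                seen.add(key)
                yield u, v


def _path(adj, src, dst):
    stack = [(src, [])]
    visited = {src}
    while stack:
        node, path = stack.pop()
        if node == dst:
            return path
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                key = tuple(sorted((repr(node), repr(nb))))
                stack.append((nb, path + [key]))
    raise AssertionError("disconnected")


def topology_splits(adj, labels):
    """Non-trivial bipartitions by cutting each internal edge."""
    splits = set()
    ref = min(labels)
    for u, v in _edges(adj):
        if not (isinstance(u, int) and isinstance(v, int)):
            continue
        # BFS from u without crossing (u, v)
        side = set()
        stack = [u]
        visited = {u, v}
        while stack:
            node = stack.pop()
            if not isinstance(node, int):
                side.add(node)
            for nb in adj[node]:
                if nb not in visited:
                    visited.add(nb)
                    stack.append(nb)
        side = frozenset(side)
        if ref in side:
            side = frozenset(labels) - side
        splits.add(side)
    return splits


def fit_branch_lengths(adj, labels, dm):
    """Least-squares branch lengths for one topology; returns residual."""
    edge_list = list(_edges(adj))
    edge_idx = {tuple(sorted((repr(u), repr(v)))): i
                for i, (u, v) in enumerate(edge_list)}
    rows, rhs = [], []
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            row = np.zeros(len(edge_list))
            for key in _path(adj, x, y):
                row[edge_idx[key]] = 1.0
            rows.append(row)
            rhs.append(dm[x, y])
    A, b = np.array(rows), np.array(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(np.abs(A @ sol - b).max()), sol


def random_additive(labels, rng):
    """A random additive distance matrix and its generating topology."""
    topos = all_unrooted_topologies(labels)
    adj = topos[int(rng.integers(len(topos)))]
    lengths = {tuple(sorted((repr(u), repr(v)))): float(rng.uniform(0.05, 1.0))
               for u, v in _edges(adj)}
    d = {}
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            d[x, y] = d[y, x] = sum(lengths[k] for k in _path(adj, x, y))
    n = len(labels)
    mat = np.zeros((n, n))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                mat[i, j] = d[x, y]
    return PkDistanceMatrix(list(labels), mat), adj, d


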