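"""Homology anchors and collinear synteny-block chaining.

Blocks are chains of homologous gene pairs whose order is conserved in
gene-rank space, the classic evidence of shared ancestry or whole-genome
duplication. The chainer follows the MCScanX conventions: gaps measured
in gene ranks (not bp), default match size 5 and maximum gap 25, with
dynamic-programming chain scoring and greedy extraction of disjoint
chains by descending score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .io import GeneModel, HomologyHit

log = logging.getLogger("polyploidkit")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# A gap of length L costs 11 + L (affine: open 11, extend 1).
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()
_AA_ALPHABET = frozenset(str(_BLOSUM62.alphabet))


def align_proteins(p1: str, p2: str) -> dict[str, float]:
    """Global protein alignment score and identity (BLOSUM62, affine gaps).

    Identity is the fraction of matching residues over all alignment
    columns, gap columns included (the BLAST tabular convention).
    """
    if not p1 or not p2:
        raise ValueError("empty protein sequence")
    for p in (p1, p2):
        bad = set(p) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid symbol: {sorted(bad)}")
    aln = _ALIGNER.align(p1, p2)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return {
        "score": float(aln.score),
        "identity": matches / len(a),
        "aligned": (a, b),
    }


@dataclass
class Anchor:
    """A homologous gene pair anchored at its gene ranks."""

    gene_a: str
    gene_b: str
    contig_a: str
    contig_b: str
    rank_a: int
    rank_b: int
    score: float

    def __post_init__(self):
        if self.score <= 0:
            raise ValueError("anchor score must be positive")


@dataclass
class SyntenyBlock:
    """A strictly collinear chain of anchors between two contigs."""

    block_id: int
    contig_a: str
    contig_b: str
    anchors: list[Anchor]
    orientation: str  # "plus" or "minus"
    score: float
    ks_summary: float | None = None

    def __len__(self) -> int:
        return len(self.anchors)

    def genes_a(self) -> list[str]:
        return [a.gene_a for a in self.anchors]

    def genes_b(self) -> list[str]:
        return [a.gene_b for a in self.anchors]


def find_anchors(
    genesA: list[GeneModel],
    genesB: list[GeneModel],
    hits: list[HomologyHit],
    min_identity: float = 0.5,
    top_k: int = 5,
    self_mode: bool = False,
) -> list[Anchor]:
    """Filter homology hits into anchors: per query, the ``top_k`` hits by
    score with identity >= ``min_identity``; self-hits dropped in self mode."""
    byA = {g.gene_id: g for g in genesA}
    byB = {g.gene_id: g for g in genesB}
    per_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query not in byA or h.subject not in byB:
            raise ValueError(f"hit references unknown gene: {h.query}->{h.subject}")
        if self_mode and h.query == h.subject:
            continue
        if h.identity < min_identity:
            continue
        per_query.setdefault(h.query, []).append(h)
    anchors = []
    for q in sorted(per_query):
        kept = sorted(per_query[q], key=lambda h: (-h.score, h.subject))[:top_k]
        for h in kept:
            ga, gb = byA[h.query], byB[h.subject]
            anchors.append(
                Anchor(ga.gene_id, gb.gene_id, ga.contig_id, gb.contig_id,
                       ga.gene_rank, gb.gene_rank, h.score)
            )
    return anchors


def hits_from_families(
    genesA: list[GeneModel],
    genesB: list[GeneModel],
    family_of: dict[str, str],
    translate_fn,
) -> list[HomologyHit]:
    """Score candidate homolog pairs within shared gene families.

    Plays the role of an all-vs-all protein homology search restricted
    to pairs that share a family assignment, which is where all true
    anchors live; the pairwise aligner supplies score and identity.
    """
    byfamB: dict[str, list[GeneModel]] = {}
    for g in genesB:
        fam = family_of.get(g.gene_id)
        if fam is not None:
            byfamB.setdefault(fam, []).append(g)
    protA = {g.gene_id: translate_fn(g.cds) for g in genesA}
    protB = {g.gene_id: translate_fn(g.cds) for g in genesB}
    hits = []
    for ga in genesA:
        fam = family_of.get(ga.gene_id)
        for gb in byfamB.get(fam, []):
            res = align_proteins(protA[ga.gene_id], protB[gb.gene_id])
            if res["score"] > 0:
                hits.append(
                    HomologyHit(ga.gene_id, gb.gene_id, res["identity"],
                                res["score"])
                )
    return hits


def _chain_group(
    anchors: list[Anchor],
    orientation: str,
    max_gap: int,
    gap_penalty: float,
) -> tuple[list[int], float]:
    """Best chain (anchor indices, score) for one contig pair and orientation."""
    sign = 1 if orientation == "plus" else -1
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b),
    )
    best_score = [0.0] * len(anchors)
    prev = [-1] * len(anchors)
    for oi, i in enumerate(order):
        ai = anchors[i]
        best_score[i] = ai.score
        for j in order[:oi]:
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            db = sign * (ai.rank_b - aj.rank_b)
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            cand = best_score[j] + ai.score - gap_penalty * ((da - 1) + (db - 1))
            if cand > best_score[i] + 1e-12:
                best_score[i] = cand
                prev[i] = j
    if not anchors:
        return [], 0.0
    end = max(range(len(anchors)),
              key=lambda i: (best_score[i], -anchors[i].rank_a))
    chain = []
    i = end
    while i != -1:
        chain.append(i)
        i = prev[i]
    return chain[::-1], best_score[end]


def chain_collinear(
    anchors: list[Anchor],
    max_gap: int = 25,
    min_block_size: int = 5,
    gap_penalty: float = 1.0,
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks per contig pair and orientation.

    Repeatedly extracts the maximum-score chain (strictly increasing
    rank_a; rank_b strictly increasing for plus, decreasing for minus,
    rank gaps <= ``max_gap`` on both sides), removes its anchors and
    recurses; chains shorter than ``min_block_size`` are discarded.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.contig_a, a.contig_b), []).append(a)
    blocks: list[SyntenyBlock] = []
    block_id = 0
    for key in sorted(groups):
        pool = groups[key]
        while pool:
            candidates = []
            for orientation in ("plus", "minus"):
                chain, score = _chain_group(pool, orientation, max_gap, gap_penalty)
                if chain:
                    candidates.append((score, orientation, chain))
            if not candidates:
                break
            score, orientation, chain = max(candidates, key=lambda c: (c[0], c[1]))
            members = [pool[i] for i in chain]
            taken = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in taken]
            if len(members) >= min_block_size:
                blocks.append(
                    SyntenyBlock(block_id, key[0], key[1], members,
                                 orientation, score)
                )
                block_id += 1
    return blocks


def self_synteny(
    genes: list[GeneModel],
    anchors: list[Anchor],
    tandem_rank_window: int = 5,
    max_gap: int = 25,
    min_block_size: int = 5,
    gap_penalty: float = 1.0,
) -> list[SyntenyBlock]:
    """Self-synteny with tandem filtering and canonical pair reporting.

    Anchors joining nearby genes on one contig (|rank_a - rank_b| <
    ``tandem_rank_window``) are tandem duplicates, not homoeologous
    copies, and are removed; each duplicated region pair is reported
    once, with the (contig, gene) pair in canonical order.
    """
    seen: set[tuple[str, str]] = set()
    filtered = []
    for a in anchors:
        if a.gene_a == a.gene_b:
            continue
        if (a.contig_a == a.contig_b
                and abs(a.rank_a - a.rank_b) < tandem_rank_window):
            log.debug("tandem filter: %s ~ %s", a.gene_a, a.gene_b)
            continue
        key = (min(a.gene_a, a.gene_b), max(a.gene_a, a.gene_b))
        if key in seen:
            continue
        seen.add(key)
        if (a.contig_a, a.rank_a, a.gene_a) > (a.contig_b, a.rank_b, a.gene_b):
            a = Anchor(a.gene_b, a.gene_a, a.contig_b, a.contig_a,
                       a.rank_b, a.rank_a, a.score)
        filtered.append(a)
    return chain_collinear(filtered, max_gap, min_block_size, gap_penalty)


def write_blocks(blocks: list[SyntenyBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tcontig_a\tcontig_b\torientation\tn_anchors"
                 "\tscore\tks_summary\tanchor_pairs\n")
        for b in blocks:
            pairs = ",".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors)
            ks = "NA" if b.ks_summary is None else f"{b.ks_summary:.5f}"
            fh.write(f"{b.block_id}\t{b.contig_a}\t{b.contig_b}"
                     f"\t{b.orientation}\t{len(b)}\t{b.score:.2f}\t{ks}\t{pairs}\n")
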