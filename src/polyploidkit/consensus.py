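"""Quality-filtered consensus sequences and per-gene nucleotide diversity.

Consensus building applies substitution calls with phred quality >= 30
(strict >= on the threshold) to a shared reference; because every
accession's consensus keeps the reference coordinate system, the
consensuses are already a gap-free multiple alignment and nucleotide
diversity can be computed gene by gene without any MSA step.

Pi follows the classic definition: the average proportion of differing
sites over all sequence pairs, with complete deletion of columns that
contain a gap or N in any sequence (the DnaSP convention). The reported
standard deviation is the sample SD of the per-pair per-site distances,
matching how diversity bar plots are usually annotated when the paper's
estimator is unstated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GeneModel, GenomeSequence, VariantRecord

log = logging.getLogger("polyploidkit")


@dataclass
class CoverageMask:
    """Reference intervals (0-based half-open) covered in one accession."""

    accession: str
    contig_id: str
    intervals: list[tuple[int, int]]

    def covered_fraction(self, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        covered = 0
        for s, e in self.intervals:
            covered += max(0, min(e, end) - max(s, start))
        return covered / (end - start)


def apply_variants(
    reference: GenomeSequence,
    variants: list[VariantRecord],
    min_qual: float = 30.0,
) -> GenomeSequence:
    """Apply substitution calls with qual >= ``min_qual`` to the reference.

    Indel records are skipped with a warning so the consensus stays
    reference-length; conflicting accepted substitutions at one position
    keep the highest-quality call.
    """
    seq = np.frombuffer(reference.residues.encode(), dtype=np.uint8).copy()
    best: dict[int, VariantRecord] = {}
    for v in sorted(variants, key=lambda v: (v.pos, -v.qual)):
        if v.contig_id != reference.id:
            continue
        ref_here = reference.residues[v.pos : v.pos + len(v.ref)]
        if ref_here != v.ref:
            raise ValueError(
                f"ref allele mismatch at {v.contig_id}:{v.pos + 1}: "
                f"expected {ref_here!r}, record says {v.ref!r}"
            )
        if len(v.ref) != 1 or len(v.alt) != 1:
            log.warning("skipping indel at %s:%d", v.contig_id, v.pos + 1)
            continue
        if v.qual < min_qual:
            continue
        if v.pos in best:
            log.warning("overlapping variants at %s:%d; keeping qual %.1f",
                        v.contig_id, v.pos + 1, best[v.pos].qual)
            continue
        best[v.pos] = v
    for pos, v in best.items():
        seq[pos] = ord(v.alt)
    return GenomeSequence(reference.id, seq.tobytes().decode(),
                          reference.topology)


def filter_covered_genes(
    genes: list[GeneModel],
    masks: list[CoverageMask],
    min_fraction: float = 1.0,
) -> list[GeneModel]:
    """Keep genes covered >= ``min_fraction`` in EVERY accession."""
    by_acc: dict[str, dict[str, list[CoverageMask]]] = {}
    for m in masks:
        by_acc.setdefault(m.accession, {}).setdefault(m.contig_id, []).append(m)
    kept = []
    for g in genes:
        ok = True
        for acc, contigs in by_acc.items():
            if g.contig_id not in contigs:
                raise ValueError(
                    f"{g.gene_id}: no coverage mask for contig "
                    f"{g.contig_id!r} in accession {acc!r}"
                )
            frac = max(m.covered_fraction(g.start, g.end)
                       for m in contigs[g.contig_id])
            if frac < min_fraction:
                log.warning("dropping %s: %.0f%% covered in %s",
                            g.gene_id, 100 * frac, acc)
                ok = False
                break
        if ok:
            kept.append(g)
    return kept


@dataclass
class PiResult:
    gene_id: str
    pi: float
    sd: float
    n_sites: int
    n_seqs: int


_MISSING = frozenset(b"N-")


def nucleotide_diversity(seqs: list[str], gene_id: str = "") -> PiResult:
    """Pi over equal-length sequences sharing reference coordinates.

    pi = 2 / (n (n-1)) * sum_{i<j} d_ij / L_used, where d_ij counts
    differing sites among the columns free of gaps and Ns in every
    sequence (complete deletion).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have identical length")
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
    usable = ~np.logical_or.reduce([(mat == ord(c)) for c in "N-"]).any(axis=0)
    L_used = int(usable.sum())
    if L_used == 0:
        raise ValueError(f"no comparable sites for {gene_id or 'alignment'}")
    sub = mat[:, usable]
    dists = []
    for i in range(n):
        diff = (sub[i + 1 :] != sub[i]).sum(axis=1)
        dists.extend((diff / L_used).tolist())
    dists = np.array(dists)
    sd = float(dists.std(ddof=1)) if dists.size > 1 else 0.0
    return PiResult(gene_id, float(dists.mean()), sd, L_used, n)


def pi_table(
    consensuses: dict[str, GenomeSequence],
    genes: list[GeneModel],
) -> list[PiResult]:
    """One Pi estimate per gene across accession consensuses, sorted by
    descending Pi (ties by gene id)."""
    results = []
    for g in genes:
        window = [c.residues[g.start : g.end] for c in consensuses.values()]
        results.append(nucleotide_diversity(window, g.gene_id))
    results.sort(key=lambda r: (-r.pi, r.gene_id))
    return results


def write_pi_table(results: list[PiResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tpi\tsd\tn_sites\tn_seqs\n")
        for r in results:
            fh.write(f"{r.gene_id}\t{r.pi:.6f}\t{r.sd:.6f}"
                     f"\t{r.n_sites}\t{r.n_seqs}\n")
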