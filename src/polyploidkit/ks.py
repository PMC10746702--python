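"""Synonymous/nonsynonymous substitution rates (Nei–Gojobori 1986).

The NG86 method counts, per codon, the expected number of synonymous
sites (the fraction of the three single-base neighbours at each position
that preserve the amino acid) and, per codon pair, the synonymous and
nonsynonymous differences averaged with equal weight over all shortest
mutational paths (paths through stop codons excluded). Proportions are
corrected for multiple hits with the Jukes–Cantor formula; proportions
at or beyond the 3/4 ceiling are flagged saturated rather than forced
into the logarithm's domain.

Modal Ks — the peak of the Ks distribution over many gene pairs or
synteny blocks — dates divergence events such as polyploidization; the
mode is found by Gaussian kernel density estimation rather than a
histogram, so no bin width needs choosing.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from ._codons import ND_PAIR, SD_PAIR, SYN_SITES, codon_indices, translate
from .synteny import SyntenyBlock, align_proteins

log = logging.getLogger("polyploidkit")


@dataclass
class KsEstimate:
    """NG86 site and difference counts with JC-corrected rates.

    ``dS``/``dN`` are ``None`` when the corresponding proportion is
    saturated (p >= 3/4) and the correction is undefined.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    n_codons: int

    @property
    def saturated(self) -> bool:
        return self.dS is None or self.dN is None


def jukes_cantor(p: float) -> float | None:
    """JC69 distance from a mismatch proportion; None at saturation.

    The saturation test carries a small epsilon so that proportions that
    are exactly 3/4 up to floating-point accumulation order are flagged
    consistently.
    """
    if p >= 0.75 - 1e-9:
        return None
    if p <= 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def codon_align(cds1: str, cds2: str) -> tuple[np.ndarray, np.ndarray]:
    """Protein-guided codon alignment of two CDS.

    Translates both sequences, aligns the proteins globally and threads
    the codons back through the protein alignment; columns with a gap in
    either protein are dropped. Returns codon-index arrays of equal
    length, one column per aligned codon pair.
    """
    p1, p2 = translate(cds1), translate(cds2)
    idx1, idx2 = codon_indices(cds1)[: len(p1)], codon_indices(cds2)[: len(p2)]
    if len(p1) == len(p2) and p1 == p2:
        return idx1, idx2  # fast path: nothing to gap
    a, b = align_proteins(p1, p2)["aligned"]
    cols1, cols2 = [], []
    i = j = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            cols1.append(idx1[i])
            cols2.append(idx2[j])
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return np.array(cols1, dtype=np.int64), np.array(cols2, dtype=np.int64)


def ng86(codons1: np.ndarray, codons2: np.ndarray) -> KsEstimate:
    """NG86 estimate from two aligned codon-index arrays."""
    codons1 = np.asarray(codons1, dtype=np.int64)
    codons2 = np.asarray(codons2, dtype=np.int64)
    if codons1.shape != codons2.shape or codons1.size == 0:
        raise ValueError("need equal-length, non-empty codon arrays")
    n = codons1.size
    S = float((SYN_SITES[codons1] + SYN_SITES[codons2]).sum() / 2.0)
    N = 3.0 * n - S
    Sd = float(SD_PAIR[codons1, codons2].sum())
    Nd = float(ND_PAIR[codons1, codons2].sum())
    if S == 0 and Sd > 0:
        raise ValueError("synonymous differences without synonymous sites")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return KsEstimate(S, N, Sd, Nd, pS, pN,
                      jukes_cantor(pS), jukes_cantor(pN), n)


def ng86_cds(cds1: str, cds2: str) -> KsEstimate:
    """Convenience: codon-align two CDS and run NG86 on the columns."""
    c1, c2 = codon_align(cds1, cds2)
    if c1.size == 0:
        raise ValueError("no aligned codon columns")
    return ng86(c1, c2)


def block_ks(block: SyntenyBlock, cds_by_gene: dict[str, str]) -> float | None:
    """Per-block Ks summary: median of defined anchor dS values.

    Returns ``None`` (and logs) when every anchor pair is saturated.
    Sets ``block.ks_summary`` as a side effect.
    """
    values = []
    for a in block.anchors:
        est = ng86_cds(cds_by_gene[a.gene_a], cds_by_gene[a.gene_b])
        if est.dS is not None:
            values.append(est.dS)
    if not values:
        log.warning("block %d: all anchor pairs saturated", block.block_id)
        block.ks_summary = None
        return None
    block.ks_summary = float(statistics.median(values))
    return block.ks_summary


@dataclass
class KsDistribution:
    values: list[float]
    mode: float
    bandwidth: float


def ks_mode(values, bandwidth: float | None = None) -> KsDistribution:
    """Modal Ks by Gaussian KDE on a 1000-point grid over [0, max].

    Bandwidth defaults to Silverman's rule; pass a float (as a fraction
    of the sample standard deviation, scipy's convention) to override.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size < 5:
        raise ValueError(f"need >= 5 finite Ks values, got {vals.size}")
    if np.ptp(vals) == 0:
        return KsDistribution(list(vals), float(vals[0]), 0.0)
    kde = gaussian_kde(vals, bw_method=bandwidth or "silverman")
    grid = np.linspace(0.0, float(vals.max()), 1000)
    dens = kde(grid)
    mode = float(grid[int(np.argmax(dens))])
    return KsDistribution(list(vals), mode, float(kde.factor))


def write_ks_table(rows, path) -> None:
    """Write per-pair NG86 results: gene_a, gene_b, S, N, Sd, Nd, dS, dN, block."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tS\tN\tSd\tNd\tdS\tdN\tblock_id\n")
        for gene_a, gene_b, est, block_id in rows:
            ds = "NA" if est.dS is None else f"{est.dS:.5f}"
            dn = "NA" if est.dN is None else f"{est.dN:.5f}"
            fh.write(f"{gene_a}\t{gene_b}\t{est.S:.2f}\t{est.N:.2f}"
                     f"\t{est.Sd:.2f}\t{est.Nd:.2f}\t{ds}\t{dn}\t{block_id}\n")
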