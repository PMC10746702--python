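"""Genetic-code tables and per-codon substitution accounting.

Everything downstream that touches codons — the Nei–Gojobori (1986)
synonymous/nonsynonymous estimator and the codon-wise divergence
simulator — works from the lookup tables built here at import time:

* ``SYN_SITES[c]``: expected synonymous sites of codon index ``c``
  (number of synonymous single-base neighbours at each position / 3,
  summed over the three positions).
* ``SD_PAIR[c1, c2]`` / ``ND_PAIR[c1, c2]``: synonymous / nonsynonymous
  difference counts for an ordered codon pair, averaged with equal
  weight over all shortest mutational paths, paths passing through a
  stop codon excluded (all-blocked pairs fall back to averaging over
  every path).
* ``SYN_NEIGHBORS`` / ``NONSYN_NEIGHBORS``: single-base neighbours of
  each sense codon that preserve / change the amino acid, stop codons
  excluded — the proposal sets of the divergence simulator.

The genetic code is the standard nuclear table (Biopython table 1).
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, '*' for stop
AA_OF = {c: _table.forward_table.get(c, "*") for c in CODONS}
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def _neighbors(codon: str):
    """Yield (position, neighbour codon) for all 9 single-base changes."""
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                yield pos, codon[:pos] + b + codon[pos + 1 :]


def _syn_sites(codon: str) -> float:
    if codon in STOP_CODONS:
        return 0.0
    syn = sum(1 for _, nb in _neighbors(codon) if AA_OF[nb] == AA_OF[codon])
    return syn / 3.0


def _path_diffs(c1: str, c2: str, exclude_stops: bool) -> list[tuple[int, int]]:
    """(syn, nonsyn) step counts for each admissible shortest path c1→c2."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    out = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if exclude_stops and nxt in STOP_CODONS and nxt != c2:
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            out.append((sd, nd))
    return out


def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    if c1 == c2:
        return 0.0, 0.0
    paths = _path_diffs(c1, c2, exclude_stops=True)
    if not paths:  # every ordering passes through a stop: average them all
        paths = _path_diffs(c1, c2, exclude_stops=False)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


SYN_SITES = np.array([_syn_sites(c) for c in CODONS])

SD_PAIR = np.zeros((64, 64))
ND_PAIR = np.zeros((64, 64))
for _i, _c1 in enumerate(CODONS):
    for _j, _c2 in enumerate(CODONS):
        SD_PAIR[_i, _j], ND_PAIR[_i, _j] = _pair_diffs(_c1, _c2)

SYN_NEIGHBORS: dict[int, list[int]] = {}
NONSYN_NEIGHBORS: dict[int, list[int]] = {}
for _c in SENSE_CODONS:
    _i = CODON_INDEX[_c]
    syn, non = [], []
    for _, _nb in _neighbors(_c):
        if _nb in STOP_CODONS:
            continue
        (syn if AA_OF[_nb] == AA_OF[_c] else non).append(CODON_INDEX[_nb])
    SYN_NEIGHBORS[_i] = sorted(syn)
    NONSYN_NEIGHBORS[_i] = sorted(non)


def codon_indices(cds: str) -> np.ndarray:
    """Encode an in-frame CDS (length divisible by 3) as codon indices."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    try:
        return np.array(
            [CODON_INDEX[cds[i : i + 3]] for i in range(0, len(cds), 3)],
            dtype=np.int64,
        )
    except KeyError as exc:
        raise ValueError(f"non-ACGT codon in CDS: {exc.args[0]!r}") from None


def indices_to_cds(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)


def translate(cds: str) -> str:
    """Translate an in-frame CDS; trims a terminal stop, rejects internal stops."""
    idx = codon_indices(cds)
    aas = [AA_OF[CODONS[i]] for i in idx]
    if aas and aas[-1] == "*":
        aas = aas[:-1]
    if "*" in aas:
        raise ValueError("internal stop codon in CDS")
    return "".join(aas)
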