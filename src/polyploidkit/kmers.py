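"""Canonical k-mer counting and k-mer-spectrum genome-size estimation.

k-mers are packed two bits per base into int64 codes (so k <= 31) and
counted in canonical form: the lexicographic minimum of the k-mer and
its reverse complement, which makes counting strand-free. Windows
containing N are skipped.

Genome size is estimated from the k-mer multiplicity histogram the
standard way: the first local minimum of the histogram separates the
sequencing-error peak from the main peak; the main peak's multiplicity
is the effective k-mer depth, and genome size = (k-mers above the
cutoff) / (peak depth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger("polyploidkit")

_CODE_OF = np.full(256, 4, dtype=np.uint8)  # 4 = N / anything else
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    return _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Forward-strand k-mer codes of every N-free window, in order."""
    if not (1 <= k <= 31):
        raise ValueError("k must be in 1..31")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    isn = codes > 3
    for j in range(k):
        acc += c[j : j + n] << (2 * (k - 1 - j))
        bad |= isn[j : j + n]
    return acc[~bad]


def revcomp_codes(kmer_codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(kmer_codes)
    for j in range(k):
        base = (kmer_codes >> (2 * j)) & 3
        rc |= (3 - base) << (2 * (k - 1 - j))
    return rc


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (min of strand pair) k-mer codes of one sequence."""
    fwd = encode_kmers(seq_to_codes(seq), k)
    if fwd.size == 0:
        return fwd
    return np.minimum(fwd, revcomp_codes(fwd, k))


@dataclass
class KmerHistogram:
    k: int
    counts: dict[int, int]  # multiplicity -> number of distinct k-mers
    total_kmers: int

    def __post_init__(self):
        assert self.total_kmers == sum(m * c for m, c in self.counts.items())


def kmer_histogram(reads, k: int) -> KmerHistogram:
    """Exact canonical k-mer multiplicity histogram over reads.

    ``reads`` is an iterable of sequences or (id, sequence) pairs;
    ``k`` must be odd (an even k can equal its own reverse complement,
    making the canonical form ambiguous).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd for unambiguous canonical k-mers")
    chunks: list[np.ndarray] = []
    buf: list[str] = []
    buf_len = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else seq_from(item)
        buf.append(seq)
        buf_len += len(seq)
        if buf_len >= 8_000_000:
            chunks.append(canonical_kmers("N".join(buf), k))
            buf, buf_len = [], 0
    if buf:
        chunks.append(canonical_kmers("N".join(buf), k))
    if not chunks:
        return KmerHistogram(k, {}, 0)
    allk = np.concatenate(chunks)
    _, mult = np.unique(allk, return_counts=True)
    hist = np.bincount(mult)
    counts = {int(m): int(c) for m, c in enumerate(hist) if m > 0 and c > 0}
    return KmerHistogram(k, counts, int(allk.size))


def seq_from(item):
    if isinstance(item, str):
        return item
    return item.residues  # GenomeSequence


def estimate_genome_size(hist: KmerHistogram) -> dict[str, float]:
    """Genome size from the k-mer spectrum's main peak.

    The error cutoff is the first local minimum of count vs
    multiplicity; if the spectrum rises from multiplicity 1 (no error
    peak, e.g. error-free reads) the cutoff is 0. Errors out when the
    spectrum is monotonically decreasing and no main peak exists.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    max_m = max(hist.counts)
    c = np.zeros(max_m + 2)
    for m, v in hist.counts.items():
        c[m] = v
    if c[1] <= c[2]:
        cutoff = 0
    else:
        cutoff = 0
        for m in range(2, max_m):
            if c[m] <= c[m - 1] and c[m] <= c[m + 1]:
                cutoff = m
                break
        if cutoff == 0:
            raise ValueError("cannot separate error peak: no local minimum")
    peak = int(np.argmax(c[cutoff + 1 :])) + cutoff + 1
    mass = sum(m * v for m, v in hist.counts.items() if m > cutoff)
    return {
        "error_cutoff": float(cutoff),
        "peak_depth": float(peak),
        "genome_size_bp": mass / peak,
    }


def write_histogram(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("multiplicity\tn_kmers\n")
        for m in sorted(hist.counts):
            fh.write(f"{m}\t{hist.counts[m]}\n")
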