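"""On-disk formats and shared domain records.

Coordinates are 1-based inclusive on disk (GFF/VCF convention) and
0-based half-open in memory; every conversion happens here, at the I/O
boundary. Minus-strand CDS are stored 5'->3' on the coding strand.

Sequence containers are deliberately thin dataclasses rather than
Biopython SeqRecords: the pipeline treats DNA as plain uppercase strings
over {A,C,G,T,N} and fails loudly on anything else.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("polyploidkit")

_VALID_DNA = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def setup_logging(level: str = "info") -> None:
    """Configure package logging to standard error."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq_id: str, residues: str) -> str:
    residues = residues.upper()
    bad = set(residues) - _VALID_DNA
    if bad:
        raise ValueError(
            f"sequence {seq_id!r} contains unsupported symbols: {sorted(bad)}"
        )
    return residues


@dataclass
class GenomeSequence:
    """A named DNA sequence (contig, chromosome or organelle genome)."""

    id: str
    residues: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        self.residues = _check_dna(self.id, self.residues)
        if not self.residues:
            raise ValueError(f"empty sequence: {self.id}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A located, stranded CDS: the unit of anchoring, Ks and family counts.

    ``start``/``end`` are 0-based half-open on the contig; ``cds`` is the
    coding-strand sequence (reverse-complemented for minus-strand genes),
    length divisible by 3. ``gene_rank`` is the 1-based ordinal of the
    gene along its contig in start order.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds: str
    gene_rank: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")


@dataclass
class VariantRecord:
    """A substitution call against a reference, with phred-scaled quality."""

    contig_id: str
    pos: int  # 0-based
    ref: str
    alt: str
    qual: float

    def __post_init__(self):
        if self.qual < 0:
            raise ValueError("negative quality")


@dataclass
class ContigDepthRecord:
    """Mean read depth over one contig for each read sample."""

    contig_id: str
    length: int
    depth_by_sample: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: non-positive length")
        for s, d in self.depth_by_sample.items():
            if d < 0:
                raise ValueError(f"{self.contig_id}/{s}: negative depth")


@dataclass
class FamilyCountRow:
    """Gene copy number of one family in each species."""

    family_id: str
    counts: dict[str, int]

    def __post_init__(self):
        if not any(v > 0 for v in self.counts.values()):
            raise ValueError(f"{self.family_id}: all counts zero")


@dataclass
class HomologyHit:
    """One row of 12-column tabular protein homology output."""

    query: str
    subject: str
    identity: float  # fraction in [0, 1]
    score: float


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[GenomeSequence]:
    """Read FASTA records; lowercase is uppercased, duplicate ids rejected."""
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    name, chunks = None, []

    def _flush():
        if name is None:
            return
        if name in seen:
            raise ValueError(f"duplicate id: {name}")
        seen.add(name)
        seqs.append(GenomeSequence(name, "".join(chunks)))

    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name, chunks = line[1:].split()[0], []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
        _flush()
    return seqs


def write_fasta(seqs, path, width: int = 80) -> None:
    with _open(path, "wt") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def write_fastq(reads, path, qual_char: str = "I") -> None:
    """Write (id, sequence) pairs as FASTQ with a constant quality."""
    with _open(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_fastq(path):
    """Yield (id, sequence) from a FASTQ file (qualities are ignored)."""
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip().upper()
            fh.readline()
            fh.readline()
            yield header[1:].strip().split()[0], seq


# ---------------------------------------------------------------------------
# GFF3 (CDS features only)


def read_gff_genes(path, seqs: list[GenomeSequence]) -> list[GeneModel]:
    """Read CDS features from a GFF3-style file.

    One CDS line per gene is assumed (the simulator writes genes that
    way); the feature's ID attribute names the gene. Genes whose CDS
    length is not a multiple of 3 are skipped with a warning; gene ranks
    are assigned by start order within each contig.
    """
    by_id = {s.id: s for s in seqs}
    genes: list[GeneModel] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            if contig not in by_id:
                raise ValueError(f"line {lineno}: unknown contig {contig!r}")
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            ref = by_id[contig]
            if start0 < 0 or end0 > len(ref):
                raise ValueError(
                    f"line {lineno}: {contig}:{start}-{end} outside contig"
                )
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID", f"{contig}:{start}-{end}")
            if (end0 - start0) % 3:
                log.warning("skipping %s: CDS length not divisible by 3", gene_id)
                continue
            cds = ref.residues[start0:end0]
            if strand == "-":
                cds = revcomp(cds)
            genes.append(GeneModel(gene_id, contig, start0, end0, strand, cds))
    _assign_ranks(genes)
    return genes


def write_gff_genes(genes: list[GeneModel], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            fh.write(
                f"{g.contig_id}\tpolyploidkit\tCDS\t{g.start + 1}\t{g.end}"
                f"\t.\t{g.strand}\t0\tID={g.gene_id}\n"
            )


def _assign_ranks(genes: list[GeneModel]) -> None:
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for members in by_contig.values():
        members.sort(key=lambda g: g.start)
        for rank, g in enumerate(members, 1):
            g.gene_rank = rank


# ---------------------------------------------------------------------------
# VCF-like TSV, depth tables, homology hits, generic maps


def read_variants(path) -> list[VariantRecord]:
    """Read a VCF-like TSV (CHROM, POS, REF, ALT, QUAL; POS 1-based)."""
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: expected 5 columns")
            chrom, pos, ref, alt, qual = fields[:5]
            out.append(VariantRecord(chrom, int(pos) - 1, ref, alt, float(qual)))
    return out


def write_variants(variants: list[VariantRecord], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\tQUAL\n")
        for v in variants:
            fh.write(f"{v.contig_id}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{v.qual:g}\n")


def read_depth_table(path) -> list[ContigDepthRecord]:
    """Read a depth TSV: contig_id, length, then one column per sample."""
    out = []
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ValueError("depth table needs contig, length and >=1 sample")
        samples = header[2:]
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"line {lineno}: expected {len(header)} columns"
                )
            out.append(
                ContigDepthRecord(
                    fields[0],
                    int(fields[1]),
                    {s: float(v) for s, v in zip(samples, fields[2:])},
                )
            )
    return out


def write_depth_table(records: list[ContigDepthRecord], path) -> None:
    samples = sorted({s for r in records for s in r.depth_by_sample})
    with _open(path, "wt") as fh:
        fh.write("contig_id\tlength\t" + "\t".join(samples) + "\n")
        for r in records:
            depths = "\t".join(f"{r.depth_by_sample[s]:.4f}" for s in samples)
            fh.write(f"{r.contig_id}\t{r.length}\t{depths}\n")


def read_homology_hits(path) -> list[HomologyHit]:
    """Read 12-column BLAST-tabular hits (identity given as a percentage)."""
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: expected 12 columns")
            if len(fields) > 12:
                log.warning("line %d: ignoring %d extra columns", lineno,
                            len(fields) - 12)
            out.append(
                HomologyHit(fields[0], fields[1], float(fields[2]) / 100.0,
                            float(fields[11]))
            )
    return out


def write_homology_hits(hits: list[HomologyHit], path) -> None:
    with _open(path, "wt") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{100 * h.identity:.2f}"
                + "\t0" * 8
                + f"\t{h.score:.1f}\n"
            )


def read_tsv_map(path, ncols: int = 2) -> dict[str, str]:
    """Read a two-column TSV into a dict (e.g. gene->family, family->pathway)."""
    out: dict[str, str] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ValueError(f"line {lineno}: expected {ncols} columns")
            out[fields[0]] = fields[1]
    return out


def write_tsv_map(mapping: dict[str, str], path, header: tuple[str, str] | None = None) -> None:
    with _open(path, "wt") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# Assembly statistics


def assembly_stats(lengths) -> dict[str, int]:
    """N50/N90-style contiguity statistics.

    Nx is the smallest contig length L such that contigs of length >= L
    jointly cover at least x% of the assembly; Lx is how many contigs
    that takes.
    """
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        raise ValueError("empty length list")
    if lengths[0] <= 0:
        raise ValueError("non-positive contig length")
    lengths = lengths[::-1]
    total = sum(lengths)
    out = {"n_contigs": len(lengths), "total_bp": total}
    cum = np.cumsum(lengths)
    for x in (50, 90):
        idx = int(np.searchsorted(cum, total * x / 100.0))
        out[f"N{x}"] = lengths[idx]
        out[f"L{x}"] = idx + 1
    return out


def n90_contigs(seqs: list[GenomeSequence]) -> list[GenomeSequence]:
    """Contigs at least as long as the assembly's N90 value."""
    n90 = assembly_stats([len(s) for s in seqs])["N90"]
    return [s for s in seqs if len(s) >= n90]


__all__ = [
    "GenomeSequence", "GeneModel", "VariantRecord", "ContigDepthRecord",
    "FamilyCountRow", "HomologyHit", "read_fasta", "write_fasta",
    "read_fastq", "write_fastq", "read_gff_genes", "write_gff_genes",
    "read_variants", "write_variants", "read_depth_table",
    "write_depth_table", "read_homology_hits", "write_homology_hits",
    "read_tsv_map", "write_tsv_map", "assembly_stats", "n90_contigs",
    "revcomp", "setup_logging",
]
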