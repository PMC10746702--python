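"""Assigning tetraploid sequence to its progenitor subgenomes.

Two independent routes are implemented and reconciled:

* **Ks partition** — homoeologous (self-synteny) block pairs are split
  by their synonymous divergence to progenitor A: in each duplicate
  pair, the copy with the strictly lower median dS to its progenitor-A
  orthologs descends from the A donor; the other copy is the B
  subgenome.
* **Depth of coverage (DOC)** — reads from each progenitor are assigned
  to tetraploid contigs by best shared canonical k-mer count; a contig
  whose depth from one progenitor's reads falls under the threshold
  (default 16x, strict <) while the other progenitor's reads cover it
  well must derive from the other progenitor.

The DOC summary table mirrors the shape of a per-condition report:
contig count, total size, and the mean (SD) depth of the *other*
species' reads for each mapped condition.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np

from .io import ContigDepthRecord, GenomeSequence, assembly_stats
from .kmers import canonical_kmers
from .synteny import SyntenyBlock

log = logging.getLogger("polyploidkit")


@dataclass
class SubgenomeLabel:
    unit_id: str
    label: str  # "A", "B" or "unassigned"
    evidence: str  # "ks", "doc" or "both"
    contig_id: str = ""
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Route 1: Ks partition of homoeologous block pairs


def partition_ab(
    self_blocks: list[SyntenyBlock],
    ks_to_refA: dict[str, float],
) -> list[SubgenomeLabel]:
    """Label the two copies of each self-synteny block pair A or B.

    ``ks_to_refA`` maps tetraploid genes to their NG86 dS against the
    progenitor-A ortholog. Per block pair, each copy's median dS over
    genes with orthologs is compared; the strictly lower median is the
    A copy. Copies with no ortholog information, or with equal medians,
    are both left unassigned (and logged).
    """
    labels = []
    for b in self_blocks:
        ks_a = [ks_to_refA[g] for g in b.genes_a() if g in ks_to_refA]
        ks_b = [ks_to_refA[g] for g in b.genes_b() if g in ks_to_refA]
        id_a, id_b = f"block{b.block_id}/1", f"block{b.block_id}/2"
        detail_a = {"median_ks_to_A": _med(ks_a), "n_orthologs": len(ks_a)}
        detail_b = {"median_ks_to_A": _med(ks_b), "n_orthologs": len(ks_b)}
        if not ks_a or not ks_b or _med(ks_a) == _med(ks_b):
            log.warning("block %d: cannot partition (missing orthologs or tie)",
                        b.block_id)
            lab_a = lab_b = "unassigned"
        elif _med(ks_a) < _med(ks_b):
            lab_a, lab_b = "A", "B"
        else:
            lab_a, lab_b = "B", "A"
        labels.append(SubgenomeLabel(id_a, lab_a, "ks", b.contig_a, detail_a))
        labels.append(SubgenomeLabel(id_b, lab_b, "ks", b.contig_b, detail_b))
    return labels


def _med(vals):
    return float(statistics.median(vals)) if vals else None


# ---------------------------------------------------------------------------
# Route 2: depth of coverage from k-mer read assignment


def assign_reads_by_kmer(
    reads,
    contigs: list[GenomeSequence],
    k: int = 31,
) -> list[ContigDepthRecord]:
    """Per-contig mean depth from best-shared-k-mer read assignment.

    Each read goes to the contig sharing the greatest number of
    canonical k-mers with it; ties and reads sharing none are counted
    as unassigned. This is a defined, exact assigner for simulator-made
    data, not a general-purpose mapper. Depth = assigned bases / contig
    length; the sample name is taken from ``reads`` when it is a
    (sample_name, read list) tuple, else "sample".
    """
    if isinstance(reads, tuple) and len(reads) == 2 and isinstance(reads[0], str):
        sample, read_list = reads
    else:
        sample, read_list = "sample", reads

    codes, owner = [], []
    for ci, contig in enumerate(contigs):
        km = np.unique(canonical_kmers(contig.residues, k))
        codes.append(km)
        owner.append(np.full(km.size, ci, dtype=np.int32))
    codes = np.concatenate(codes)
    owner = np.concatenate(owner)
    order = np.argsort(codes, kind="stable")
    codes, owner = codes[order], owner[order]

    n_contigs = len(contigs)
    assigned_bases = np.zeros(n_contigs, dtype=np.int64)
    n_unassigned = 0
    n_reads = 0

    chunk_reads: list[str] = []

    def _flush(chunk: list[str]):
        nonlocal n_unassigned
        if not chunk:
            return
        per_read = []
        kmer_list = []
        for seq in chunk:
            km = canonical_kmers(seq, k)
            per_read.append(km.size)
            kmer_list.append(km)
        allk = np.concatenate(kmer_list) if kmer_list else np.empty(0, np.int64)
        read_idx = np.repeat(np.arange(len(chunk)), per_read)
        lo = np.searchsorted(codes, allk, side="left")
        hi = np.searchsorted(codes, allk, side="right")
        nmatch = hi - lo
        has = nmatch > 0
        # expand matches into (read, contig) pairs without a Python loop
        counts = nmatch[has]
        starts = lo[has]
        exp_read = np.repeat(read_idx[has], counts)
        offs = np.repeat(np.cumsum(counts) - counts, counts)
        ranges = np.arange(int(counts.sum())) - offs + np.repeat(starts, counts)
        exp_contig = owner[ranges]
        key = exp_read * n_contigs + exp_contig
        table = np.bincount(key, minlength=len(chunk) * n_contigs).reshape(
            len(chunk), n_contigs
        )
        best = table.max(axis=1)
        winners = table.argmax(axis=1)
        tied = (table == best[:, None]).sum(axis=1) > 1
        ok = (best > 0) & ~tied
        lens = np.array([len(s) for s in chunk])
        np.add.at(assigned_bases, winners[ok], lens[ok])
        n_unassigned += int((~ok).sum())

    for item in read_list:
        seq = item[1] if isinstance(item, tuple) else item
        chunk_reads.append(seq)
        n_reads += 1
        if len(chunk_reads) >= 20_000:
            _flush(chunk_reads)
            chunk_reads = []
    _flush(chunk_reads)

    if n_reads:
        log.info("%s: %d/%d reads unassigned (%.2f%%)", sample, n_unassigned,
                 n_reads, 100.0 * n_unassigned / n_reads)
    return [
        ContigDepthRecord(
            c.id, len(c), {sample: float(assigned_bases[i]) / len(c)}
        )
        for i, c in enumerate(contigs)
    ]


def merge_depths(*record_lists) -> list[ContigDepthRecord]:
    """Combine per-sample depth records into one record per contig."""
    merged: dict[str, ContigDepthRecord] = {}
    for records in record_lists:
        for r in records:
            if r.contig_id not in merged:
                merged[r.contig_id] = ContigDepthRecord(r.contig_id, r.length, {})
            merged[r.contig_id].depth_by_sample.update(r.depth_by_sample)
    return list(merged.values())


@dataclass
class DocSummaryRow:
    condition: str
    contig_number: int
    total_size: int
    other_sample: str
    mean_depth: float | None
    sd_depth: float | None


def classify_contigs_doc(
    depths: list[ContigDepthRecord],
    sampleA: str,
    sampleB: str,
    threshold: float = 16.0,
    n90_filter: bool = True,
) -> tuple[list[SubgenomeLabel], list[DocSummaryRow]]:
    """Classify contigs by which progenitor's reads fail to cover them.

    DOC under ``threshold`` (strict <) for sample A's reads while sample
    B covers the contig marks a B-origin contig, and symmetrically;
    contigs under the threshold for both samples are unassigned-both,
    contigs covered by both are unassigned-ambiguous. With
    ``n90_filter`` only contigs of length >= the N90 of the input set
    are classified.
    """
    for r in depths:
        for s in (sampleA, sampleB):
            if s not in r.depth_by_sample:
                raise ValueError(f"{r.contig_id}: missing depth for {s!r}")
    pool = depths
    if n90_filter and depths:
        n90 = assembly_stats([r.length for r in depths])["N90"]
        pool = [r for r in depths if r.length >= n90]

    groups: dict[str, list[ContigDepthRecord]] = {
        "A": [], "B": [], "unassigned-both": [], "unassigned-ambiguous": []
    }
    labels = []
    for r in pool:
        da, db = r.depth_by_sample[sampleA], r.depth_by_sample[sampleB]
        if da < threshold and db >= threshold:
            lab = "B"          # progenitor-A reads fail to map
        elif db < threshold and da >= threshold:
            lab = "A"
        elif da < threshold and db < threshold:
            lab = "unassigned-both"
        else:
            lab = "unassigned-ambiguous"
        groups[lab].append(r)
        labels.append(
            SubgenomeLabel(r.contig_id,
                           lab if lab in ("A", "B") else "unassigned",
                           "doc", r.contig_id,
                           {sampleA: da, sampleB: db, "condition": lab})
        )

    def _row(condition, members, other):
        vals = [m.depth_by_sample[other] for m in members]
        return DocSummaryRow(
            condition, len(members), sum(m.length for m in members), other,
            float(np.mean(vals)) if vals else None,
            float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
        )

    summary = [
        _row(f"DOC under {threshold:g}x for {sampleA} reads", groups["B"], sampleB),
        _row(f"DOC under {threshold:g}x for {sampleB} reads", groups["A"], sampleA),
        _row(f"DOC under {threshold:g}x for both samples' reads",
             groups["unassigned-both"], sampleB),
        _row("DOC at or above threshold for both samples",
             groups["unassigned-ambiguous"], sampleB),
    ]
    return labels, summary


# ---------------------------------------------------------------------------
# Reconciliation


@dataclass
class ReconcileReport:
    agreement: float | None  # None when nothing was comparable
    n_compared: int
    disagreements: list[tuple[str, str, str]]
    self_contained: list[str]


def reconcile(
    ks_labels: list[SubgenomeLabel],
    doc_labels: list[SubgenomeLabel],
) -> ReconcileReport:
    """Agreement between the Ks and DOC routes on shared contigs.

    Each Ks-labelled block copy is mapped to its contig; block pairs
    whose two copies share one contig (an internal duplication) are
    flagged self-contained and excluded from the comparison.
    """
    doc_by_contig = {l.contig_id: l.label for l in doc_labels}
    by_block: dict[str, list[SubgenomeLabel]] = {}
    for l in ks_labels:
        by_block.setdefault(l.unit_id.split("/")[0], []).append(l)
    self_contained = sorted(
        b for b, ls in by_block.items()
        if len({l.contig_id for l in ls}) == 1
    )
    skip = set(self_contained)
    agree = n = 0
    disagreements = []
    for l in ks_labels:
        if l.unit_id.split("/")[0] in skip:
            continue
        if l.label == "unassigned":
            continue
        doc = doc_by_contig.get(l.contig_id)
        if doc not in ("A", "B"):
            continue
        n += 1
        if doc == l.label:
            agree += 1
        else:
            disagreements.append((l.unit_id, l.label, doc))
    return ReconcileReport(agree / n if n else None, n,
                           disagreements, self_contained)


def write_labels(labels: list[SubgenomeLabel], path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\tcontig_id\tlabel\tevidence\tdetail\n")
        for l in labels:
            detail = ";".join(f"{k}={v}" for k, v in l.detail.items())
            fh.write(f"{l.unit_id}\t{l.contig_id}\t{l.label}\t{l.evidence}\t{detail}\n")


def write_doc_summary(rows: list[DocSummaryRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("condition\tcontig_number\ttotal_size\tother_sample"
                 "\tmean_depth\tsd_depth\n")
        for r in rows:
            mean = "NA" if r.mean_depth is None else f"{r.mean_depth:.1f}"
            sd = "NA" if r.sd_depth is None else f"{r.sd_depth:.1f}"
            fh.write(f"{r.condition}\t{r.contig_number}\t{r.total_size}"
                     f"\t{r.other_sample}\t{mean}\t{sd}\n")
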