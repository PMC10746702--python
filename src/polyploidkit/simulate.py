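"""Truth-labelled synthetic allotetraploid system.

The generator realises the statistical structure the downstream
analyses assume about a young allotetraploid and its two diploid
progenitors:

* an ancestor genome with regularly spaced, translatable genes;
* progenitor A keeps the ancestral sequence while progenitor B diverges
  codon-wise so that the measured pairwise NG86 dS equals the target
  (default 0.05, the scale of recent Vigna-like speciation events) — a
  calibration loop against the package's own NG86 estimator tunes the
  per-codon event rate;
* an allotetraploid formed as the union of both progenitor genomes,
  each copy independently re-diverged by a small additional dS
  (default 0.01) and optionally fractionated (gene annotations lost
  independently at a configurable rate; the DNA stays in place, i.e.
  pseudogenization-style loss);
* uniform single-end short reads with per-base substitution errors;
* gene-family copy-number tables with a known amplified subset; and
* a plastome-like reference with variant-called accessions evolved on a
  known tree, for the consensus/diversity/phylogeny stages.

Every operation is bit-reproducible for a fixed seed, and every piece
of ground truth is recorded in a :class:`TruthTable` that can round-trip
through plain TSV files so that recovery tests consume only files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skbio import TreeNode

from ._codons import (
    CODON_INDEX,
    NONSYN_NEIGHBORS,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_NEIGHBORS,
    SYN_SITES,
    codon_indices,
    indices_to_cds,
)
from .consensus import CoverageMask
from .io import (
    FamilyCountRow,
    GeneModel,
    GenomeSequence,
    VariantRecord,
    revcomp,
)
from .ks import ng86

log = logging.getLogger("polyploidkit")

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def dna_to_codes(seq: str) -> np.ndarray:
    codes = _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return codes


def codes_to_dna(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode()


@dataclass
class SimulationConfig:
    """Knobs of the synthetic system; defaults are the desk-scale preset
    (20 contigs x 50 kb per progenitor, 10 genes of 900 bp per contig,
    progenitor divergence dS 0.05, 40x reads at 0.5% error)."""

    seed: int = 0
    n_contigs: int = 20
    contig_length: int = 50_000
    genes_per_contig: int = 10
    cds_length: int = 900
    target_dS: float = 0.05
    target_dN: float = 0.01
    extra_dS: float = 0.01
    fractionation_rate: float = 0.05
    read_length: int = 100
    coverage: float = 40.0
    error_rate: float = 0.005
    n_families: int = 1000
    n_amplified: int = 100

    def __post_init__(self):
        if self.cds_length % 3:
            raise ValueError("cds_length must be a multiple of 3")
        if not (0 <= self.fractionation_rate < 1):
            raise ValueError("fractionation_rate must be in [0, 1)")
        if self.target_dS < 0 or self.target_dN < 0:
            raise ValueError("divergence targets must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class TruthTable:
    """Machine-checkable ground truth of one simulated system."""

    contig_origin: dict[str, str] = field(default_factory=dict)
    gene_family: dict[str, str] = field(default_factory=dict)
    amplified_families: set[str] = field(default_factory=set)
    ortholog_pairs: dict[str, str] = field(default_factory=dict)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# Ancestor

_SENSE_NONSTOP = np.array(
    [CODON_INDEX[c] for c in SENSE_CODONS if c != "ATG"], dtype=np.int64
)
_STOP_IDX = np.array(sorted(CODON_INDEX[c] for c in STOP_CODONS), dtype=np.int64)


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """ATG + random non-stop codons + one stop codon, as codon indices."""
    body = rng.choice(_SENSE_NONSTOP, size=max(n_codons - 2, 0))
    stop = rng.choice(_STOP_IDX, size=1)
    return np.concatenate([[CODON_INDEX["ATG"]], body, stop])


def simulate_ancestor(
    config: SimulationConfig, rng=None
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Ancestral genome: uniform DNA with regularly spaced genes."""
    rng = _rng(config.seed if rng is None else rng)
    slot = config.contig_length // config.genes_per_contig
    if config.cds_length > slot:
        raise ValueError(
            "genes do not fit: genes_per_contig x cds_length exceeds contig_length"
        )
    seqs, genes = [], []
    for c in range(config.n_contigs):
        contig_id = f"ctg{c + 1:03d}"
        codes = rng.integers(0, 4, size=config.contig_length, dtype=np.uint8)
        for g in range(config.genes_per_contig):
            start = g * slot + (slot - config.cds_length) // 2
            end = start + config.cds_length
            cds = indices_to_cds(_random_cds(config.cds_length // 3, rng))
            strand = "+" if rng.random() < 0.5 else "-"
            placed = cds if strand == "+" else revcomp(cds)
            codes[start:end] = dna_to_codes(placed)
            genes.append(
                GeneModel(f"{contig_id}_g{g + 1}", contig_id, start, end,
                          strand, cds, gene_rank=g + 1)
            )
        seqs.append(GenomeSequence(contig_id, codes_to_dna(codes)))
    return seqs, genes


# ---------------------------------------------------------------------------
# Divergence


def _mutate_codons(
    codons: np.ndarray,
    lam_s: float,
    lam_n: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply Poisson(lam) synonymous then nonsynonymous events per codon,
    each event a uniform draw among the admissible single-base neighbours."""
    out = codons.copy()
    for lam, neighbors in ((lam_s, SYN_NEIGHBORS), (lam_n, NONSYN_NEIGHBORS)):
        if lam <= 0:
            continue
        n_events = rng.poisson(lam, size=out.size)
        for i in np.flatnonzero(n_events):
            cur = int(out[i])
            for _ in range(int(n_events[i])):
                opts = neighbors.get(cur)
                if not opts:
                    break
                cur = opts[int(rng.integers(len(opts)))]
            out[i] = cur
    return out


def diverge(
    seqs: list[GenomeSequence],
    genes: list[GeneModel],
    target_dS: float,
    target_dN: float,
    seed,
    max_rounds: int = 10,
    rel_tol: float = 0.10,
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Mutate one lineage so the pairwise NG86 dS/dN against the input
    genome hits the targets.

    The full pairwise target is applied to this single lineage (the
    other lineage keeps the ancestor), so one knob equals the measured
    quantity. Codon substitution is unbiased among single-base
    synonymous (resp. nonsynonymous) neighbours, the model under which
    NG86 counting is exact; the per-codon event rates are calibrated in
    a propose/measure/adjust loop against :func:`polyploidkit.ks.ng86`.
    Intergenic DNA is mutated at ``target_dS`` per site.
    """
    ss = _seedseq(seed)
    coding = [codon_indices(g.cds)[:-1] for g in genes]  # keep stops fixed
    concat = np.concatenate(coding) if coding else np.empty(0, dtype=np.int64)

    if (target_dS == 0 and target_dN == 0) or concat.size == 0:
        mutated = concat
    else:
        sbar = float(SYN_SITES[concat].mean()) if concat.size else 1.0
        lam_s = target_dS * sbar
        lam_n = target_dN * (3.0 - sbar)
        mutated = None
        for round_ss in ss.spawn(max_rounds):
            rng = np.random.default_rng(round_ss)
            cand = _mutate_codons(concat, lam_s, lam_n, rng)
            est = ng86(concat, cand)
            ok = True

            def _accept(value, target, n_diff):
                # counting noise dominates on short CDS: widen the band to
                # three relative standard errors of the difference count
                band = max(rel_tol / 2, 3.0 / np.sqrt(max(n_diff, 1.0)))
                return abs(value - target) <= band * target

            if target_dS > 0:
                if est.dS is None:
                    ok = False
                    lam_s *= 0.5
                else:
                    ok &= _accept(est.dS, target_dS, est.Sd)
                    lam_s *= target_dS / max(est.dS, 1e-9)
            if target_dN > 0:
                if est.dN is None:
                    ok = False
                    lam_n *= 0.5
                else:
                    ok &= _accept(est.dN, target_dN, est.Nd)
                    lam_n *= target_dN / max(est.dN, 1e-9)
            if ok:
                mutated = cand
                break
        if mutated is None:
            raise RuntimeError(
                f"divergence calibration failed after {max_rounds} rounds "
                f"(target dS={target_dS}, dN={target_dN})"
            )

    # rebuild gene CDS
    new_genes = []
    offset = 0
    for g, cod in zip(genes, coding):
        stop = g.cds[-3:]
        new_cds = indices_to_cds(mutated[offset : offset + cod.size]) + stop
        offset += cod.size
        new_genes.append(replace(g, cds=new_cds))

    # intergenic mutation + splice mutated CDS back into contigs
    rng_ig = np.random.default_rng(ss.spawn(1)[0])
    by_contig: dict[str, list[GeneModel]] = {}
    for g in new_genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    new_seqs = []
    for s in seqs:
        codes = dna_to_codes(s.residues)
        genic = np.zeros(codes.size, dtype=bool)
        for g in by_contig.get(s.id, []):
            genic[g.start : g.end] = True
        if target_dS > 0:
            hit = (rng_ig.random(codes.size) < target_dS) & ~genic
            codes[hit] = (codes[hit] + rng_ig.integers(1, 4, size=int(hit.sum()),
                                                       dtype=np.uint8)) % 4
        for g in by_contig.get(s.id, []):
            placed = g.cds if g.strand == "+" else revcomp(g.cds)
            codes[g.start : g.end] = dna_to_codes(placed)
        new_seqs.append(GenomeSequence(s.id, codes_to_dna(codes)))
    return new_seqs, new_genes


def relabel(
    seqs: list[GenomeSequence],
    genes: list[GeneModel],
    prefix: str,
) -> tuple[list[GenomeSequence], list[GeneModel], dict[str, str]]:
    """Prefix contig and gene ids; returns the old->new gene id map."""
    new_seqs = [GenomeSequence(f"{prefix}_{s.id}", s.residues, s.topology)
                for s in seqs]
    gene_map = {g.gene_id: f"{prefix}_{g.gene_id}" for g in genes}
    new_genes = [
        replace(g, gene_id=gene_map[g.gene_id], contig_id=f"{prefix}_{g.contig_id}")
        for g in genes
    ]
    return new_seqs, new_genes, gene_map


# ---------------------------------------------------------------------------
# Allotetraploid


def build_allotetraploid(
    progA: tuple[list[GenomeSequence], list[GeneModel]],
    progB: tuple[list[GenomeSequence], list[GeneModel]],
    fractionation_rate: float,
    seed,
    extra_dS: float = 0.01,
) -> tuple[list[GenomeSequence], list[GeneModel], TruthTable]:
    """Union of both progenitor genomes with re-divergence and fractionation.

    Each subgenome copy is independently re-diverged by ``extra_dS``
    (synonymous only) relative to its progenitor, tetraploid contigs get
    neutral shuffled ids, and gene annotations are lost independently at
    ``fractionation_rate``. The returned :class:`TruthTable` records the
    origin of every tetraploid contig and every progenitor->tetraploid
    ortholog pair (for surviving copies).
    """
    if {s.id for s in progA[0]} & {s.id for s in progB[0]}:
        raise ValueError("progenitor contig ids must be disjoint (relabel first)")
    ss = _seedseq(seed)
    ss_a, ss_b, ss_misc = ss.spawn(3)
    truth = TruthTable()
    copies = []
    for (seqs, genes), origin, sub_ss in ((progA, "A", ss_a), (progB, "B", ss_b)):
        dseqs, dgenes = diverge(seqs, genes, extra_dS, 0.0, sub_ss)
        copies.append((dseqs, dgenes, origin, {g.gene_id: g.gene_id for g in genes}))

    rng = np.random.default_rng(ss_misc)
    all_contigs = [(s, origin, members)
                   for dseqs, dgenes, origin, _ in copies
                   for s, members in _group_by_contig(dseqs, dgenes)]
    order = rng.permutation(len(all_contigs))

    tet_seqs, tet_genes = [], []
    for new_idx, old_idx in enumerate(order):
        s, origin, members = all_contigs[old_idx]
        tet_id = f"vr_tig{new_idx + 1:03d}"
        truth.contig_origin[tet_id] = origin
        tet_seqs.append(GenomeSequence(tet_id, s.residues))
        keep = rng.random(len(members)) >= fractionation_rate
        rank = 0
        for g, k in zip(sorted(members, key=lambda g: g.start), keep):
            if not k:
                log.debug("fractionation: dropped %s", g.gene_id)
                continue
            rank += 1
            new_gid = f"{tet_id}_g{rank}"
            tet_genes.append(
                replace(g, gene_id=new_gid, contig_id=tet_id, gene_rank=rank)
            )
            truth.ortholog_pairs[g.gene_id] = new_gid
    return tet_seqs, tet_genes, truth


def _group_by_contig(seqs, genes):
    by = {s.id: [] for s in seqs}
    for g in genes:
        by[g.contig_id].append(g)
    return [(s, by[s.id]) for s in seqs]


def ancestral_families(
    genes: list[GeneModel], gene_maps: list[dict[str, str]]
) -> dict[str, str]:
    """Family id per descendant gene: one family per ancestral gene.

    ``gene_maps`` are ancestor->descendant id maps (from :func:`relabel`
    and the truth table's ortholog pairs), chained as needed.
    """
    fam: dict[str, str] = {}
    for g in genes:
        fam[g.gene_id] = f"fam_{g.gene_id}"
    for m in gene_maps:
        for src, dst in m.items():
            if src in fam:
                fam[dst] = fam[src]
    return fam


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(
    seqs: list[GenomeSequence],
    coverage: float,
    read_length: int,
    error_rate: float,
    seed,
    id_prefix: str = "r",
) -> list[tuple[str, str]]:
    """Uniform single-end reads with per-base substitution errors.

    The read count is ``round(coverage * genome_bp / read_length)``;
    start positions are uniform within contigs (length-weighted across
    contigs) and the strand is drawn uniformly.
    """
    rng = _rng(seed)
    lengths = np.array([len(s) for s in seqs])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest contig")
    total = int(lengths.sum())
    n_reads = int(round(coverage * total / read_length))
    starts_per = lengths - read_length + 1
    probs = starts_per / starts_per.sum()
    contig_idx = rng.choice(len(seqs), size=n_reads, p=probs)
    starts = (rng.random(n_reads) * starts_per[contig_idx]).astype(np.int64)

    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    genome = np.concatenate([dna_to_codes(s.residues) for s in seqs])
    abs_starts = offsets[contig_idx] + starts
    flip = rng.random(n_reads) < 0.5

    out: list[tuple[str, str]] = []
    chunk = 100_000
    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        idx = abs_starts[lo:hi, None] + np.arange(read_length)
        reads = genome[idx]
        f = flip[lo:hi]
        reads[f] = 3 - reads[f][:, ::-1]
        if error_rate > 0:
            err = rng.random(reads.shape) < error_rate
            reads[err] = (reads[err] + rng.integers(1, 4, size=int(err.sum()),
                                                    dtype=np.uint8)) % 4
        blob = _LETTERS[reads].tobytes()
        out.extend(
            (f"{id_prefix}{lo + i:07d}",
             blob[i * read_length : (i + 1) * read_length].decode())
            for i in range(hi - lo)
        )
    return out


# ---------------------------------------------------------------------------
# Gene-family count tables

TETRAPLOID = "reflexopilosa"
DIPLOID_A = "trinervia"
DIPLOID_B = "hirtella"


def simulate_family_counts(
    n_families: int,
    n_amplified: int,
    seed,
) -> tuple[list[FamilyCountRow], set[str]]:
    """Copy-number table with a known amplified subset.

    Background families draw each diploid count from {1,2,3}; the
    tetraploid count is the diploid sum, fractionated (minus one) with
    probability 1/2 — and always fractionated when the two diploid
    counts are equal, which keeps background rows strictly outside the
    twofold-amplification rule so truth recovery is exact. Amplified
    families get a tetraploid count of at least twice each diploid count.
    """
    if n_amplified > n_families:
        raise ValueError("n_amplified exceeds n_families")
    rng = _rng(seed)
    rows, amplified = [], set()
    amp_idx = set(rng.choice(n_families, size=n_amplified, replace=False).tolist())
    for i in range(n_families):
        fam = f"cfam{i + 1:05d}"
        d1, d2 = rng.integers(1, 4), rng.integers(1, 4)
        if i in amp_idx:
            tet = 2 * max(d1, d2) + int(rng.integers(0, 3))
            amplified.add(fam)
        else:
            frac = 1 if d1 == d2 else int(rng.random() < 0.5)
            tet = int(d1 + d2 - frac)
        rows.append(
            FamilyCountRow(fam, {TETRAPLOID: int(tet), DIPLOID_A: int(d1),
                                 DIPLOID_B: int(d2)})
        )
    return rows, amplified


# ---------------------------------------------------------------------------
# Plastome accessions (consensus / diversity / phylogeny stage)


@dataclass
class PlastomeSim:
    reference: GenomeSequence
    genes: list[GeneModel]
    variants: dict[str, list[VariantRecord]]
    masks: list[CoverageMask]
    true_tree: TreeNode
    accession_seqs: dict[str, str]


def _random_tree(labels: list[str], rng, bl_range=(0.002, 0.01)) -> TreeNode:
    nodes = [TreeNode(name=l) for l in labels]
    for n in nodes:
        n.length = float(rng.uniform(*bl_range))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(*bl_range))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return root


def _evolve(codes: np.ndarray, p: float, rng) -> np.ndarray:
    out = codes.copy()
    hit = rng.random(out.size) < p
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()),
                                        dtype=np.uint8)) % 4
    return out


def simulate_plastome_accessions(
    seed,
    n_accessions: int = 23,
    ref_length: int = 30_000,
    n_genes: int = 40,
    gene_length: int = 600,
    noise_variant_rate: float = 5e-4,
    dropout_genes: int = 2,
) -> PlastomeSim:
    """Reference plastome plus variant-called accessions on a known tree.

    Accession sequences evolve by per-site substitution along a random
    binary tree; each accession's variants against the reference carry
    high phred qualities, spiked with spurious low-quality (< 30) calls
    that the consensus step must reject. One accession loses RNA-seq
    coverage over ``dropout_genes`` genes, exercising the
    comprehensive-coverage filter.
    """
    rng = np.random.default_rng(_seedseq(seed))
    config = SimulationConfig(
        n_contigs=1, contig_length=ref_length, genes_per_contig=n_genes,
        cds_length=gene_length,
    )
    seqs, genes = simulate_ancestor(config, rng)
    ref = GenomeSequence("plastid_ref", seqs[0].residues)
    genes = [replace(g, contig_id=ref.id) for g in genes]
    labels = [f"acc{i + 1:02d}" for i in range(n_accessions)]
    tree = _random_tree(labels, rng)

    ref_codes = dna_to_codes(ref.residues)
    acc_codes: dict[str, np.ndarray] = {}

    def _descend(node, codes):
        for child in node.children:
            ccodes = _evolve(codes, child.length or 0.0, rng)
            if child.is_tip():
                acc_codes[child.name] = ccodes
            else:
                _descend(child, ccodes)

    _descend(tree, ref_codes)

    variants: dict[str, list[VariantRecord]] = {}
    letters = "ACGT"
    for label in labels:
        codes = acc_codes[label]
        recs = []
        for pos in np.flatnonzero(codes != ref_codes):
            recs.append(
                VariantRecord(ref.id, int(pos), letters[ref_codes[pos]],
                              letters[codes[pos]], float(rng.uniform(35, 60)))
            )
        # spurious low-quality calls: must be ignored by the consensus rule
        n_noise = rng.poisson(noise_variant_rate * ref_codes.size)
        for pos in rng.integers(0, ref_codes.size, size=n_noise):
            alt = letters[(ref_codes[pos] + rng.integers(1, 4)) % 4]
            recs.append(
                VariantRecord(ref.id, int(pos), letters[ref_codes[pos]], alt,
                              float(rng.uniform(2, 29.99)))
            )
        recs.sort(key=lambda v: v.pos)
        variants[label] = recs

    dropped = rng.choice(len(genes), size=dropout_genes, replace=False)
    masks = []
    for label in labels:
        intervals = [(0, len(ref))]
        if label == labels[0] and dropout_genes:
            intervals = _punch_holes(len(ref), [genes[i] for i in dropped])
        masks.append(CoverageMask(label, ref.id, intervals))

    acc_seqs = {l: codes_to_dna(c) for l, c in acc_codes.items()}
    return PlastomeSim(ref, genes, variants, masks, tree, acc_seqs)


def _punch_holes(length: int, genes: list[GeneModel]) -> list[tuple[int, int]]:
    holes = sorted((g.start, g.end) for g in genes)
    intervals, cur = [], 0
    for s, e in holes:
        if s > cur:
            intervals.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        intervals.append((cur, length))
    return intervals


# ---------------------------------------------------------------------------
# Truth table I/O (plain TSV, so downstream tests consume only files)


def write_truth(truth: TruthTable, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "contig_origin.tsv", "w") as fh:
        fh.write("contig_id\torigin\n")
        for k in sorted(truth.contig_origin):
            fh.write(f"{k}\t{truth.contig_origin[k]}\n")
    with open(outdir / "gene_family.tsv", "w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for k in sorted(truth.gene_family):
            fh.write(f"{k}\t{truth.gene_family[k]}\n")
    with open(outdir / "amplified_families.tsv", "w") as fh:
        fh.write("family_id\n")
        for k in sorted(truth.amplified_families):
            fh.write(f"{k}\n")
    with open(outdir / "ortholog_pairs.tsv", "w") as fh:
        fh.write("progenitor_gene\ttetraploid_gene\n")
        for k in sorted(truth.ortholog_pairs):
            fh.write(f"{k}\t{truth.ortholog_pairs[k]}\n")


def read_truth(outdir) -> TruthTable:
    from pathlib import Path

    from .io import read_tsv_map

    outdir = Path(outdir)
    truth = TruthTable()
    truth.contig_origin = read_tsv_map(outdir / "contig_origin.tsv")
    truth.contig_origin.pop("contig_id", None)
    truth.gene_family = read_tsv_map(outdir / "gene_family.tsv")
    truth.gene_family.pop("gene_id", None)
    with open(outdir / "amplified_families.tsv") as fh:
        rows = [l.strip() for l in fh if l.strip()]
    truth.amplified_families = set(rows[1:])
    truth.ortholog_pairs = read_tsv_map(outdir / "ortholog_pairs.tsv")
    truth.ortholog_pairs.pop("progenitor_gene", None)
    return truth
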