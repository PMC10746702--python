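"""End-to-end desk benchmark: simulate a truth-labelled allotetraploid
system, run every analysis stage on the emitted files, and score
parameter recovery against the truth files.

Stages communicate only through on-disk files in the documented
formats, so each stage is independently testable and can later be fed
real data. The run report is a JSON-able dict with one entry per stage
and pass/fail flags against the configured recovery thresholds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import consensus as cons
from . import families as fam
from . import kmers, phylo, simulate, subgenome, synteny
from . import ks as ks_mod
from ._codons import translate
from .io import (
    assembly_stats,
    read_fasta,
    read_fastq,
    read_gff_genes,
    read_tsv_map,
    read_variants,
    write_fasta,
    write_fastq,
    write_gff_genes,
    write_tsv_map,
    write_variants,
)

log = logging.getLogger("polyploidkit")

PATHWAYS = [
    "ribosome", "spliceosome", "proteasome", "photosynthesis",
    "glycolysis", "oxidative phosphorylation", "starch metabolism",
    "flavonoid biosynthesis", "DNA replication", "plant hormone signaling",
]

RECOVERY_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# Stage 1: simulation


def stage_simulate(config: simulate.SimulationConfig, outdir: Path) -> dict:
    import numpy as np

    outdir = Path(outdir)
    sim = outdir / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    (ss_anc, ss_div, ss_tet, ss_readsA, ss_readsB, ss_fam,
     ss_plast) = ss.spawn(7)

    anc_seqs, anc_genes = simulate.simulate_ancestor(
        config, np.random.default_rng(ss_anc))
    progB_raw = simulate.diverge(anc_seqs, anc_genes, config.target_dS,
                                 config.target_dN, ss_div)
    seqsA, genesA, mapA = simulate.relabel(anc_seqs, anc_genes, "A")
    seqsB, genesB, mapB = simulate.relabel(*progB_raw, "B")
    tet_seqs, tet_genes, truth = simulate.build_allotetraploid(
        (seqsA, genesA), (seqsB, genesB), config.fractionation_rate,
        ss_tet, config.extra_dS)

    # gene -> family maps: one family per ancestral gene
    fam_of_anc = {g.gene_id: f"fam_{g.gene_id}" for g in anc_genes}
    famA = {mapA[g]: f for g, f in fam_of_anc.items()}
    famB = {mapB[g]: f for g, f in fam_of_anc.items()}
    prog_fams = {**famA, **famB}
    famT = {tet: prog_fams[prog] for prog, tet in truth.ortholog_pairs.items()}
    truth.gene_family = {**prog_fams, **famT}

    write_fasta(seqsA, sim / "progenitorA.fa")
    write_gff_genes(genesA, sim / "progenitorA.gff")
    write_fasta(seqsB, sim / "progenitorB.fa")
    write_gff_genes(genesB, sim / "progenitorB.gff")
    write_fasta(tet_seqs, sim / "tetraploid.fa")
    write_gff_genes(tet_genes, sim / "tetraploid.gff")
    write_tsv_map(famA, sim / "gene_families_progenitorA.tsv",
                  ("gene_id", "family_id"))
    write_tsv_map(famB, sim / "gene_families_progenitorB.tsv",
                  ("gene_id", "family_id"))
    write_tsv_map(famT, sim / "gene_families_tetraploid.tsv",
                  ("gene_id", "family_id"))

    readsA = simulate.simulate_reads(seqsA, config.coverage,
                                     config.read_length, config.error_rate,
                                     np.random.default_rng(ss_readsA), "ra")
    readsB = simulate.simulate_reads(seqsB, config.coverage,
                                     config.read_length, config.error_rate,
                                     np.random.default_rng(ss_readsB), "rb")
    write_fastq(readsA, sim / "readsA.fastq.gz")
    write_fastq(readsB, sim / "readsB.fastq.gz")

    rows, amplified = simulate.simulate_family_counts(
        config.n_families, config.n_amplified, np.random.default_rng(ss_fam))
    truth.amplified_families = amplified
    fam.write_family_counts(rows, sim / "families_counts.tsv")
    rng_pw = np.random.default_rng(ss_fam.spawn(1)[0])
    pathways = {r.family_id: PATHWAYS[int(rng_pw.integers(len(PATHWAYS)))]
                for r in rows}
    write_tsv_map(pathways, sim / "family_pathways.tsv",
                  ("family_id", "pathway"))

    plast = simulate.simulate_plastome_accessions(ss_plast)
    pdir = sim / "plastome"
    pdir.mkdir(exist_ok=True)
    write_fasta([plast.reference], pdir / "reference.fa")
    write_gff_genes(plast.genes, pdir / "genes.gff")
    for acc, recs in plast.variants.items():
        write_variants(recs, pdir / f"{acc}.vcf.tsv")
    with open(pdir / "masks.tsv", "w") as fh:
        fh.write("accession\tcontig_id\tstart\tend\n")
        for m in plast.masks:
            for s, e in m.intervals:
                fh.write(f"{m.accession}\t{m.contig_id}\t{s + 1}\t{e}\n")
    phylo.write_newick(plast.true_tree, pdir / "true_tree.nwk")

    simulate.write_truth(truth, sim / "truth")
    return {
        "n_progenitor_contigs": len(seqsA),
        "n_tetraploid_contigs": len(tet_seqs),
        "n_tetraploid_genes": len(tet_genes),
        "n_reads_per_progenitor": len(readsA),
        "tetraploid_assembly": assembly_stats([len(s) for s in tet_seqs]),
    }


# ---------------------------------------------------------------------------
# Stage 2: plastome consensus, Pi, NJ, RF


def stage_plastome(outdir: Path, bootstrap_reps: int = 100, seed: int = 0) -> dict:
    pdir = Path(outdir) / "sim" / "plastome"
    out = Path(outdir) / "out"
    out.mkdir(exist_ok=True)
    ref = read_fasta(pdir / "reference.fa")[0]
    genes = read_gff_genes(pdir / "genes.gff", [ref])

    masks: dict[str, list] = {}
    with open(pdir / "masks.tsv") as fh:
        fh.readline()
        for line in fh:
            acc, ctg, s, e = line.rstrip("\n").split("\t")
            masks.setdefault(acc, []).append((ctg, int(s) - 1, int(e)))
    mask_objs = [
        cons.CoverageMask(acc, ctg,
                          [(s, e) for c2, s, e in ivs if c2 == ctg])
        for acc, ivs in masks.items()
        for ctg in {c for c, _, _ in ivs}
    ]

    consensuses = {}
    for vcf in sorted(pdir.glob("*.vcf.tsv")):
        acc = vcf.name.removesuffix(".vcf.tsv")
        consensuses[acc] = cons.apply_variants(ref, read_variants(vcf))

    covered = cons.filter_covered_genes(genes, mask_objs, min_fraction=1.0)
    pis = cons.pi_table(consensuses, covered)
    cons.write_pi_table(pis, out / "pi.tsv")

    aln = {acc: c.residues for acc, c in consensuses.items()}
    tree, completed = phylo.bootstrap_support(aln, bootstrap_reps, seed)
    phylo.write_newick(tree, out / "njtree.nwk")
    true_tree = phylo.read_newick(pdir / "true_tree.nwk")
    rf = phylo.rf_metrics(tree, true_tree)
    with open(out / "rf.tsv", "w") as fh:
        fh.write("rf\tmax_rf\tnrf\n")
        fh.write(f"{rf.rf}\t{rf.max_rf}\t{rf.nrf:.4f}\n")
    return {
        "n_accessions": len(consensuses),
        "n_genes_covered": len(covered),
        "top_pi_gene": pis[0].gene_id,
        "top_pi": pis[0].pi,
        "bootstrap_completed": completed,
        "rf_vs_truth": {"rf": rf.rf, "max_rf": rf.max_rf, "nrf": rf.nrf},
    }


# ---------------------------------------------------------------------------
# Stage 3: synteny and Ks


def _load_genome(outdir: Path, name: str):
    sim = Path(outdir) / "sim"
    seqs = read_fasta(sim / f"{name}.fa")
    genes = read_gff_genes(sim / f"{name}.gff", seqs)
    fam_map = read_tsv_map(sim / f"gene_families_{name}.tsv")
    fam_map.pop("gene_id", None)
    return seqs, genes, fam_map


def stage_synteny_ks(outdir: Path) -> dict:
    out = Path(outdir) / "out"
    out.mkdir(exist_ok=True)
    _, genesA, famA = _load_genome(outdir, "progenitorA")
    _, genesB, famB = _load_genome(outdir, "progenitorB")
    _, genesT, famT = _load_genome(outdir, "tetraploid")
    cds = {g.gene_id: g.cds for g in genesA + genesB + genesT}

    # progenitor A vs progenitor B: the speciation Ks peak
    hitsAB = synteny.hits_from_families(genesA, genesB, {**famA, **famB},
                                        translate)
    anchorsAB = synteny.find_anchors(genesA, genesB, hitsAB)
    blocksAB = synteny.chain_collinear(anchorsAB)
    ksAB = [v for b in blocksAB
            if (v := ks_mod.block_ks(b, cds)) is not None]
    synteny.write_blocks(blocksAB, out / "blocks_AB.tsv")
    mode_AB = ks_mod.ks_mode(ksAB).mode if len(ksAB) >= 5 else None

    # tetraploid self-synteny: the homoeolog (polyploidization) Ks peak
    hitsT = synteny.hits_from_families(genesT, genesT, famT, translate)
    anchorsT = synteny.find_anchors(genesT, genesT, hitsT, self_mode=True)
    blocksT = synteny.self_synteny(genesT, anchorsT)
    ksT = [v for b in blocksT if (v := ks_mod.block_ks(b, cds)) is not None]
    synteny.write_blocks(blocksT, out / "blocks_self.tsv")
    mode_self = ks_mod.ks_mode(ksT).mode if len(ksT) >= 5 else None

    # tetraploid genes vs progenitor-A orthologs: per-gene dS map
    hitsAT = synteny.hits_from_families(genesA, genesT, {**famA, **famT},
                                        translate)
    best: dict[str, tuple[float, str]] = {}
    for h in hitsAT:
        if h.query not in best or h.score > best[h.query][0]:
            best[h.query] = (h.score, h.subject)
    best_hits = {q: s for q, (sc, s) in best.items()}
    orthologs = fam.true_orthologs(best_hits, {**famA, **famT})
    write_tsv_map(dict(orthologs), out / "true_orthologs_A.tsv",
                  ("progenitor_gene", "tetraploid_gene"))

    ks_to_refA: dict[str, float] = {}
    ksA_tet_values = []
    for h in hitsAT:  # every within-family pair, both subgenome copies
        est = ks_mod.ng86_cds(cds[h.query], cds[h.subject])
        if est.dS is not None:
            ks_to_refA[h.subject] = est.dS
            ksA_tet_values.append(est.dS)
    write_tsv_map({g: f"{v:.5f}" for g, v in ks_to_refA.items()},
                  out / "ks_to_refA.tsv", ("tetraploid_gene", "dS"))

    return {
        "n_blocks_AB": len(blocksAB),
        "mode_AB": mode_AB,
        "n_blocks_self": len(blocksT),
        "mode_self": mode_self,
        "n_true_orthologs_A": len(orthologs),
        "initial_peak_A_copies": _initial_peak(ksA_tet_values),
    }


def _initial_peak(values, split: float = 0.5):
    """Mode of the lower component of a bimodal Ks set (A copies sit near
    the re-divergence dS, B copies near speciation + re-divergence)."""
    if len(values) < 5:
        return None
    lo = sorted(values)[: max(5, len(values) // 2)]
    try:
        return ks_mod.ks_mode(lo).mode
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Stage 4: subgenome assignment and reconciliation


def stage_subgenome(outdir: Path, doc_threshold: float = 16.0, k: int = 31) -> dict:
    out = Path(outdir) / "out"
    sim = Path(outdir) / "sim"
    tet_seqs = read_fasta(sim / "tetraploid.fa")

    depth_records = []
    for sample, fq in (("progenitorA", "readsA.fastq.gz"),
                       ("progenitorB", "readsB.fastq.gz")):
        reads = read_fastq(sim / fq)
        depth_records.append(
            subgenome.assign_reads_by_kmer((sample, reads), tet_seqs, k))
    depths = subgenome.merge_depths(*depth_records)
    from .io import write_depth_table
    write_depth_table(depths, out / "depth.tsv")

    doc_labels, doc_summary = subgenome.classify_contigs_doc(
        depths, "progenitorA", "progenitorB", doc_threshold)
    subgenome.write_labels(doc_labels, out / "doc_labels.tsv")
    subgenome.write_doc_summary(doc_summary, out / "doc_summary.tsv")

    truth = simulate.read_truth(sim / "truth")
    doc_correct = sum(1 for l in doc_labels
                      if l.label == truth.contig_origin.get(l.contig_id))
    doc_accuracy = doc_correct / len(doc_labels) if doc_labels else 0.0

    # Ks route: re-load self blocks and the per-gene dS map from disk
    blocks = _read_blocks(out / "blocks_self.tsv")
    ks_map = {g: float(v) for g, v in
              read_tsv_map(out / "ks_to_refA.tsv").items() if g != "tetraploid_gene"}
    ks_labels = subgenome.partition_ab(blocks, ks_map)
    subgenome.write_labels(ks_labels, out / "ks_labels.tsv")
    ks_scored = [l for l in ks_labels if l.label in ("A", "B")]
    ks_correct = sum(1 for l in ks_labels
                     if l.label == truth.contig_origin.get(l.contig_id))
    ks_accuracy = ks_correct / len(ks_labels) if ks_labels else 0.0

    rec = subgenome.reconcile(ks_labels, doc_labels)
    return {
        "doc_accuracy": doc_accuracy,
        "doc_summary": [
            {"condition": r.condition, "contigs": r.contig_number,
             "total_bp": r.total_size, "mean_other_depth": r.mean_depth}
            for r in doc_summary
        ],
        "ks_partition_accuracy": ks_accuracy,
        "ks_assigned_copies": len(ks_scored),
        "reconcile_agreement": rec.agreement,
        "reconcile_n": rec.n_compared,
        "self_contained_blocks": rec.self_contained,
    }


def _read_blocks(path) -> list[synteny.SyntenyBlock]:
    """Rebuild synteny blocks (rank-free anchors) from a blocks TSV."""
    blocks = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (bid, ca, cb, orientation, n, score, ks_summary,
             pairs) = line.rstrip("\n").split("\t")
            anchors = []
            for rank, pair in enumerate(pairs.split(","), 1):
                ga, gb = pair.split("|")
                anchors.append(
                    synteny.Anchor(ga, gb, ca, cb, rank, rank, 1.0))
            blocks.append(
                synteny.SyntenyBlock(int(bid), ca, cb, anchors, orientation,
                                     float(score),
                                     None if ks_summary == "NA"
                                     else float(ks_summary)))
    return blocks


# ---------------------------------------------------------------------------
# Stage 5: gene families


def stage_families(outdir: Path) -> dict:
    sim = Path(outdir) / "sim"
    out = Path(outdir) / "out"
    rows = fam.read_family_counts(sim / "families_counts.tsv")
    reports = fam.amplified_families(
        rows, simulate.TETRAPLOID, (simulate.DIPLOID_A, simulate.DIPLOID_B))
    fam.write_amplified(reports, out / "amplified.tsv")
    detected = {r.family_id for r in reports if r.amplified}

    truth = simulate.read_truth(sim / "truth")
    tp = len(detected & truth.amplified_families)
    precision = tp / len(detected) if detected else 1.0
    recall = (tp / len(truth.amplified_families)
              if truth.amplified_families else 1.0)

    pathways = read_tsv_map(sim / "family_pathways.tsv")
    pathways.pop("family_id", None)
    rollup, unmapped = fam.pathway_rollup(detected, pathways)
    with open(out / "pathway_rollup.tsv", "w") as fh:
        fh.write("pathway\tn_amplified_families\n")
        for pw, n in rollup:
            fh.write(f"{pw}\t{n}\n")

    ortho = read_tsv_map(out / "true_orthologs_A.tsv")
    ortho.pop("progenitor_gene", None)
    truth_A = {p: t for p, t in truth.ortholog_pairs.items()
               if p.startswith("A_")}
    hit = sum(1 for p, t in truth_A.items() if ortho.get(p) == t)
    ortholog_recall = hit / len(truth_A) if truth_A else 1.0

    return {
        "n_amplified_detected": len(detected),
        "family_precision": precision,
        "family_recall": recall,
        "top_pathways": rollup[:3],
        "ortholog_recall_A": ortholog_recall,
    }


# ---------------------------------------------------------------------------
# Stage 6: k-mer genome size


def stage_kmer(outdir: Path, k: int = 21) -> dict:
    sim = Path(outdir) / "sim"
    reads = ((rid, seq) for rid, seq in read_fastq(sim / "readsA.fastq.gz"))
    hist = kmers.kmer_histogram(reads, k)
    kmers.write_histogram(hist, Path(outdir) / "out" / "kmer_hist.tsv")
    est = kmers.estimate_genome_size(hist)
    true_size = sum(len(s) for s in read_fasta(sim / "progenitorA.fa"))
    return {
        "k": k,
        "peak_depth": est["peak_depth"],
        "genome_size_bp": est["genome_size_bp"],
        "true_size_bp": true_size,
        "relative_error": est["genome_size_bp"] / true_size - 1.0,
    }


# ---------------------------------------------------------------------------
# Orchestration


STAGES = [
    ("simulate", stage_simulate),
    ("plastome", stage_plastome),
    ("synteny_ks", stage_synteny_ks),
    ("subgenome", stage_subgenome),
    ("families", stage_families),
    ("kmer", stage_kmer),
]

DEPENDS = {
    "plastome": ["simulate"],
    "synteny_ks": ["simulate"],
    "subgenome": ["simulate", "synteny_ks"],
    "families": ["simulate", "synteny_ks"],
    "kmer": ["simulate"],
}


def run_desk_benchmark(
    config: simulate.SimulationConfig,
    outdir,
    bootstrap_reps: int = 100,
) -> dict:
    """Run every stage on the desk preset and score recovery.

    Returns (and writes to ``outdir/out/report.json``) a report with
    per-stage metrics and pass/fail flags against the 95% recovery
    thresholds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: getattr(config, k)
                               for k in config.__dataclass_fields__},
                    "stages": {}}
    failed: set[str] = set()
    for name, func in STAGES:
        if any(dep in failed for dep in DEPENDS.get(name, [])):
            report["stages"][name] = {"status": "skipped"}
            failed.add(name)
            continue
        try:
            if name == "simulate":
                result = func(config, outdir)
            elif name == "plastome":
                result = func(outdir, bootstrap_reps, config.seed)
            else:
                result = func(outdir)
            report["stages"][name] = {"status": "ok", **result}
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            failed.add(name)

    checks = {}
    sub = report["stages"].get("subgenome", {})
    famr = report["stages"].get("families", {})
    syn = report["stages"].get("synteny_ks", {})
    if syn.get("mode_AB") is not None:
        checks["ks_mode_in_band"] = bool(0.04 <= syn["mode_AB"] <= 0.06)
    for key, src in (("doc_accuracy", sub), ("ks_partition_accuracy", sub),
                     ("reconcile_agreement", sub),
                     ("family_precision", famr), ("family_recall", famr),
                     ("ortholog_recall_A", famr)):
        if src.get(key) is not None:
            checks[key] = bool(src[key] >= RECOVERY_THRESHOLD)
    report["checks"] = checks
    report["passed"] = all(checks.values()) if checks else False

    (outdir / "out").mkdir(exist_ok=True)
    with open(outdir / "out" / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
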