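import numpy as np
import pytest

from polyploidkit import _codons
from polyploidkit.io import revcomp
from polyploidkit.ks import ng86
from polyploidkit.simulate import (
    SimulationConfig,
    build_allotetraploid,
    diverge,
    read_truth,
    relabel,
    simulate_ancestor,
    simulate_family_counts,
    simulate_plastome_accessions,
    simulate_reads,
    write_truth,
)


def _small_config(**kw):
    defaults = dict(seed=0, n_contigs=2, contig_length=10_000,
                    genes_per_contig=5, cds_length=300)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _concat_codons(genes):
    return np.concatenate([_codons.codon_indices(g.cds)[:-1] for g in genes])


class TestAncestor:
    def test_structure(self):
        seqs, genes = simulate_ancestor(_small_config())
        assert len(seqs) == 2 and len(genes) == 10
        ranks = [g.gene_rank for g in genes if g.contig_id == seqs[0].id]
        assert ranks == [1, 2, 3, 4, 5]

    def test_determinism(self):
        a = simulate_ancestor(_small_config(seed=5))
        b = simulate_ancestor(_small_config(seed=5))
        assert [s.residues for s in a[0]] == [s.residues for s in b[0]]
        assert [g.cds for g in a[1]] == [g.cds for g in b[1]]

    def test_cds_translates_with_terminal_stop(self):
        _, genes = simulate_ancestor(_small_config(cds_length=9))
        for g in genes:
            assert g.cds[:3] == "ATG"
            assert g.cds[-3:] in ("TAA", "TAG", "TGA")
            assert len(_codons.translate(g.cds)) == 2

    def test_genes_embedded_in_contig(self):
        seqs, genes = simulate_ancestor(_small_config())
        by_id = {s.id: s.residues for s in seqs}
        for g in genes:
            window = by_id[g.contig_id][g.start:g.end]
            assert window == (g.cds if g.strand == "+" else revcomp(g.cds))

    def test_overfull_contig_rejected(self):
        with pytest.raises(ValueError, match="do not fit"):
            simulate_ancestor(_small_config(contig_length=1200,
                                            genes_per_contig=5))


class TestDiverge:
    def test_zero_targets_identity(self):
        seqs, genes = simulate_ancestor(_small_config())
        dseqs, dgenes = diverge(seqs, genes, 0.0, 0.0, 3)
        assert [s.residues for s in dseqs] == [s.residues for s in seqs]
        assert [g.cds for g in dgenes] == [g.cds for g in genes]

    def test_calibrated_ds_recovery(self):
        """200 genes x 900 bp at target dS 0.05: measured NG86 dS on the
        emitted pair lands within +/-10% of target."""
        config = SimulationConfig(seed=7, n_contigs=20)
        seqs, genes = simulate_ancestor(config)
        _, dgenes = diverge(seqs, genes, 0.05, 0.0, 7)
        est = ng86(_concat_codons(genes), _concat_codons(dgenes))
        assert 0.045 <= est.dS <= 0.055
        # dN target 0 leaves every protein unchanged; NG86 may still count
        # tiny fractional Nd via path averaging over double synonymous hits
        assert est.dN < 1e-3

    def test_proteins_unchanged_when_dn_zero(self):
        seqs, genes = simulate_ancestor(_small_config())
        _, dgenes = diverge(seqs, genes, 0.05, 0.0, 1)
        for g, d in zip(genes, dgenes):
            assert _codons.translate(g.cds) == _codons.translate(d.cds)

    def test_deterministic(self):
        seqs, genes = simulate_ancestor(_small_config())
        a = diverge(seqs, genes, 0.05, 0.01, 9)
        b = diverge(seqs, genes, 0.05, 0.01, 9)
        assert [s.residues for s in a[0]] == [s.residues for s in b[0]]


class TestAllotetraploid:
    def _progenitors(self, config=None):
        config = config or _small_config()
        seqs, genes = simulate_ancestor(config)
        progA = relabel(seqs, genes, "A")[:2]
        dseqs, dgenes = diverge(seqs, genes, 0.05, 0.01, 2)
        progB = relabel(dseqs, dgenes, "B")[:2]
        return progA, progB

    def test_no_fractionation_keeps_all_genes(self):
        progA, progB = self._progenitors()
        tet, tgenes, truth = build_allotetraploid(progA, progB, 0.0, 4)
        assert len(tgenes) == len(progA[1]) + len(progB[1])
        assert set(truth.contig_origin) == {s.id for s in tet}

    def test_fractionation_within_binomial_interval(self):
        config = SimulationConfig(seed=3, n_contigs=50, contig_length=10_000,
                                  genes_per_contig=10, cds_length=300)
        progA, progB = self._progenitors(config)
        tet, tgenes, truth = build_allotetraploid(progA, progB, 0.1, 3)
        deleted = 1000 - len(tgenes)
        assert 72 <= deleted <= 129  # binomial(1000, 0.1) 99% interval

    def test_origin_covers_all_contigs_and_ranks_rebuilt(self):
        progA, progB = self._progenitors()
        tet, tgenes, truth = build_allotetraploid(progA, progB, 0.3, 8)
        assert set(truth.contig_origin.values()) <= {"A", "B"}
        by_contig = {}
        for g in tgenes:
            by_contig.setdefault(g.contig_id, []).append(g.gene_rank)
        for ranks in by_contig.values():
            assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_overlapping_contig_ids_rejected(self):
        seqs, genes = simulate_ancestor(_small_config())
        with pytest.raises(ValueError, match="disjoint"):
            build_allotetraploid((seqs, genes), (seqs, genes), 0.0, 1)

    def test_truth_roundtrip_via_files(self, tmp_path):
        progA, progB = self._progenitors()
        _, _, truth = build_allotetraploid(progA, progB, 0.1, 5)
        truth.gene_family = {"g1": "fam1"}
        truth.amplified_families = {"fam9"}
        write_truth(truth, tmp_path)
        back = read_truth(tmp_path)
        assert back.contig_origin == truth.contig_origin
        assert back.ortholog_pairs == truth.ortholog_pairs
        assert back.amplified_families == truth.amplified_families


class TestReads:
    def test_read_count_arithmetic(self):
        seqs, _ = simulate_ancestor(_small_config())  # 20 kb genome
        reads = simulate_reads(seqs, 10.0, 100, 0.0, 1)
        assert len(reads) == 2000

    def test_error_free_reads_are_substrings(self):
        seqs, _ = simulate_ancestor(_small_config())
        genome = {s.id: s.residues for s in seqs}
        for _, seq in simulate_reads(seqs, 1.0, 80, 0.0, 2)[:50]:
            assert any(seq in r or revcomp(seq) in r
                       for r in genome.values())

    def test_error_rate_calibration(self):
        """Mismatch fraction over >= 1e6 bases within binomial bounds."""
        config = _small_config(n_contigs=4, contig_length=50_000,
                               genes_per_contig=5, cds_length=300)
        seqs, _ = simulate_ancestor(config)
        clean = simulate_reads(seqs, 6.0, 100, 0.0, 5)
        noisy = simulate_reads(seqs, 6.0, 100, 0.01, 5)
        mismatches = total = 0
        for (_, a), (_, b) in zip(clean, noisy):
            mismatches += sum(x != y for x, y in zip(a, b))
            total += len(a)
        assert total >= 1_000_000
        assert 0.008 <= mismatches / total <= 0.012

    def test_deterministic(self):
        seqs, _ = simulate_ancestor(_small_config())
        assert simulate_reads(seqs, 2.0, 50, 0.01, 7) == \
            simulate_reads(seqs, 2.0, 50, 0.01, 7)


class TestFamilyCounts:
    def test_no_amplified_truth_empty(self):
        rows, amplified = simulate_family_counts(50, 0, 1)
        assert amplified == set()
        assert len(rows) == 50

    def test_amplified_rows_satisfy_rule(self):
        rows, amplified = simulate_family_counts(300, 60, 2)
        by_id = {r.family_id: r.counts for r in rows}
        for fam in amplified:
            c = by_id[fam]
            t, d1, d2 = c["reflexopilosa"], c["trinervia"], c["hirtella"]
            assert t >= 2 * d1 and t >= 2 * d2 and d1 >= 1 and d2 >= 1

    def test_background_rows_strictly_outside_rule(self):
        rows, amplified = simulate_family_counts(500, 50, 3)
        for r in rows:
            if r.family_id in amplified:
                continue
            t = r.counts["reflexopilosa"]
            d1, d2 = r.counts["trinervia"], r.counts["hirtella"]
            assert not (t >= 2 * d1 and t >= 2 * d2)

    def test_deterministic(self):
        a = simulate_family_counts(100, 10, 9)
        b = simulate_family_counts(100, 10, 9)
        assert a == b


class TestPlastome:
    def test_structure_and_determinism(self):
        sim1 = simulate_plastome_accessions(4, n_accessions=8,
                                            ref_length=6000, n_genes=8)
        sim2 = simulate_plastome_accessions(4, n_accessions=8,
                                            ref_length=6000, n_genes=8)
        assert len(sim1.variants) == 8
        assert sim1.accession_seqs == sim2.accession_seqs
        assert {len(s) for s in sim1.accession_seqs.values()} == {6000}

    def test_variants_reconstruct_accessions(self):
        from polyploidkit.consensus import apply_variants

        sim = simulate_plastome_accessions(6, n_accessions=5,
                                           ref_length=5000, n_genes=5,
                                           noise_variant_rate=0.0)
        for acc, recs in sim.variants.items():
            cons = apply_variants(sim.reference, recs, min_qual=30)
            assert cons.residues == sim.accession_seqs[acc]

    def test_low_quality_noise_filtered(self):
        from polyploidkit.consensus import apply_variants

        sim = simulate_plastome_accessions(6, n_accessions=5,
                                           ref_length=5000, n_genes=5,
                                           noise_variant_rate=5e-3)
        acc = sorted(sim.variants)[0]
        assert any(v.qual < 30 for v in sim.variants[acc])
        cons = apply_variants(sim.reference, sim.variants[acc], min_qual=30)
        assert cons.residues == sim.accession_seqs[acc]
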