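import numpy as np
import pytest

from polyploidkit.io import ContigDepthRecord, GenomeSequence
from polyploidkit.simulate import simulate_reads
from polyploidkit.subgenome import (
    assign_reads_by_kmer,
    classify_contigs_doc,
    merge_depths,
    partition_ab,
    reconcile,
    SubgenomeLabel,
)
from polyploidkit.synteny import Anchor, SyntenyBlock


def _block(bid, contig_a, contig_b, genes_a, genes_b):
    anchors = [Anchor(a, b, contig_a, contig_b, i + 1, i + 1, 1.0)
               for i, (a, b) in enumerate(zip(genes_a, genes_b))]
    return SyntenyBlock(bid, contig_a, contig_b, anchors, "plus", 1.0)


class TestPartitionAb:
    def test_lower_median_is_A(self):
        b = _block(0, "c1", "c2", ["x1", "x2"], ["y1", "y2"])
        ks = {"x1": 0.015, "x2": 0.015, "y1": 0.060, "y2": 0.062}
        labels = {l.unit_id: l.label for l in partition_ab([b], ks)}
        assert labels == {"block0/1": "A", "block0/2": "B"}

    def test_reversed_median_order(self):
        b = _block(0, "c1", "c2", ["x1"], ["y1"])
        labels = {l.unit_id: l.label
                  for l in partition_ab([b], {"x1": 0.06, "y1": 0.01})}
        assert labels == {"block0/1": "B", "block0/2": "A"}

    def test_tie_unassigned(self, caplog):
        b = _block(0, "c1", "c2", ["x1"], ["y1"])
        with caplog.at_level("WARNING"):
            labels = partition_ab([b], {"x1": 0.05, "y1": 0.05})
        assert all(l.label == "unassigned" for l in labels)

    def test_missing_orthologs_unassigned(self, caplog):
        b = _block(0, "c1", "c2", ["x1"], ["y1"])
        with caplog.at_level("WARNING"):
            labels = partition_ab([b], {"x1": 0.05})
        assert all(l.label == "unassigned" for l in labels)


class TestKmerAssignment:
    def _contigs(self, rng, n=3, length=4000):
        return [
            GenomeSequence(f"c{i}", "".join("ACGT"[b] for b in
                                            rng.integers(0, 4, length)))
            for i in range(n)
        ]

    def test_reads_from_one_contig_only(self):
        rng = np.random.default_rng(0)
        contigs = self._contigs(rng)
        reads = simulate_reads([contigs[0]], 8.0, 100, 0.0, 1)
        records = assign_reads_by_kmer(("s", reads), contigs, k=31)
        depths = {r.contig_id: r.depth_by_sample["s"] for r in records}
        assert depths["c0"] == pytest.approx(8.0, rel=0.05)
        assert depths["c1"] == 0.0 and depths["c2"] == 0.0

    def test_identical_contigs_all_tied(self, caplog):
        rng = np.random.default_rng(1)
        base = self._contigs(rng, n=1)[0]
        twins = [GenomeSequence("t1", base.residues),
                 GenomeSequence("t2", base.residues)]
        reads = simulate_reads([base], 5.0, 100, 0.0, 2)
        with caplog.at_level("INFO"):
            records = assign_reads_by_kmer(("s", reads), twins, k=31)
        assert all(r.depth_by_sample["s"] == 0.0 for r in records)
        assert "100.00%" in caplog.text

    def test_reads_with_errors_still_assigned(self):
        rng = np.random.default_rng(3)
        contigs = self._contigs(rng)
        reads = simulate_reads([contigs[1]], 10.0, 100, 0.005, 4)
        records = assign_reads_by_kmer(("s", reads), contigs, k=31)
        depths = {r.contig_id: r.depth_by_sample["s"] for r in records}
        assert depths["c1"] > 9.0
        assert depths["c0"] == 0.0


def _depth(contig, length, da, db):
    return ContigDepthRecord(contig, length,
                             {"trinervia": da, "hirtella": db})


class TestDocClassification:
    def test_table_rule_examples(self):
        # depth magnitudes as in the reference report: one contig poorly
        # covered by trinervia reads but well covered by hirtella reads
        # derives from hirtella, and symmetrically
        depths = [_depth("c1", 1000, 3.2, 70.4),
                  _depth("c2", 1000, 91.8, 3.0),
                  _depth("c3", 1000, 5.0, 5.0),
                  _depth("c4", 1000, 40.0, 40.0)]
        labels, summary = classify_contigs_doc(depths, "trinervia",
                                               "hirtella", 16.0,
                                               n90_filter=False)
        by = {l.unit_id: l.detail["condition"] for l in labels}
        assert by["c1"] == "B"  # hirtella-origin
        assert by["c2"] == "A"  # trinervia-origin
        assert by["c3"] == "unassigned-both"
        assert by["c4"] == "unassigned-ambiguous"
        rows = {r.condition: r for r in summary}
        under_tri = rows["DOC under 16x for trinervia reads"]
        assert under_tri.contig_number == 1
        assert under_tri.mean_depth == pytest.approx(70.4)

    def test_threshold_is_strict_less_than(self):
        depths = [_depth("c1", 1000, 16.0, 80.0)]
        labels, _ = classify_contigs_doc(depths, "trinervia", "hirtella",
                                         16.0, n90_filter=False)
        assert labels[0].detail["condition"] == "unassigned-ambiguous"

    def test_partition_and_summary_totals(self):
        rng = np.random.default_rng(5)
        depths = [_depth(f"c{i}", int(rng.integers(500, 5000)),
                         float(rng.uniform(0, 60)), float(rng.uniform(0, 60)))
                  for i in range(40)]
        labels, summary = classify_contigs_doc(depths, "trinervia",
                                               "hirtella", 16.0,
                                               n90_filter=False)
        assert len(labels) == 40
        assert sum(r.contig_number for r in summary) == 40
        assert sum(r.total_size for r in summary) == \
            sum(d.length for d in depths)

    def test_raising_threshold_never_rescues_unassigned_both(self):
        rng = np.random.default_rng(6)
        depths = [_depth(f"c{i}", 1000, float(rng.uniform(0, 40)),
                         float(rng.uniform(0, 40))) for i in range(30)]

        def both_under(threshold):
            labels, _ = classify_contigs_doc(depths, "trinervia", "hirtella",
                                             threshold, n90_filter=False)
            return {l.unit_id for l in labels
                    if l.detail["condition"] == "unassigned-both"}

        low = both_under(16.0)
        for thr in (20.0, 30.0, 45.0):
            assert low <= both_under(thr)

    def test_n90_filter_restricts_to_long_contigs(self):
        depths = [_depth("big1", 9000, 40.0, 3.0),
                  _depth("big2", 9000, 3.0, 40.0),
                  _depth("tiny", 100, 3.0, 3.0)]
        labels, _ = classify_contigs_doc(depths, "trinervia", "hirtella")
        assert {l.unit_id for l in labels} == {"big1", "big2"}

    def test_missing_sample_error(self):
        rec = ContigDepthRecord("c1", 1000, {"trinervia": 5.0})
        with pytest.raises(ValueError, match="hirtella"):
            classify_contigs_doc([rec], "trinervia", "hirtella")


class TestReconcile:
    def _ks(self, block, copy, label, contig):
        return SubgenomeLabel(f"block{block}/{copy}", label, "ks", contig)

    def _doc(self, contig, label):
        return SubgenomeLabel(contig, label, "doc", contig)

    def test_full_agreement(self):
        ks = [self._ks(0, 1, "A", "c1"), self._ks(0, 2, "B", "c2")]
        doc = [self._doc("c1", "A"), self._doc("c2", "B")]
        rep = reconcile(ks, doc)
        assert rep.agreement == 1.0 and rep.n_compared == 2

    def test_disagreement_listed(self):
        ks = [self._ks(0, 1, "A", "c1"), self._ks(0, 2, "B", "c2")]
        doc = [self._doc("c1", "B"), self._doc("c2", "B")]
        rep = reconcile(ks, doc)
        assert rep.agreement == 0.5
        assert rep.disagreements == [("block0/1", "A", "B")]

    def test_self_contained_block_excluded(self):
        ks = [self._ks(0, 1, "A", "c1"), self._ks(0, 2, "B", "c1"),
              self._ks(1, 1, "A", "c2"), self._ks(1, 2, "B", "c3")]
        doc = [self._doc("c1", "A"), self._doc("c2", "A"),
               self._doc("c3", "B")]
        rep = reconcile(ks, doc)
        assert rep.self_contained == ["block0"]
        assert rep.n_compared == 2 and rep.agreement == 1.0


def test_merge_depths_combines_samples():
    a = [ContigDepthRecord("c1", 100, {"s1": 5.0})]
    b = [ContigDepthRecord("c1", 100, {"s2": 7.0})]
    merged = merge_depths(a, b)
    assert merged[0].depth_by_sample == {"s1": 5.0, "s2": 7.0}
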