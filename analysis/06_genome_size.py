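#!/usr/bin/env python
"""k-mer genome-size estimation from progenitor reads.

Counts canonical 21-mers in the progenitor-A read set, separates the
sequencing-error peak at the spectrum's first local minimum, and
estimates genome size as (k-mers above the cutoff) / (main-peak depth).
Writes kmer_hist.tsv to scratch/run/out/ and publishes them to results/run/.
"""

from polyploidkit.io import setup_logging
from polyploidkit.pipeline import stage_kmer

from common import WORKDIR, publish_outputs

OUTDIR = WORKDIR

if __name__ == "__main__":
    setup_logging("info")
    summary = stage_kmer(OUTDIR, k=21)
    print("k-mer genome size:")
    print(f"  k = {summary['k']}, main-peak depth = {summary['peak_depth']:g}")
    print(f"  estimate = {summary['genome_size_bp']:.0f} bp"
          f" (truth {summary['true_size_bp']} bp,"
          f" error {100 * summary['relative_error']:+.1f}%)")
    publish_outputs()
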