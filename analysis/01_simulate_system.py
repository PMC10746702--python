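#!/usr/bin/env python
"""Simulate the truth-labelled allotetraploid study system.

Emits, under scratch/run/sim/: two diploid progenitor genomes diverged
at dS 0.05, their allotetraploid union (with 5% gene fractionation),
40x short reads from each progenitor, a gene-family count table with
100 amplified families, a plastome reference with 23 variant-called
accessions on a known tree, and the truth tables every later step is
scored against.
"""

from polyploidkit.io import setup_logging
from polyploidkit.pipeline import stage_simulate
from polyploidkit.simulate import SimulationConfig

from common import SEED, WORKDIR, publish_outputs

OUTDIR = WORKDIR

if __name__ == "__main__":
    setup_logging("info")
    config = SimulationConfig(seed=SEED)
    summary = stage_simulate(config, OUTDIR)
    print("simulated system:")
    for key, value in summary.items():
        print(f"  {key}: {value}")
    publish_outputs()
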