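"""Shared paths for the numbered analysis drivers.

The working directory (simulated genomes, reads, intermediate files)
lives under scratch/ because it is bulky and fully regenerable from the
seed; only the small result tables under <workdir>/out are published to
results/.
"""

import shutil
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
WORKDIR = REPO / "scratch" / "run"
RESULTS = REPO / "results" / "run"
SEED = 1

PUBLISH_LIMIT = 64_000  # bytes


def publish_outputs() -> None:
    """Copy the (small) analysis tables from the workdir to results/."""
    out = WORKDIR / "out"
    if not out.is_dir():
        return
    RESULTS.mkdir(parents=True, exist_ok=True)
    for path in sorted(out.iterdir()):
        if path.is_file() and path.stat().st_size <= PUBLISH_LIMIT:
            shutil.copy2(path, RESULTS / path.name)
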