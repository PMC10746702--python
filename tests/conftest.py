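import pytest

from polyploidkit import pipeline
from polyploidkit.simulate import SimulationConfig

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_report(tmp_path_factory):
    """One full desk-preset benchmark run shared by the recovery tests."""
    outdir = tmp_path_factory.mktemp("desk")
    config = SimulationConfig(seed=DESK_SEED)
    return pipeline.run_desk_benchmark(config, outdir, bootstrap_reps=50)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast preset for structural/determinism tests."""
    return SimulationConfig(
        seed=11, n_contigs=6, contig_length=20_000, genes_per_contig=8,
        cds_length=600, coverage=25.0, n_families=200, n_amplified=20,
    )
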