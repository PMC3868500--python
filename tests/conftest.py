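import numpy as np
import pytest

from smallrna_dx import pipeline as pl
from smallrna_dx import profiling as pr
from smallrna_dx import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    """Desk-scale simulation: 20 miRNAs, 5k reads/library, edits + contamination."""
    return sim.SimulationConfig(
        n_chromosomes=2,
        chrom_length=5000,
        n_mirnas=20,
        library_depths=(5000, 5000),
        log2_effects={"syn-mir-001": 2.0, "syn-mir-002": -2.0},
        seed_edit_rate=0.05,
        contamination_rate=0.10,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(genome, reference, reads_nc, reads_mn, truth) for the small config."""
    genome = sim.generate_genome(
        small_config.n_chromosomes, small_config.chrom_length, small_config.rng_seed
    )
    reference, truth = sim.plant_mirnas(genome, small_config)
    reads_nc, reads_mn, truth = sim.simulate_libraries(reference, small_config, truth)
    return genome, reference, reads_nc, reads_mn, truth


@pytest.fixture(scope="session")
def mature_reference(small_dataset):
    _genome, reference, *_ = small_dataset
    return [pr.MatureMiRNA(name, seq) for name, seq in reference]


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory, small_config):
    cfg = pl.PipelineConfig(
        outdir=str(tmp_path_factory.mktemp("pipe")),
        simulation=small_config,
        n_pairs=3,
    )
    return pl.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
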