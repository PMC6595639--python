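import logging

import numpy as np
import pytest

from footgrn.pipeline import PipelineConfig, run_all
from footgrn.simulate import SimConfig, simulate_cohort

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort for fast unit tests: one small chromosome pair,
    fewer peaks, moderate depth."""
    return SimConfig(
        seed=11,
        n_chromosomes=1,
        chrom_length=300_000,
        n_genes=30,
        n_peaks=40,
        samples_per_subtype=2,
        n_control_samples=2,
        reads_per_sample=400_000,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at generator defaults, shared across tests."""
    outdir = tmp_path_factory.mktemp("run_default")
    manifest = run_all(PipelineConfig(outdir=str(outdir), seed=1))
    return manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
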