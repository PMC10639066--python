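import numpy as np
import pytest

from pausekit.synthetic import ScenarioEffect, SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast four-arm design kept small enough for per-test reuse."""
    return SimulationConfig(
        n_genes=300,
        genome_length=8_000_000,
        depth_per_sample=400_000,
        n_replicates=2,
        seed=20240917,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def release_only_config() -> SimulationConfig:
    """Vehicle plus a single pause-release arm; used for directional checks."""
    return SimulationConfig(
        n_genes=500,
        genome_length=12_000_000,
        depth_per_sample=600_000,
        conditions=(
            ScenarioEffect("DMSO"),
            ScenarioEffect("CDK12i", 1.0, 0.5, 1.5),
        ),
        seed=77,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
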