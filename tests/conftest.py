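import numpy as np
import pytest

from chemograd.cli_io import normalize_intensities
from chemograd.sequential_pipeline import PipelineConfig
from chemograd.synthetic_data import (
    generate,
    reference_scenarios,
    scaled_scenario,
)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Short chemokine-like scenario small enough for fast end-to-end tests."""
    return scaled_scenario(
        reference_scenarios()["ccl19-like"],
        n_positions=40,
        grid_refinement=2,
        substep_refinement=2,
    )


@pytest.fixture(scope="session")
def tiny_synthetic(tiny_scenario):
    return generate(tiny_scenario, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_synthetic):
    ds, scale = normalize_intensities(tiny_synthetic.dataset)
    return ds


@pytest.fixture()
def fast_config():
    """MCMC settings scaled for smoke tests, not for quantitative accuracy."""
    return PipelineConfig(
        n_iter=600, burn_in=200, n_nodes=31, substeps=10, seed=7
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
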