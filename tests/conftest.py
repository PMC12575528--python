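import numpy as np
import pytest

from lewyquant import synthcohort
from lewyquant.pipeline import PipelineConfig, simulate_tiles, train_and_validate
from lewyquant.regions import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def easy_cohort():
    """Easy-preset cohort: 71 subjects, well-separated subgroup profiles."""
    config = synthcohort.easy_cohort_config(seed=11)
    subjects, measurements = synthcohort.generate_cohort(config)
    return subjects, measurements


@pytest.fixture(scope="session")
def trained_segmentation():
    """Train the deposit classifier on 10 synthetic tiles and keep the
    10 independent test tiles around (shared: training is the slow part)."""
    config = PipelineConfig(seed=1, sim_tile_px=192)
    train_tiles, test_tiles = simulate_tiles(config)
    model, report = train_and_validate(config, train_tiles, test_tiles)
    return config, train_tiles, test_tiles, model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
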