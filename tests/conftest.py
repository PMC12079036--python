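import dataclasses

import pytest

from smiledetect import (
    RaterSimConfig,
    SimulationConfig,
    simulate_raters,
    simulate_segments,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded dataset at the default study geometry (158 x 50 frames)."""
    cfg = dataclasses.replace(SimulationConfig(), seed=7)
    segments, truth = simulate_segments(cfg)
    return segments, truth


@pytest.fixture(scope="session")
def default_ratings(default_dataset):
    _, truth = default_dataset
    cfg = dataclasses.replace(RaterSimConfig(), seed=11)
    return simulate_raters(truth, cfg)
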