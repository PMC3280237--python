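import dataclasses

import numpy as np
import pytest

from brainrisk.gpc import GPConfig
from brainrisk.nested_rfe import RFEConfig, run_nested_cv
from brainrisk.synthetic import presets, simulate


@pytest.fixture(scope="session")
def easy_data():
    """The strong-signal preset dataset (57 planted voxels among 2000)."""
    return simulate(presets()["easy"])


@pytest.fixture(scope="session")
def easy_cv(easy_data):
    """Nested CV on the easy preset at a desk-scale RFE step."""
    return run_nested_cv(easy_data.datasets["neutral"], RFEConfig(step=500), GPConfig())


@pytest.fixture(scope="session")
def null_data():
    """One no-effect dataset (8 pairs, 500 voxels, exchangeable labels)."""
    return simulate(presets()["null"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_balanced_labels(n_pairs: int) -> np.ndarray:
    return np.array([1, -1] * n_pairs, dtype=float)


@pytest.fixture(scope="session")
def tiny_spec():
    """A deliberately small generator setting for fast end-to-end runs."""
    return dataclasses.replace(
        presets()["easy"],
        n_pairs=5,
        grid_shape=(6, 6, 3),
        cluster_center=(3, 3, 1),
        cluster_radius=1.5,
        effect_size=2.5,
        outcome_coupling=2.0,
        seed=2,  # yields both outcome classes among the 5 at-risk subjects
    )
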