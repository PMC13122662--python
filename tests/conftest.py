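import numpy as np
import pytest

from plurimap.simdata import PROGRAMS, STATES, SimConfig


def small_sizes() -> dict:
    return {
        "primed": 200, "bridge": 40, "intermediate_A": 60, "intermediate_B": 60,
        "naive": 80, "ectoderm": 80, "mesoderm": 100,
    }


@pytest.fixture
def small_config() -> SimConfig:
    """A ~620-cell dataset: fast enough for unit tests, same structure."""
    return SimConfig(seed=11, n_cells_per_state=small_sizes())


@pytest.fixture
def blob_config() -> SimConfig:
    """Separable state blobs: flattened gradients, no heterogeneity, strong
    fold-changes and near-Poisson counts."""
    return SimConfig(
        seed=7,
        n_cells_per_state={s: 90 for s in STATES},
        discrete_states=True,
        primed_heterogeneity=0.0,
        branch_noise_sd=0.0,
        doublet_rate=0.0,
        nb_dispersion=50.0,
        program_logfc={p: 8.0 for p in PROGRAMS},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
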