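import numpy as np
import pytest

import firefeedback as ff
from firefeedback.engine import DEFAULT_FUEL_MODELS
from firefeedback.landscape import LandscapeState


@pytest.fixture(scope="session")
def default_result():
    """The full default paired experiment (3 transects x 3 scenarios x 10
    replicates x 2 modes); shared across the directional-analysis tests."""
    return ff.run_experiment(ff.ExperimentConfig())


@pytest.fixture(scope="session")
def small_config():
    """A reduced single-transect configuration for fast pipeline tests."""
    return ff.ExperimentConfig(
        n_rows=40,
        n_cols=40,
        n_replicates=2,
        transect_names=("north",),
        scenarios={"climA": {"trend": 25.0, "noise_sd": 25.0, "base": 150.0}},
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return ff.run_experiment(small_config)


def uniform_landscape(
    n=20,
    live=10000.0,
    dead=1000.0,
    fuel="mixed_conifer",
    veg="mixed_conifer",
    cell_area=1.0,
    year=2010,
) -> LandscapeState:
    """A homogeneous landscape for engine-level tests."""
    shape = (n, n)
    return LandscapeState(
        veg_type=np.full(shape, veg, dtype="U20"),
        elevation=np.full(shape, 1000.0),
        live_biomass=np.full(shape, float(live)),
        dead_biomass=np.full(shape, float(dead)),
        fuel_model=np.full(shape, fuel, dtype="U20"),
        time_since_fire=np.full(shape, 100, dtype=int),
        year=year,
        cell_area=cell_area,
    )


@pytest.fixture
def flat_landscape():
    return uniform_landscape()


@pytest.fixture
def fuel_models():
    return DEFAULT_FUEL_MODELS
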