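import numpy as np
import pytest

from extrisk import ExtinctionRiskModel, ForestConfig, WorldConfig, simulate

#: compact world used by most unit tests: same generating structure as the
#: default, fewer species and a coarser lattice
SMALL_WORLD = dict(
    n_species=400, resolution=1.0, lat_min=-60.0, lat_max=60.0, field_smooth_cells=5.0,
)


@pytest.fixture(scope="session")
def small_data():
    return simulate(WorldConfig(seed=42, **SMALL_WORLD))


@pytest.fixture(scope="session")
def small_fit(small_data):
    """A fitted model/results pair on the small world."""
    model = ExtinctionRiskModel.from_dataframe(
        small_data.traits, small_data.rasters, small_data.atlas,
        config=ForestConfig(n_trees=60),
    )
    return model, model.fit(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
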