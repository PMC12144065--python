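import numpy as np
import pytest

from vacmorph import synthetic as vg


@pytest.fixture
def rng():
    return np.random.default_rng(20250904)


@pytest.fixture(scope="session")
def geometry():
    return vg.CellGeometry()


@pytest.fixture(scope="session")
def cell_mask(geometry):
    return geometry.cell_mask()


@pytest.fixture(scope="session")
def quiet_scenario():
    """No events, no noise: every frame identical."""
    return vg.Scenario(
        "quiet", constriction_rate=0.0, fusion_rate=0.0, satellite_vacuole_count=2,
        noise_sd=0.0, frame_count=10,
    )


@pytest.fixture(scope="session")
def unpollinated_movie():
    sc = vg.scenario_presets("unpollinated", seed=11)
    return vg.simulate_vacuole_sequence(sc)
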