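import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cafprox as cp
from cafprox import CellType

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def flat_geom():
    """Flat interface, 2000 x 150 um band — the zero-waviness fixture."""
    return cp.make_interface(2000, 150, 0, 1)


@pytest.fixture(scope="session")
def wavy_geom():
    """Standard wavy fixture used for ROI placement and pipelines."""
    return cp.make_interface(2000, 150, 20, 7)


@pytest.fixture(scope="session")
def sparse_setup():
    """Large frame, 20 sparse references — the pure-offspring regime."""
    geom = cp.make_flat_geometry(2600, 150, tumor_zone_height=2400)
    refs = cp.sparse_reference_table(geom, 20, seed=1)
    return geom, refs


def offspring_fraction(geom, refs, sigma, n, seed, inner=50.0, outer=100.0):
    """Within-fraction of n pure-offspring CAFs around the references."""
    cfg = cp.SimulationConfig(
        clustered_fraction=1.0,
        displacement_scale_sigma=sigma,
        spindle_fraction=1.0,
        n_cafs=n,
        rng_seed=seed,
    )
    cafs = cp.simulate_cafs(geom, refs, cfg)
    res = cp.nearest_neighbor_distances(cafs.select(CellType.CAF), refs)
    return cp.fraction_within(res, inner=inner, outer=outer)


@pytest.fixture(scope="session")
def default_cells(wavy_geom):
    cfg = cp.SimulationConfig(rng_seed=5)
    refs = cp.simulate_reference_cells(wavy_geom, cfg)
    cafs = cp.simulate_cafs(wavy_geom, refs, cfg)
    return cp.concat_tables([refs, cafs])
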