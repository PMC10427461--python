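import numpy as np
import pytest
from hypothesis import settings

import farmscape as fs

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    # 2-degree cells over a 60 x 180 degree tropical window: big enough in km
    # for dispersal radii of a few thousand km, small enough to keep fits fast
    return fs.GridSpec(n_lat=30, n_lon=90, lat_min=-30, lat_max=30, lon_min=-90, lon_max=90)


@pytest.fixture(scope="session")
def climate(grid):
    return fs.gen_climate(grid, seed=1)


@pytest.fixture(scope="session")
def species_pool(climate):
    return fs.gen_species_pool(5, climate, seed=7)


@pytest.fixture(scope="session")
def richness_true(species_pool, climate):
    return fs.true_richness_map(species_pool, climate, radius_km=3000.0)


@pytest.fixture(scope="session")
def societies(climate, richness_true):
    return fs.gen_societies(300, climate, richness_true, seed=5)


@pytest.fixture(scope="session")
def propensity_scores(societies):
    return fs.farming_propensity(societies, n_draws=100, seed=2)


@pytest.fixture(scope="session")
def fitted_species(species_pool, climate):
    """One fitted niche model (first species of the pool, 200 records)."""
    from farmscape.niche import fit_species

    sp = species_pool.species[0]
    occ = fs.sample_occurrences(sp, climate, 200, seed=11)
    res = fit_species(sp.species_id, occ, climate, seed=3)
    assert res is not None
    return sp, occ, res
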