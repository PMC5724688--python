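import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from canophot.canopy3d import CanopySpec, LeafBladeSpec, default_canopy_spec
from canophot.lightenv import SolarState
from canophot.synthetic import (
    random_homogeneous_canopy,
    single_facet_canopy,
    stacked_facets_canopy,
)


@pytest.fixture(scope="session")
def small_canopy_spec():
    """Reduced stand (fewer tillers/segments) for fast pipeline tests."""
    return default_canopy_spec(tillers=3, segments=5)


@pytest.fixture(scope="session")
def tiny_canopy_spec():
    """Miniature 2x2-plant stand for sweep tests."""
    return default_canopy_spec(plants_x=2, plants_y=2, tillers=2, segments=4)


@pytest.fixture(scope="session")
def one_leaf_spec():
    """Single plant with one nearly-horizontal leaf."""
    blade = LeafBladeSpec(
        rank=1,
        base_height=0.5,
        base_azimuth=0.0,
        base_inclination=5.0,
        length=0.2,
        max_width=0.05,
        curvature=0.1,
        segments=4,
    )
    return CanopySpec(
        plants_x=1,
        plants_y=1,
        row_spacing=1.0,
        plant_spacing=1.0,
        leaves_per_plant=(blade,),
        position_jitter=0.0,
        azimuth_jitter_deg=0.0,
    )


@pytest.fixture(scope="session")
def overhead_sun():
    """Beam from the zenith, 1000 umol m-2 s-1, no diffuse."""
    return SolarState(
        latitude=0.0, day_of_year=235, hour=12.0, zenith=0.0, azimuth=180.0,
        direct_ppfd=1000.0, diffuse_ppfd=0.0,
    )


@pytest.fixture(scope="session")
def single_facet():
    return single_facet_canopy(area=0.04, height=0.5)


@pytest.fixture(scope="session")
def stacked_pair():
    """Two cell-spanning layers: periodic tiling makes them infinite slabs."""
    return stacked_facets_canopy(n_layers=2, area=1.0, top_height=1.0, spacing=0.4)


@pytest.fixture(scope="session")
def spherical_canopy():
    return random_homogeneous_canopy(lai=3.0, n_facets=3000, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
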