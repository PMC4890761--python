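import numpy as np
import pytest
from shapely.geometry import box

import blockpop as bp


def _small_config(seed: int, **kwargs) -> bp.SimConfig:
    """A fast 4-municipality country for statistical checks over many seeds."""
    defaults = dict(
        n_municipalities=4,
        districts_per_municipality=(2, 3),
        neighbourhoods_per_district=(3, 5),
        buildings_per_neighbourhood=(10, 25),
    )
    defaults.update(kwargs)
    return bp.SimConfig(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_config():
    return _small_config


@pytest.fixture(scope="session")
def world():
    """Default desk-scale country (12 municipalities, ~150 neighbourhoods)."""
    return bp.generate_world(bp.SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_world():
    return bp.generate_world(_small_config(7))


@pytest.fixture(scope="session")
def noiseless_world():
    """Constant space per resident, no floorspace noise, fractions in {0, 1}."""
    return bp.generate_world(
        bp.SimConfig.noiseless_proportional(seed=11, n_municipalities=4)
    )


def _rect_building(bid, nbhd, x0, y0, w, d, *, height=6.0, fraction=1.0,
                   floorspace=None, base=0.0):
    poly = box(x0, y0, x0 + w, y0 + d)
    area = w * d
    return bp.Building(
        id=bid, neighbourhood_id=nbhd, footprint=poly, footprint_area=area,
        floorspace=area * 2 if floorspace is None else floorspace,
        base_elevation=base, height=height, residential_fraction=fraction,
    )


@pytest.fixture(scope="session")
def rect_building():
    return _rect_building


@pytest.fixture()
def prison_world():
    """Toy district with two neighbourhoods: one ordinary residential one,
    and one whose only building is non-residential but inhabited (a prison
    whose inmates are counted in the census)."""
    units = [
        bp.StatUnit(id="C0", level="country", parent_id=None, population=575,
                    land_area=2e6),
        bp.StatUnit(id="MU0", level="municipality", parent_id="C0",
                    population=575, land_area=2e6),
        bp.StatUnit(id="DI0", level="district", parent_id="MU0", population=575,
                    land_area=2e6),
        bp.StatUnit(id="NB-res", level="neighbourhood", parent_id="DI0",
                    population=500, land_area=1e6),
        bp.StatUnit(id="NB-prison", level="neighbourhood", parent_id="DI0",
                    population=75, land_area=1e6),
    ]
    hierarchy = bp.Hierarchy(units)
    buildings = [
        _rect_building("B-house1", "NB-res", 0, 0, 20, 15, fraction=1.0),
        _rect_building("B-house2", "NB-res", 50, 0, 25, 16, fraction=1.0),
        _rect_building("B-prison", "NB-prison", 200, 0, 40, 30, fraction=0.0),
    ]
    return hierarchy, buildings
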