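import numpy as np
import pytest
from shapely.geometry import Polygon

from sapmap import (
    PriorityArea,
    ResponseSet,
    SyntheticScenario,
    Vessel,
    draw_interviews,
    generate_population,
)


def square(x0, y0, side_m):
    return Polygon(
        [(x0, y0), (x0 + side_m, y0), (x0 + side_m, y0 + side_m), (x0, y0 + side_m)]
    )


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def population(scenario):
    """Full synthetic register and census responses (generated once)."""
    return generate_population(scenario)


@pytest.fixture(scope="session")
def sampled_register(scenario, population):
    register, _ = population
    flagged, _cov = draw_interviews(register, scenario)
    return flagged


@pytest.fixture(scope="session")
def map_products(scenario, population, sampled_register):
    """Full mapping pipeline on the interview sample (run once per session)."""
    from sapmap import build_maps

    _, census = population
    return build_maps(
        sampled_register, census, port_coords=scenario.port_coords()
    )


@pytest.fixture
def toy_register():
    """Two ports, two gears, small enough to check by hand."""
    return [
        Vessel("A1", "P1", "pots", 6.0, crew_fulltime=1, interviewed=True),
        Vessel("A2", "P1", "pots", 6.5, crew_fulltime=1, interviewed=True),
        Vessel("A3", "P1", "pots", 6.2, crew_fulltime=1),
        Vessel("B1", "P1", "nephrops_trawl", 12.0, crew_fulltime=3, interviewed=True),
        Vessel("B2", "P1", "nephrops_trawl", 13.0, crew_fulltime=3),
        Vessel("C1", "P2", "pots", 6.8, crew_fulltime=1, interviewed=True),
    ]


def toy_response(vessel_id, geom, raw=None, kind=None, fishery="pots", suffix="1"):
    return PriorityArea(
        area_id=f"{vessel_id}-{suffix}",
        respondent_id=f"R-{vessel_id}",
        vessel_id=vessel_id,
        fishery=fishery,
        geometry=geom,
        raw_importance=raw,
        raw_kind=kind,
    )


@pytest.fixture
def toy_responses(toy_register):
    """One 4 km² square per interviewed toy vessel, near its port."""
    areas = []
    for i, v in enumerate(v for v in toy_register if v.interviewed):
        areas.append(
            toy_response(
                v.vessel_id,
                square(i * 10_000, 5_000, 2_000),
                fishery="nephrops" if v.gear == "nephrops_trawl" else "pots",
            )
        )
    return ResponseSet(areas)
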