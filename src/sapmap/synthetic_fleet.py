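"""Synthetic fleets and surveys with the structure the method assumes.

Generates a register of ~250 vessels across ~20 ports on a synthetic
coastline, with gear and length mixtures shaped like a small-boat inshore
fleet (trawlers and dredgers concentrated at three main ports, pot boats
scattered across minor ports), crew increasing with vessel length, fishing
ranges increasing with length, and per-combination priority polygons that
share a common core so within-combination spatial overlap is high.  An
interview subsample is drawn by stratified Bernoulli sampling.  Everything
is deterministic given the scenario seed.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .errors import SyntheticError
from .fleet_registry import (
    CategoryScheme,
    Vessel,
    categorize,
    default_category_scheme,
)
from .survey import PriorityArea, ResponseSet

logger = logging.getLogger(__name__)

#: Mean full-time crew per length class: rises with vessel size, pot boats
#: (which are often single-handed) sit below trawlers of the same length,
#: and pelagic vessels carry far larger crews (8-10) than anything else.
DEFAULT_CREW_BASE: dict[str, float] = {
    "<7": 1.0,
    "7-<9": 1.5,
    "9-<10 pots": 1.0,
    "9-<10 non-pots": 2.5,
    "10-<15": 3.0,
    "15-<20": 4.0,
    ">=20": 6.0,
    "pelagic": 9.0,
}

#: Gear mixtures: main ports host the trawl, dredge and pelagic fleets;
#: minor ports are almost entirely pot boats.
MAIN_PORT_GEAR_MIX: dict[str, float] = {
    "nephrops_trawl": 0.60,
    "dredge": 0.15,
    "whitefish_trawl": 0.05,
    "pots": 0.17,
    "pelagic": 0.03,
}
MINOR_PORT_GEAR_MIX: dict[str, float] = {
    "pots": 0.90,
    "nephrops_trawl": 0.06,
    "dredge": 0.04,
}

#: Length ranges (metres) drawn uniformly per gear.
GEAR_LENGTH_RANGE: dict[str, tuple[float, float]] = {
    "pots": (4.5, 9.9),
    "nephrops_trawl": (9.0, 24.0),
    "dredge": (10.0, 22.0),
    "whitefish_trawl": (12.0, 20.0),
    "pelagic": (28.0, 36.0),
}

GEAR_FISHERY: dict[str, str] = {
    "nephrops_trawl": "nephrops",
    "pots": "pots",
    "dredge": "scallops",
    "whitefish_trawl": "whitefish",
    "pelagic": "other",
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameter set for one synthetic fleet + survey.

    Defaults are the study conditions: 246 active vessels across 20 ports,
    three of them major, an interview inclusion probability of 0.48, and
    size-dependent ranges from port.
    """

    seed: int = 0
    n_vessels: int = 246
    n_ports: int = 20
    n_main_ports: int = 3
    main_port_share: tuple[float, ...] = (0.28, 0.22, 0.18)
    port_spacing_m: float = 12_000.0
    crew_sd: float = 0.5
    seasonal_rate: float = 0.25
    interview_p: float = 0.48
    #: per-gear overrides of the inclusion probability
    interview_p_by_gear: Mapping[str, float] = field(default_factory=dict)
    #: force at least one interview per populated category (0 disables)
    min_per_category: int = 1
    areas_per_respondent_mean: float = 0.8  # extra areas ~ Poisson(mean)
    max_areas: int = 4
    importance_kind: str = "months"
    dirichlet_alpha: float = 2.0
    core_jitter: float = 0.08  # respondent jitter as a fraction of range
    crs: str = "EPSG:3035"

    def port_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_ports)]

    def port_coords(self) -> dict[str, tuple[float, float]]:
        """Ports spaced along a straight east-west coastline; sea to the north."""
        return {
            name: (100_000.0 + i * self.port_spacing_m, 0.0)
            for i, name in enumerate(self.port_names())
        }

    def main_ports(self) -> list[str]:
        # spread the major ports along the coast
        idx = np.linspace(2, self.n_ports - 3, self.n_main_ports).round().astype(int)
        names = self.port_names()
        return [names[i] for i in idx]


def fishing_range_m(gear: str, length_m: float) -> float:
    """Maximum distance from port: grows with length, short for pot boats."""
    if gear == "pots":
        return (2.0 + 0.6 * length_m) * 1000.0
    return (4.0 + 1.6 * length_m) * 1000.0


def _combo_rng(scenario: SyntheticScenario, port: str, gear: str) -> np.random.Generator:
    """Deterministic per-(port, gear) stream, independent of vessel order."""
    return np.random.default_rng(
        [scenario.seed, zlib.crc32(port.encode()), zlib.crc32(gear.encode())]
    )


def _port_allocation(scenario: SyntheticScenario) -> dict[str, int]:
    """Deterministic largest-remainder allocation of vessels to ports."""
    names = scenario.port_names()
    mains = scenario.main_ports()
    if scenario.n_vessels < scenario.n_ports:
        raise SyntheticError(
            f"{scenario.n_vessels} vessels cannot populate {scenario.n_ports} ports"
        )
    weights = {}
    minor_share = 1.0 - sum(scenario.main_port_share)
    n_minor = scenario.n_ports - scenario.n_main_ports
    if minor_share <= 0 or n_minor < 0:
        raise SyntheticError("main_port_share must sum to < 1")
    for name in names:
        if name in mains:
            weights[name] = scenario.main_port_share[mains.index(name)]
        else:
            weights[name] = minor_share / n_minor
    quotas = {p: scenario.n_vessels * w for p, w in weights.items()}
    counts = {p: max(1, int(math.floor(q))) for p, q in quotas.items()}
    # distribute the remainder by largest fractional part, then port name
    while sum(counts.values()) < scenario.n_vessels:
        p = max(names, key=lambda p: (quotas[p] - counts[p], p))
        counts[p] += 1
    while sum(counts.values()) > scenario.n_vessels:
        p = max(names, key=lambda p: (counts[p] - quotas[p], p))
        if counts[p] > 1:
            counts[p] -= 1
    return counts


def generate_population(
    scenario: SyntheticScenario,
    scheme: CategoryScheme | None = None,
) -> tuple[list[Vessel], ResponseSet]:
    """Generate the full register and a census response set (every vessel).

    Priority polygons are buffered discs anchored on a per-(port, gear)
    core bearing and distance, so respondents within a combination share a
    common footprint (high overlap) while pot fleets at different ports are
    spatially separate.  Same seed, same output, bit for bit.
    """
    scheme = scheme or default_category_scheme()
    rng = np.random.default_rng(scenario.seed)
    coords = scenario.port_coords()
    mains = set(scenario.main_ports())
    counts = _port_allocation(scenario)

    vessels: list[Vessel] = []
    vid = 0
    for port in scenario.port_names():
        mix = MAIN_PORT_GEAR_MIX if port in mains else MINOR_PORT_GEAR_MIX
        gears = list(mix)
        probs = np.array([mix[g] for g in gears])
        probs = probs / probs.sum()
        for _ in range(counts[port]):
            vid += 1
            gear = gears[int(rng.choice(len(gears), p=probs))]
            lo, hi = GEAR_LENGTH_RANGE[gear]
            length = float(rng.uniform(lo, hi))
            cat = categorize(
                Vessel(f"tmp", port, gear, length), scheme
            )
            base = DEFAULT_CREW_BASE.get(cat, 2.0)
            crew = max(1, int(round(base + rng.normal(0.0, scenario.crew_sd))))
            seasonal: tuple[tuple[int, float], ...] = ()
            if rng.random() < scenario.seasonal_rate:
                seasonal = ((1, float(rng.integers(3, 10))),)
            vessels.append(
                Vessel(
                    vessel_id=f"V{vid:04d}",
                    port=port,
                    gear=gear,
                    length_m=round(length, 2),
                    crew_fulltime=crew,
                    seasonal_crew=seasonal,
                    active=True,
                )
            )

    areas = []
    for v in vessels:
        areas.extend(_vessel_areas(v, scenario, scheme, coords, rng))
    logger.info(
        "generated %d vessels at %d ports; census of %d priority areas",
        len(vessels),
        scenario.n_ports,
        len(areas),
    )
    return vessels, ResponseSet(areas, crs=scenario.crs)


def _vessel_areas(
    v: Vessel,
    scenario: SyntheticScenario,
    scheme: CategoryScheme,
    coords: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
) -> list[PriorityArea]:
    """Priority polygons for one vessel's respondent."""
    crng = _combo_rng(scenario, v.port, v.gear)
    # combination core: a seaward bearing and anchor distance shared by all
    # respondents of this port+gear
    bearing = crng.uniform(math.radians(50), math.radians(130))
    rng_m = fishing_range_m(v.gear, v.length_m)
    anchor_d = 0.55 * rng_m
    core_r = max(500.0, 0.30 * rng_m)
    px, py = coords[v.port]

    n_areas = min(scenario.max_areas, 1 + int(rng.poisson(scenario.areas_per_respondent_mean)))
    if scenario.importance_kind == "months":
        raw = rng.dirichlet([scenario.dirichlet_alpha] * n_areas) * 12.0
    else:
        raw = rng.dirichlet([scenario.dirichlet_alpha] * n_areas) * 100.0
    areas = []
    for i in range(n_areas):
        if i == 0:
            jit = scenario.core_jitter * rng_m
            d, r = anchor_d, core_r * rng.uniform(0.85, 1.15)
            ang = bearing
        else:  # secondary grounds: smaller, further scattered
            jit = 0.5 * rng_m
            d, r = anchor_d * rng.uniform(0.6, 1.4), 0.5 * core_r
            ang = bearing + rng.normal(0.0, 0.3)
        cx = px + d * math.cos(ang) + rng.normal(0.0, jit)
        cy = py + abs(d * math.sin(ang) + rng.normal(0.0, jit))
        cy = max(cy, r + 100.0)  # keep the ground at sea (north of the coast)
        geom = Point(cx, cy).buffer(r, quad_segs=16)
        areas.append(
            PriorityArea(
                area_id=f"{v.vessel_id}-A{i + 1}",
                respondent_id=f"R-{v.vessel_id}",
                vessel_id=v.vessel_id,
                fishery=GEAR_FISHERY[v.gear],
                geometry=geom,
                raw_importance=float(raw[i]),
                raw_kind=scenario.importance_kind,
            )
        )
    return areas


def draw_interviews(
    register: Sequence[Vessel],
    scenario: SyntheticScenario,
    seed: int | None = None,
) -> tuple[list[Vessel], pd.DataFrame]:
    """Stratified Bernoulli interview sample; returns flagged register + coverage.

    Inclusion probability is ``interview_p`` with optional per-gear
    overrides.  With ``min_per_category >= 1``, every populated length/gear
    category is guaranteed at least that many interviews (the lowest vessel
    ids are forced in), so the category mean crew is always estimable.
    """
    rng = np.random.default_rng(scenario.seed + 100_003 if seed is None else seed)
    scheme = default_category_scheme()
    out = []
    for v in register:
        p = scenario.interview_p_by_gear.get(v.gear, scenario.interview_p)
        out.append(replace(v, interviewed=bool(v.active and rng.random() < p)))

    if scenario.min_per_category > 0:
        by_cat: dict[str, list[int]] = {}
        for i, v in enumerate(out):
            if v.active:
                by_cat.setdefault(categorize(v, scheme), []).append(i)
        for cat, idxs in sorted(by_cat.items()):
            have = sum(out[i].interviewed for i in idxs)
            need = min(scenario.min_per_category, len(idxs)) - have
            for i in sorted(idxs, key=lambda i: out[i].vessel_id):
                if need <= 0:
                    break
                if not out[i].interviewed:
                    out[i] = replace(out[i], interviewed=True)
                    need -= 1

    cov = (
        pd.DataFrame(
            {
                "gear": [v.gear for v in out if v.active],
                "interviewed": [int(v.interviewed) for v in out if v.active],
            }
        )
        .groupby("gear")
        .agg(n_active=("interviewed", "size"), n_interviewed=("interviewed", "sum"))
        .reset_index()
    )
    cov["percent"] = 100.0 * cov.n_interviewed / cov.n_active
    logger.info(
        "interviewed %d of %d active vessels (%.1f%%)",
        cov.n_interviewed.sum(),
        cov.n_active.sum(),
        100.0 * cov.n_interviewed.sum() / cov.n_active.sum(),
    )
    return out, cov


def write_ports_csv(scenario: SyntheticScenario, path) -> None:
    coords = scenario.port_coords()
    pd.DataFrame(
        {
            "port": list(coords),
            "x": [c[0] for c in coords.values()],
            "y": [c[1] for c in coords.values()],
        }
    ).to_csv(path, index=False)


def read_ports_csv(path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, dtype={"port": str})
    return {r.port: (float(r.x), float(r.y)) for r in df.itertuples()}
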