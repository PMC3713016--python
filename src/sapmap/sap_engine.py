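"""SAP densities, up-scaling weights with fallback, and weighting adaptations.

The spatial access priority (SAP) of an area is ``crew x importance / area``
in SAP per km².  Sample maps are scaled to the whole fleet by multiplying
each respondent's densities by the weight ``W = E/S`` of the vessel's
port-gear-length combination, where E is the estimated crew on all active
vessels of the combination and S the crew actually sampled there.
Combinations that were never sampled donate their E to the most similar
sampled combination (same port and gear, nearest length class; failing that,
the nearest port with that gear), which conserves total estimated crew.
"""

from __future__ import annotations

import logging
import math
from copy import deepcopy
from dataclasses import dataclass
from typing import Mapping, Sequence

from shapely.geometry.base import BaseGeometry

from .errors import ConfigError, UnsampledGearError
from .fleet_registry import (
    ComboKey,
    ComboTable,
    DEFAULT_FISHERY_OF_GEAR,
    Vessel,
    categorize,
    pro_rata_crew,
)
from .survey import PriorityArea, ResponseSet

logger = logging.getLogger(__name__)


def sap_density(area: PriorityArea, crew: float) -> float:
    """SAP per km² of one area: crew x importance / area_km2.

    With crew 1 and the whole year's importance (100) spread over 10 km²
    the density is 10 SAP km⁻² — a tenth of a fisher per square kilometre.
    """
    if area.importance is None:
        raise ConfigError(f"area {area.area_id!r}: importance not normalized")
    if not (area.area_km2 > 0):
        raise ConfigError(f"area {area.area_id!r}: zero area")
    return crew * area.importance / area.area_km2


# ---------------------------------------------------------------------------
# Weights and fallback


def _donor_for(
    key: ComboKey,
    sampled: list[ComboKey],
    table: ComboTable,
    port_coords: Mapping[str, tuple[float, float]] | None,
    port_sequence: Sequence[str] | None,
) -> ComboKey:
    """Pick the sampled combination that represents an unsampled one.

    Preference order: same port and gear with minimal length-class rank
    difference (ties to the smaller class); otherwise the same gear at the
    nearest port (configured coordinates, else position in a configured
    coastal sequence), again nearest length class.
    """
    rank = table.scheme.rank(key.length_class)

    same_pg = [k for k in sampled if k.port == key.port and k.gear == key.gear]
    if same_pg:
        return min(
            same_pg,
            key=lambda k: (abs(table.scheme.rank(k.length_class) - rank),
                           table.scheme.rank(k.length_class)),
        )

    same_gear = [k for k in sampled if k.gear == key.gear]
    if not same_gear:
        raise UnsampledGearError(
            f"gear {key.gear!r} has no interviewed vessels anywhere; "
            "cannot up-scale that gear"
        )

    def port_distance(other: str) -> float:
        if port_coords and key.port in port_coords and other in port_coords:
            (x0, y0), (x1, y1) = port_coords[key.port], port_coords[other]
            return math.hypot(x1 - x0, y1 - y0)
        if port_sequence and key.port in port_sequence and other in port_sequence:
            return abs(port_sequence.index(other) - port_sequence.index(key.port))
        raise ConfigError(
            f"cannot rank port distance {key.port!r} -> {other!r}: provide "
            "port coordinates or a coastal port sequence"
        )

    return min(
        same_gear,
        key=lambda k: (
            port_distance(k.port),
            abs(table.scheme.rank(k.length_class) - rank),
            table.scheme.rank(k.length_class),
            k.port,
        ),
    )


def compute_weights(
    combos: ComboTable,
    port_coords: Mapping[str, tuple[float, float]] | None = None,
    port_sequence: Sequence[str] | None = None,
) -> ComboTable:
    """Fill in up-scaling weights W, reassigning unsampled combinations.

    Sampled combinations start at ``W = E/S``.  Each unsampled combination
    (S = 0, E > 0) is assigned to a donor; the donor's weight becomes
    ``(E_donor + Σ E_assigned) / S_donor``, so the total estimated crew
    represented is conserved: Σ W x S = Σ E.
    """
    table = ComboTable(deepcopy(combos.cells), combos.scheme)
    sampled = sorted(k for k, c in table.cells.items() if c.S > 0)
    if not sampled:
        raise UnsampledGearError("no combination has any interviewed crew")

    assigned_E: dict[ComboKey, float] = {k: 0.0 for k in sampled}
    for key in sorted(table.cells):
        cell = table.cells[key]
        if cell.S > 0 or cell.E <= 0:
            continue
        donor = _donor_for(key, sampled, table, port_coords, port_sequence)
        assigned_E[donor] += cell.E
        table.cells[donor].donor_of.append(key)
        logger.debug("combo %s unsampled; represented by %s", key, donor)

    for key in sampled:
        cell = table.cells[key]
        cell.W = (cell.E + assigned_E[key]) / cell.S
    n_fallback = sum(len(table.cells[k].donor_of) for k in sampled)
    if n_fallback:
        logger.info("%d unsampled combinations reassigned to donors", n_fallback)
    return table


# ---------------------------------------------------------------------------
# Weighted layers


@dataclass
class WeightedLayer:
    """One respondent area with its SAP density and up-scaling weight applied."""

    area_id: str
    respondent_id: str
    vessel_id: str
    fishery: str
    combo: ComboKey
    sap_density: float
    weight: float
    weighted_density: float
    geometry: BaseGeometry

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6


def weight_responses(
    responses: ResponseSet,
    register: Sequence[Vessel],
    combos: ComboTable,
) -> list[WeightedLayer]:
    """Attach each area's combination weight, producing fleet-scaled layers.

    Every area inherits the weight of its vessel's port-gear-length
    combination.  An area whose combination carries no weight (never sampled
    and not a donor) is an error naming the combination.
    """
    vessels = {v.vessel_id: v for v in register}
    layers: list[WeightedLayer] = []
    for a in responses.areas:
        v = vessels.get(a.vessel_id)
        if v is None:
            raise ConfigError(f"area {a.area_id!r}: unknown vessel {a.vessel_id!r}")
        key = ComboKey(v.port, v.gear, categorize(v, combos.scheme))
        cell = combos.cells.get(key)
        if cell is None or cell.W is None:
            raise ConfigError(
                f"area {a.area_id!r}: combination {key} has no computed weight"
            )
        d = sap_density(a, pro_rata_crew(v))
        layers.append(
            WeightedLayer(
                area_id=a.area_id,
                respondent_id=a.respondent_id,
                vessel_id=a.vessel_id,
                fishery=a.fishery,
                combo=key,
                sap_density=d,
                weight=cell.W,
                weighted_density=cell.W * d,
                geometry=a.geometry,
            )
        )
    return layers


def vector_total_sap(layers: Sequence[WeightedLayer]) -> float:
    """Total fleet SAP in vector space: Σ weighted_density x area_km2."""
    return sum(l.weighted_density * l.area_km2 for l in layers)


# ---------------------------------------------------------------------------
# Adaptations


def adapt_processors(
    combos: ComboTable,
    processor_fte_per_fishery: Mapping[str, float],
    fishery_of_gear: Mapping[str, str] | None = None,
) -> ComboTable:
    """Fold shore-side processing jobs into the estimated crew totals.

    Each fishery's processor FTE is split across that fishery's combinations
    in proportion to their share of the fishery's estimated crew E, then
    added to E.  Weights must be recomputed afterwards.  Total E increases by
    exactly the FTE added.
    """
    fishery_of_gear = DEFAULT_FISHERY_OF_GEAR if fishery_of_gear is None else fishery_of_gear
    table = ComboTable(deepcopy(combos.cells), combos.scheme)
    for fishery, fte in processor_fte_per_fishery.items():
        if fte < 0:
            raise ConfigError(f"fishery {fishery!r}: processor FTE must be >= 0")
        if fte == 0:
            continue
        keys = [
            k for k in sorted(table.cells) if fishery_of_gear.get(k.gear) == fishery
        ]
        fishery_E = sum(table.cells[k].E for k in keys)
        if not keys or fishery_E <= 0:
            raise ConfigError(
                f"fishery {fishery!r} has processor FTE {fte} but no combinations"
            )
        for k in keys:
            table.cells[k].E += fte * table.cells[k].E / fishery_E
        for k in keys:  # weights are stale once E moves
            table.cells[k].W = None
    return table


def adapt_landings(
    layers: Sequence[WeightedLayer],
    landed_value_per_fishery: Mapping[str, float],
    fishers_per_fishery: Mapping[str, float],
) -> list[WeightedLayer]:
    """Scale layer weights by landed value per fisher of each fishery.

    Output densities are currency-scaled SAP: each layer's weight (and hence
    weighted density) is multiplied by ``value/fishers`` of its fishery.
    """
    out = []
    for l in layers:
        if l.fishery not in landed_value_per_fishery or l.fishery not in fishers_per_fishery:
            raise ConfigError(
                f"fishery {l.fishery!r}: landed value and fisher count both required"
            )
        value = landed_value_per_fishery[l.fishery]
        fishers = fishers_per_fishery[l.fishery]
        if fishers <= 0:
            raise ConfigError(
                f"fishery {l.fishery!r}: fisher count must be > 0 (got {fishers})"
            )
        factor = value / fishers
        out.append(
            WeightedLayer(
                area_id=l.area_id,
                respondent_id=l.respondent_id,
                vessel_id=l.vessel_id,
                fishery=l.fishery,
                combo=l.combo,
                sap_density=l.sap_density,
                weight=l.weight * factor,
                weighted_density=l.weighted_density * factor,
                geometry=l.geometry,
            )
        )
    return out
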