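"""Fleet register: vessels, pro-rata crew, category scheme and combo table.

The up-scaling strata of the method are *combinations* of home port, gear
type and vessel length class.  This module loads and validates the fleet
register, computes full-time-equivalent (FTE) crew per vessel, assigns each
vessel to a length/gear category, and estimates the total crew fishing from
every port-gear-length combination.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, RegisterError, UnsampledCategoryError

logger = logging.getLogger(__name__)

#: Canonical gear vocabulary.  Mixed registrations are mapped onto a primary
#: gear at ingest via a configurable alias table (see :data:`DEFAULT_GEAR_MAP`).
CANONICAL_GEARS = (
    "pots",
    "nephrops_trawl",
    "whitefish_trawl",
    "dredge",
    "pelagic",
    "gill_net",
    "seine",
    "hand",
    "other",
)

#: Default mapping from raw register labels to the canonical gear vocabulary.
#: Mixed-gear registrations are assigned a primary gear.
DEFAULT_GEAR_MAP: dict[str, str] = {
    "pots": "pots",
    "nephrops trawl": "nephrops_trawl",
    "nephrops_trawl": "nephrops_trawl",
    "whitefish trawl": "whitefish_trawl",
    "whitefish_trawl": "whitefish_trawl",
    "nephrops & whitefish trawl": "nephrops_trawl",
    "dredge": "dredge",
    "scallop dredge": "dredge",
    "dredge & nephrops trawl": "dredge",
    "pots & nephrops trawl": "pots",
    "pots, dredge & nephrops trawl": "pots",
    "pots & dredge": "pots",
    "pelagic": "pelagic",
    "pelagic trawl": "pelagic",
    "gill net": "gill_net",
    "nephrops trawl & gill net": "nephrops_trawl",
    "seine netting": "seine",
    "hand fishing": "hand",
}

#: Default mapping from canonical gear to the fishery its areas target when a
#: response does not carry an explicit fishery tag.
DEFAULT_FISHERY_OF_GEAR: dict[str, str] = {
    "nephrops_trawl": "nephrops",
    "pots": "pots",
    "dredge": "scallops",
    "whitefish_trawl": "whitefish",
    "pelagic": "other",
    "gill_net": "other",
    "seine": "other",
    "hand": "other",
    "other": "other",
}


def normalize_gear(raw: str, gear_map: Mapping[str, str] | None = None) -> str:
    """Map a raw register gear label onto the canonical vocabulary."""
    gear_map = DEFAULT_GEAR_MAP if gear_map is None else gear_map
    key = raw.strip().lower()
    if key in gear_map:
        return gear_map[key]
    if key in CANONICAL_GEARS:
        return key
    raise RegisterError(f"unknown gear label {raw!r}; extend the gear map")


# ---------------------------------------------------------------------------
# Vessels


@dataclass(frozen=True)
class Vessel:
    """One register entry.

    ``seasonal_crew`` holds ``(headcount, months_per_year)`` pairs; each
    seasonal member counts as ``months/12`` of a full-time member.
    """

    vessel_id: str
    port: str
    gear: str
    length_m: float
    crew_fulltime: int = 0
    seasonal_crew: tuple[tuple[int, float], ...] = ()
    active: bool = True
    interviewed: bool = False

    def __post_init__(self) -> None:
        if not self.vessel_id:
            raise RegisterError("vessel_id must be non-empty")
        if not (self.length_m > 0):
            raise RegisterError(
                f"vessel {self.vessel_id}: length_m must be > 0, got {self.length_m}"
            )
        if self.crew_fulltime < 0:
            raise RegisterError(
                f"vessel {self.vessel_id}: crew_fulltime must be >= 0"
            )
        for head, months in self.seasonal_crew:
            if head < 1:
                raise RegisterError(
                    f"vessel {self.vessel_id}: seasonal headcount must be >= 1"
                )
            if not (0 < months <= 12):
                raise RegisterError(
                    f"vessel {self.vessel_id}: months_per_year must be in (0, 12], "
                    f"got {months}"
                )


def pro_rata_crew(vessel: Vessel) -> float:
    """Full-time-equivalent crew of a vessel.

    Seasonal members are counted pro rata as ``months/12`` of a full-time
    member, so a boat with four year-round crew plus one extra member for six
    months carries 4.5 crew.  Additive over entries and order-invariant.
    """
    return vessel.crew_fulltime + sum(
        head * months / 12.0 for head, months in vessel.seasonal_crew
    )


# ---------------------------------------------------------------------------
# Category scheme


@dataclass(frozen=True)
class Category:
    """Half-open length interval ``[lo, hi)`` with an optional gear predicate.

    ``gear_in`` restricts the category to those gears; ``gear_not_in``
    excludes gears.  ``rank`` orders categories for nearest-class fallback.
    """

    category_id: str
    lo: float = 0.0
    hi: float = math.inf
    gear_in: tuple[str, ...] | None = None
    gear_not_in: tuple[str, ...] | None = None

    def matches(self, gear: str, length_m: float) -> bool:
        if self.gear_in is not None and gear not in self.gear_in:
            return False
        if self.gear_not_in is not None and gear in self.gear_not_in:
            return False
        return self.lo <= length_m < self.hi


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered categories; every (gear, length) pair maps to exactly one."""

    categories: tuple[Category, ...]

    def __post_init__(self) -> None:
        ids = [c.category_id for c in self.categories]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate category ids in scheme")

    def ids(self) -> list[str]:
        return [c.category_id for c in self.categories]

    def rank(self, category_id: str) -> int:
        """Ordinal position of a category, used for nearest-class fallback."""
        for i, c in enumerate(self.categories):
            if c.category_id == category_id:
                return i
        raise ConfigError(f"unknown category id {category_id!r}")


def default_category_scheme() -> CategoryScheme:
    """The eight-category default.

    Seven length bins with the 9-<10 m bin split by gear (pot boats of that
    size carry fewer crew than trawlers or dredgers), the two largest bins
    merged into a single >=20 m class, and pelagic vessels — whose crews of
    8-10 dwarf every other type — as their own class at any length.
    """
    return CategoryScheme(
        (
            Category("pelagic", gear_in=("pelagic",)),
            Category("<7", 0.0, 7.0, gear_not_in=("pelagic",)),
            Category("7-<9", 7.0, 9.0, gear_not_in=("pelagic",)),
            Category("9-<10 pots", 9.0, 10.0, gear_in=("pots",)),
            Category("9-<10 non-pots", 9.0, 10.0, gear_not_in=("pots", "pelagic")),
            Category("10-<15", 10.0, 15.0, gear_not_in=("pelagic",)),
            Category("15-<20", 15.0, 20.0, gear_not_in=("pelagic",)),
            Category(">=20", 20.0, math.inf, gear_not_in=("pelagic",)),
        )
    )


def categorize(vessel: Vessel, scheme: CategoryScheme) -> str:
    """Assign a vessel to its (unique) category.

    Raises :class:`ConfigError` naming the gap if the scheme does not cover
    the vessel's (gear, length) pair.
    """
    matches = [
        c.category_id for c in scheme.categories if c.matches(vessel.gear, vessel.length_m)
    ]
    if not matches:
        raise ConfigError(
            f"category scheme does not cover gear={vessel.gear!r} "
            f"length={vessel.length_m} m (vessel {vessel.vessel_id})"
        )
    if len(matches) > 1:
        raise ConfigError(
            f"category scheme is ambiguous for gear={vessel.gear!r} "
            f"length={vessel.length_m} m: {matches}"
        )
    return matches[0]


def category_mean_crew(
    vessels: Iterable[Vessel], scheme: CategoryScheme
) -> dict[str, float]:
    """Mean pro-rata crew per category, from interviewed vessels only."""
    crews: dict[str, list[float]] = {}
    for v in vessels:
        if not v.interviewed:
            continue
        crews.setdefault(categorize(v, scheme), []).append(pro_rata_crew(v))
    return {cat: sum(c) / len(c) for cat, c in crews.items()}


# ---------------------------------------------------------------------------
# Combo table


@dataclass(frozen=True, order=True)
class ComboKey:
    """A port x gear x length-class stratum."""

    port: str
    gear: str
    length_class: str


@dataclass
class ComboCell:
    """Per-combination census and sample totals.

    E is the estimated crew FTE on all active vessels of the combination
    (register count times the category's sample mean crew); S is the crew FTE
    actually interviewed there; W = E/S is the up-scaling weight, adjusted by
    donor fallback when some combinations were never sampled.
    """

    n_vessels: int
    mean_crew: float
    E: float
    S: float
    W: float | None = None
    donor_of: list[ComboKey] = field(default_factory=list)


@dataclass
class ComboTable:
    cells: dict[ComboKey, ComboCell]
    scheme: CategoryScheme

    def total_E(self) -> float:
        return sum(c.E for c in self.cells.values())

    def total_S(self) -> float:
        return sum(c.S for c in self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        """Audit table of the weighting scheme, one row per combination."""
        rows = []
        for key in sorted(self.cells):
            c = self.cells[key]
            rows.append(
                {
                    "port": key.port,
                    "gear": key.gear,
                    "length_class": key.length_class,
                    "n_vessels": c.n_vessels,
                    "mean_crew": c.mean_crew,
                    "E": c.E,
                    "S": c.S,
                    "W": c.W,
                    "donor_of": ";".join(
                        f"{k.port}|{k.gear}|{k.length_class}" for k in c.donor_of
                    ),
                }
            )
        return pd.DataFrame(rows)


def build_combo_table(
    register: Sequence[Vessel],
    scheme: CategoryScheme,
    mean_crew: Mapping[str, float] | None = None,
) -> ComboTable:
    """Estimate total crew per port-gear-length combination.

    ``E = n_vessels x mean_crew(category)`` uses the category-level sample
    mean (interview data); ``S`` sums the pro-rata crew of interviewed vessels
    in the combination.  Only active vessels enter the table.

    Raises :class:`UnsampledCategoryError` listing every category that has
    active vessels but no interviewed vessel to estimate mean crew from.
    """
    if mean_crew is None:
        mean_crew = category_mean_crew(register, scheme)

    cells: dict[ComboKey, ComboCell] = {}
    missing: set[str] = set()
    for v in register:
        if not v.active:
            continue
        cat = categorize(v, scheme)
        if cat not in mean_crew:
            missing.add(cat)
            continue
        key = ComboKey(v.port, v.gear, cat)
        cell = cells.get(key)
        if cell is None:
            cell = cells[key] = ComboCell(0, mean_crew[cat], 0.0, 0.0)
        cell.n_vessels += 1
        cell.E = cell.n_vessels * cell.mean_crew
        if v.interviewed:
            cell.S += pro_rata_crew(v)
    if missing:
        raise UnsampledCategoryError(
            "no interviewed vessels in categories: " + ", ".join(sorted(missing))
        )
    return ComboTable(cells, scheme)


# ---------------------------------------------------------------------------
# Register IO

REGISTER_COLUMNS = [
    "vessel_id",
    "port",
    "gear",
    "length_m",
    "crew_fulltime",
    "seasonal_crew",
    "active",
    "interviewed",
]


def _parse_seasonal(text: str) -> tuple[tuple[int, float], ...]:
    """Parse the ``"headcount:months;headcount:months"`` encoding."""
    text = (text or "").strip()
    if not text:
        return ()
    entries = []
    for chunk in text.split(";"):
        head_s, _, months_s = chunk.partition(":")
        try:
            entries.append((int(head_s), float(months_s)))
        except ValueError as exc:
            raise RegisterError(f"bad seasonal_crew entry {chunk!r}") from exc
    return tuple(entries)


def _encode_seasonal(entries: Iterable[tuple[int, float]]) -> str:
    return ";".join(f"{h}:{m:g}" for h, m in entries)


def read_register(
    path, gear_map: Mapping[str, str] | None = None
) -> list[Vessel]:
    """Load a fleet register CSV and validate every row.

    Expected columns: vessel_id, port, gear, length_m, crew_fulltime,
    seasonal_crew (``"headcount:months;..."``, may be empty), active (0/1)
    and optionally interviewed (0/1).  Gear labels are normalized onto the
    canonical vocabulary.  Errors name the offending row.
    """
    df = pd.read_csv(path, dtype={"vessel_id": str, "seasonal_crew": str}, keep_default_na=False)
    required = set(REGISTER_COLUMNS) - {"interviewed", "seasonal_crew"}
    missing = required - set(df.columns)
    if missing:
        raise RegisterError(f"register missing columns: {sorted(missing)}")
    vessels = []
    for idx, row in df.iterrows():
        try:
            vessels.append(
                Vessel(
                    vessel_id=str(row["vessel_id"]),
                    port=str(row["port"]),
                    gear=normalize_gear(str(row["gear"]), gear_map),
                    length_m=float(row["length_m"]),
                    crew_fulltime=int(row["crew_fulltime"]),
                    seasonal_crew=_parse_seasonal(str(row.get("seasonal_crew", ""))),
                    active=bool(int(row["active"])),
                    interviewed=bool(int(row["interviewed"]))
                    if "interviewed" in df.columns
                    else False,
                )
            )
        except (RegisterError, ValueError) as exc:
            raise RegisterError(f"register row {idx} (vessel_id={row['vessel_id']!r}): {exc}") from exc
    ids = [v.vessel_id for v in vessels]
    if len(set(ids)) != len(ids):
        raise RegisterError("duplicate vessel_id values in register")
    logger.info("read register: %d vessels (%d active)", len(vessels), sum(v.active for v in vessels))
    return vessels


def write_register(register: Sequence[Vessel], path) -> None:
    """Write a register back to the CSV schema ``read_register`` consumes."""
    df = pd.DataFrame(
        {
            "vessel_id": [v.vessel_id for v in register],
            "port": [v.port for v in register],
            "gear": [v.gear for v in register],
            "length_m": [v.length_m for v in register],
            "crew_fulltime": [v.crew_fulltime for v in register],
            "seasonal_crew": [_encode_seasonal(v.seasonal_crew) for v in register],
            "active": [int(v.active) for v in register],
            "interviewed": [int(v.interviewed) for v in register],
        }
    )
    df.to_csv(path, index=False)


def mark_interviewed(
    register: Sequence[Vessel], vessel_ids: Iterable[str]
) -> list[Vessel]:
    """Return a copy of the register with the given vessels flagged interviewed."""
    wanted = set(vessel_ids)
    unknown = wanted - {v.vessel_id for v in register}
    if unknown:
        raise RegisterError(f"unknown vessel ids: {sorted(unknown)}")
    return [
        replace(v, interviewed=True) if v.vessel_id in wanted else v
        for v in register
    ]
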