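"""Survey responses: priority polygons and importance normalization.

Respondents draw polygons over the sea and attach either the fraction of the
year spent in each area (months) or unitless rank weights.  Both are coerced
onto a percent scale and renormalized so that every respondent-vessel's
importances sum to exactly 100 — the convention under which each full-time
fisher carries a total spatial access priority (SAP) of 100.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import CRSError, GeometryError, RegisterError
from .fleet_registry import Vessel

logger = logging.getLogger(__name__)

_GEOGRAPHIC_TOKENS = ("4326", "crs84", "longlat")


@dataclass
class PriorityArea:
    """One polygon a respondent drew, with its normalized importance.

    ``raw_importance`` is either months-of-year in (0, 12] (``raw_kind ==
    "months"``) or a positive rank weight (``raw_kind == "rank"``).
    ``importance`` is the percent of the fisher's total priority assigned to
    this area, populated by :func:`normalize_importance`.
    """

    area_id: str
    respondent_id: str
    vessel_id: str
    fishery: str
    geometry: BaseGeometry
    raw_importance: float | None = None
    raw_kind: str | None = None
    importance: float | None = None

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6


@dataclass
class ResponseSet:
    """All priority areas of a survey, grouped by (respondent, vessel)."""

    areas: list[PriorityArea]
    crs: str = "EPSG:3035"

    def groups(self) -> dict[tuple[str, str], list[PriorityArea]]:
        out: dict[tuple[str, str], list[PriorityArea]] = {}
        for a in self.areas:
            out.setdefault((a.respondent_id, a.vessel_id), []).append(a)
        return out

    def vessel_ids(self) -> set[str]:
        return {a.vessel_id for a in self.areas}


def _repair(geom: BaseGeometry, area_id: str) -> BaseGeometry:
    """Zero-buffer repair; reject geometries that stay invalid or empty."""
    if not geom.is_valid:
        geom = geom.buffer(0)
    if not geom.is_valid:
        raise GeometryError(f"area {area_id!r}: geometry invalid after repair")
    if geom.is_empty or geom.area <= 0:
        raise GeometryError(f"area {area_id!r}: zero-area geometry rejected")
    return geom


def _check_crs(crs_name: str) -> None:
    low = crs_name.lower()
    if any(tok in low for tok in _GEOGRAPHIC_TOKENS):
        raise CRSError(
            f"CRS {crs_name!r} is geographic (degrees); reproject responses to a "
            "projected equal-area CRS in metres before loading"
        )


def read_responses(path, register: Sequence[Vessel] | None = None) -> ResponseSet:
    """Read priority polygons from a GeoJSON FeatureCollection.

    The file must carry a named ``crs`` member with a projected (metre)
    authority code; geographic CRSs are refused with instructions to
    reproject.  Geometries are zero-buffer repaired and zero-area polygons
    rejected by area id.  When a register is given, every ``vessel_id`` must
    resolve to an active register vessel; offenders are listed.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    crs_name = (
        doc.get("crs", {}).get("properties", {}).get("name")
        if isinstance(doc.get("crs"), dict)
        else None
    )
    if not crs_name:
        raise CRSError(
            f"{path}: no CRS authority code; responses must declare a projected "
            "equal-area CRS in metres"
        )
    _check_crs(crs_name)

    areas: list[PriorityArea] = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        area_id = str(props.get("area_id"))
        geom = _repair(shape(feat["geometry"]), area_id)
        raw = props.get("raw_importance")
        areas.append(
            PriorityArea(
                area_id=area_id,
                respondent_id=str(props.get("respondent_id")),
                vessel_id=str(props.get("vessel_id")),
                fishery=str(props.get("fishery", "other")),
                geometry=geom,
                raw_importance=float(raw) if raw is not None else None,
                raw_kind=props.get("raw_kind"),
            )
        )

    if register is not None:
        known = {v.vessel_id: v for v in register}
        bad = sorted(
            {
                a.vessel_id
                for a in areas
                if a.vessel_id not in known or not known[a.vessel_id].active
            }
        )
        if bad:
            raise RegisterError(
                f"responses reference unknown or inactive vessels: {bad}"
            )
    logger.info("read %d priority areas from %s", len(areas), path)
    return ResponseSet(areas, crs=crs_name)


def write_responses(responses: ResponseSet, path) -> None:
    """Write a ResponseSet as GeoJSON, mirroring :func:`read_responses`."""
    features = []
    for a in responses.areas:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(a.geometry),
                "properties": {
                    "area_id": a.area_id,
                    "respondent_id": a.respondent_id,
                    "vessel_id": a.vessel_id,
                    "fishery": a.fishery,
                    "raw_importance": a.raw_importance,
                    "raw_kind": a.raw_kind,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": responses.crs}},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def normalize_importance(areas: Sequence[PriorityArea]) -> None:
    """Normalize one respondent-vessel's raw importances to sum to 100.

    Months-of-year become ``months/12 x 100`` and are then rescaled so the
    respondent's importances sum to exactly 100 (handling stated months that
    do not fill the year); rank weights are scaled proportionally; a single
    area with no raw value gets 100.  Mixing months and ranks within one
    respondent is an error.  Idempotent: importances are recomputed from the
    raw values on every call.
    """
    if not areas:
        return
    kinds = {a.raw_kind for a in areas if a.raw_importance is not None}
    if len(kinds) > 1:
        raise GeometryError(
            f"respondent {areas[0].respondent_id!r}: mixed raw-importance kinds {sorted(kinds)}"
        )
    raws = [a.raw_importance for a in areas]
    if any(r is None for r in raws):
        if len(areas) == 1:
            areas[0].importance = 100.0
            return
        raise GeometryError(
            f"respondent {areas[0].respondent_id!r}: missing raw importance on "
            "some of several areas"
        )
    kind = kinds.pop() if kinds else "rank"
    if kind == "months":
        for a in areas:
            if not (0 < a.raw_importance <= 12):
                raise GeometryError(
                    f"area {a.area_id!r}: months must be in (0, 12], got {a.raw_importance}"
                )
    else:
        for a in areas:
            if not (a.raw_importance > 0):
                raise GeometryError(
                    f"area {a.area_id!r}: rank weight must be > 0, got {a.raw_importance}"
                )
    total = sum(raws)
    if total != 12.0 and kind == "months":
        logger.info(
            "respondent %s: stated months sum to %.3g, renormalizing to a full year",
            areas[0].respondent_id,
            total,
        )
    for a in areas:
        a.importance = a.raw_importance / total * 100.0


def normalize_responses(responses: ResponseSet) -> ResponseSet:
    """Apply :func:`normalize_importance` to every respondent-vessel group."""
    for group in responses.groups().values():
        normalize_importance(group)
    return responses


def subset_to_interviewed(
    responses: ResponseSet, register: Sequence[Vessel]
) -> ResponseSet:
    """Keep only areas whose vessel is flagged interviewed in the register."""
    interviewed = {v.vessel_id for v in register if v.interviewed}
    return ResponseSet(
        [a for a in responses.areas if a.vessel_id in interviewed],
        crs=responses.crs,
    )
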