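"""Equal-area gridding of weighted priority layers.

Layers are rasterized onto an axis-aligned 1 km² grid in the projected CRS.
The default ``exact_area`` mode adds ``weighted_density x (polygon-cell
intersection area / cell area)`` to each cell, which conserves total SAP to
float precision regardless of grid origin; ``cell_center`` mode mimics a
plain GIS rasterizer (a cell gets the full density if its centre falls
inside the polygon) and is provided for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ConfigError, GeometryError, GridExtentError, GridMismatchError
from .sap_engine import WeightedLayer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned grid: cells are half-open ``[x, x+cs) x [y, y+cs)``.

    ``(x0, y0)`` is the lower-left corner in CRS metres; rows of the value
    array run north to south (row 0 is the top row), matching the ESRI ASCII
    grid convention.
    """

    x0: float
    y0: float
    nx: int
    ny: int
    cell_size: float = 1000.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.nx < 1 or self.ny < 1:
            raise ConfigError("grid needs positive cell size and dimensions")

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    @classmethod
    def from_bounds(
        cls,
        bounds: tuple[float, float, float, float],
        cell_size: float = 1000.0,
        snap: bool = True,
    ) -> "GridSpec":
        """Smallest grid covering ``bounds``; origin snapped to the cell lattice."""
        minx, miny, maxx, maxy = bounds
        if snap:
            x0 = np.floor(minx / cell_size) * cell_size
            y0 = np.floor(miny / cell_size) * cell_size
        else:
            x0, y0 = minx, miny
        nx = max(1, int(np.ceil((maxx - x0) / cell_size)))
        ny = max(1, int(np.ceil((maxy - y0) / cell_size)))
        return cls(float(x0), float(y0), nx, ny, cell_size)


def grid_for_layers(
    layers: Sequence[WeightedLayer], cell_size: float = 1000.0, pad_cells: int = 1
) -> GridSpec:
    """Grid covering the union bounds of all layers, padded by whole cells."""
    if not layers:
        raise ConfigError("cannot derive a grid from zero layers")
    b = np.array([l.geometry.bounds for l in layers])
    pad = pad_cells * cell_size
    return GridSpec.from_bounds(
        (b[:, 0].min() - pad, b[:, 1].min() - pad, b[:, 2].max() + pad, b[:, 3].max() + pad),
        cell_size,
    )


@dataclass
class PriorityRaster:
    """SAP km⁻² per cell.  ``touched`` distinguishes true zeros from no-data."""

    grid: GridSpec
    values: np.ndarray
    touched: np.ndarray
    tags: frozenset = frozenset()

    def total_sap(self) -> float:
        """Integrated SAP mass: Σ values x cell area (km²)."""
        return float(self.values.sum() * self.grid.cell_area_km2)

    def copy(self) -> "PriorityRaster":
        return PriorityRaster(self.grid, self.values.copy(), self.touched.copy(), self.tags)


def empty_raster(grid: GridSpec, tags: Iterable = ()) -> PriorityRaster:
    return PriorityRaster(
        grid,
        np.zeros((grid.ny, grid.nx)),
        np.zeros((grid.ny, grid.nx), dtype=bool),
        frozenset(tags),
    )


# ---------------------------------------------------------------------------
# Rasterization


def _cell_window(geom: BaseGeometry, grid: GridSpec) -> tuple[int, int, int, int]:
    minx, miny, maxx, maxy = geom.bounds
    gx0, gy0, gx1, gy1 = grid.bounds
    if minx < gx0 or miny < gy0 or maxx > gx1 or maxy > gy1:
        raise GridExtentError(
            f"polygon bounds {geom.bounds} exceed grid extent {grid.bounds}; "
            f"extend the grid to cover ({minx:.0f}, {miny:.0f}, {maxx:.0f}, {maxy:.0f})"
        )
    cs = grid.cell_size
    i0 = int(np.floor((minx - gx0) / cs))
    j0 = int(np.floor((miny - gy0) / cs))
    i1 = min(int(np.floor((maxx - gx0) / cs)), grid.nx - 1)
    j1 = min(int(np.floor((maxy - gy0) / cs)), grid.ny - 1)
    return i0, j0, i1, j1


def rasterize_layer(
    layer: WeightedLayer,
    grid: GridSpec,
    mode: str = "exact_area",
    out: PriorityRaster | None = None,
) -> PriorityRaster:
    """Burn one weighted layer onto the grid.

    ``exact_area``: each cell receives the layer's weighted density times the
    fraction of the cell covered by the polygon, so the raster total equals
    the vector total exactly.  ``cell_center``: a cell receives the full
    density when its centre lies inside the polygon.
    """
    if mode not in ("exact_area", "cell_center"):
        raise ConfigError(f"unknown rasterization mode {mode!r}")
    raster = out if out is not None else empty_raster(grid)
    geom = layer.geometry
    i0, j0, i1, j1 = _cell_window(geom, grid)
    cs = grid.cell_size
    xs = grid.x0 + np.arange(i0, i1 + 1) * cs
    ys = grid.y0 + np.arange(j0, j1 + 1) * cs
    XX, YY = np.meshgrid(xs, ys)

    if mode == "exact_area":
        boxes = shapely.box(XX.ravel(), YY.ravel(), XX.ravel() + cs, YY.ravel() + cs)
        frac = shapely.area(shapely.intersection(boxes, geom)) / (cs * cs)
        frac = frac.reshape(XX.shape)
        contrib = layer.weighted_density * frac
        hit = frac > 0
    else:
        inside = shapely.contains_xy(geom, XX.ravel() + cs / 2, YY.ravel() + cs / 2)
        inside = inside.reshape(XX.shape)
        contrib = layer.weighted_density * inside
        hit = inside

    # rows run north->south: grid row index = ny - 1 - j
    rows = grid.ny - 1 - np.arange(j0, j1 + 1)
    raster.values[rows[:, None], np.arange(i0, i1 + 1)[None, :]] += contrib
    raster.touched[rows[:, None], np.arange(i0, i1 + 1)[None, :]] |= hit
    return raster


def rasterize_layers(
    layers: Sequence[WeightedLayer],
    grid: GridSpec,
    mode: str = "exact_area",
    tags: Iterable = (),
) -> PriorityRaster:
    """Rasterize and sum many layers onto one grid."""
    raster = empty_raster(grid, tags)
    for layer in layers:
        rasterize_layer(layer, grid, mode=mode, out=raster)
    return raster


def combine(rasters: Sequence[PriorityRaster]) -> PriorityRaster:
    """Cell-wise sum of rasters on identical grids (the raster-calculator step)."""
    if not rasters:
        raise ConfigError("combine requires at least one raster")
    grid = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != grid:
            raise GridMismatchError(
                f"grid mismatch: {r.grid} vs {grid}; no silent resampling"
            )
    out = empty_raster(grid, frozenset().union(*(r.tags for r in rasters)))
    for r in rasters:
        out.values += r.values
        out.touched |= r.touched
    return out


def subset_map(
    layers: Sequence[WeightedLayer],
    grid: GridSpec,
    predicate: Callable[[WeightedLayer], bool],
    mode: str = "exact_area",
    tags: Iterable = (),
) -> PriorityRaster:
    """Map for one sector: rasterize only the layers matching the predicate."""
    selected = [l for l in layers if predicate(l)]
    if not selected:
        warnings.warn("subset predicate matched no layers; returning zero raster")
        return empty_raster(grid, tags)
    return rasterize_layers(selected, grid, mode=mode, tags=tags)


def relative_priority(raster: PriorityRaster, total_sap: float) -> PriorityRaster:
    """Divide by a group's total SAP; with the raster's own total the result
    integrates to 1 over the map."""
    if not (total_sap > 0):
        raise ConfigError(f"total SAP must be > 0, got {total_sap}")
    out = raster.copy()
    out.values = out.values / total_sap
    return out


# ---------------------------------------------------------------------------
# Closure impact


@dataclass
class ClosureImpact:
    """Fraction of one group's SAP that falls inside a closure."""

    group: str
    sap_inside: float
    sap_total: float

    @property
    def fraction(self) -> float:
        return self.sap_inside / self.sap_total if self.sap_total > 0 else 0.0


def closure_impact(
    layers: Sequence[WeightedLayer],
    closures: Sequence[BaseGeometry] | BaseGeometry,
    group_of: Callable[[WeightedLayer], str] = lambda l: "fleet",
) -> list[ClosureImpact]:
    """Per-group fraction of total SAP inside the closure, vector-exact.

    ``group_of`` keys layers into groups (whole fleet, fishery, combination,
    ...).  Monotone: enlarging the closure never decreases any fraction.
    """
    if isinstance(closures, BaseGeometry):
        closures = [closures]
    for c in closures:
        if not c.is_valid:
            raise GeometryError("invalid closure geometry")
    closure = unary_union(list(closures)) if closures else None

    totals: dict[str, float] = {}
    inside: dict[str, float] = {}
    for l in layers:
        g = group_of(l)
        mass = l.weighted_density * l.area_km2
        totals[g] = totals.get(g, 0.0) + mass
        if closure is not None and not closure.is_empty:
            cut = l.geometry.intersection(closure).area / 1e6
            inside[g] = inside.get(g, 0.0) + l.weighted_density * cut
        else:
            inside.setdefault(g, 0.0)
    return [
        ClosureImpact(g, inside.get(g, 0.0), totals[g]) for g in sorted(totals)
    ]


# ---------------------------------------------------------------------------
# Raster IO (ESRI ASCII grid)


def write_ascii_grid(raster: PriorityRaster, path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid; never-touched cells become no-data."""
    vals = np.where(raster.touched, raster.values, nodata)
    header = (
        f"ncols {raster.grid.nx}\n"
        f"nrows {raster.grid.ny}\n"
        f"xllcorner {raster.grid.x0:.6f}\n"
        f"yllcorner {raster.grid.y0:.6f}\n"
        f"cellsize {raster.grid.cell_size:.6f}\n"
        f"NODATA_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> PriorityRaster:
    """Read an ESRI ASCII grid (e.g. an external effort raster)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or parts[0][0].isdigit() or parts[0][0] == "-":
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(fh, ndmin=2)
    try:
        grid = GridSpec(
            header["xllcorner"],
            header["yllcorner"],
            int(header["ncols"]),
            int(header["nrows"]),
            header["cellsize"],
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing ASCII grid header field {exc}") from exc
    nodata = header.get("nodata_value", -9999.0)
    touched = data != nodata
    values = np.where(touched, data, 0.0)
    return PriorityRaster(grid, values, touched)
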