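"""Sample representativeness, response consistency, and effort congruency.

Up-scaling a ~50% interview sample to the whole fleet is only defensible if
the sample looks like the fleet (length, port and gear distributions), if
responses within a port-gear-length combination agree spatially, and if the
resulting maps cover everywhere an independent effort source says fishing
happens.  This module quantifies all three.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.ops import unary_union

from .errors import ConfigError, GridMismatchError
from .fleet_registry import CategoryScheme, ComboKey, Vessel, categorize, pro_rata_crew
from .gridding import PriorityRaster
from .survey import ResponseSet

logger = logging.getLogger(__name__)


def coverage_percent(n_sub: float, n_total: float, ndigits: int = 1) -> float:
    """Percentage of a stratum covered by the sample, rounded for reporting."""
    if n_total <= 0:
        raise ConfigError("coverage denominator must be > 0")
    return round(100.0 * n_sub / n_total, ndigits)


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided two-sample t-test with pooled variance; df = n1 + n2 - 2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), len(x) + len(y) - 2, float(p)


def chi_squared_gof(
    sample_counts: Sequence[float], population_counts: Sequence[float]
) -> tuple[float, int, float]:
    """Goodness-of-fit of sample stratum frequencies to population shares.

    Expected counts are the population proportions scaled to the sample
    size; df = k - 1; no continuity correction.  Invariant to stratum order.
    """
    obs = np.asarray(sample_counts, float)
    pop = np.asarray(population_counts, float)
    if len(obs) != len(pop) or len(obs) < 2:
        raise ConfigError("need matching counts over >= 2 strata")
    if (pop <= 0).any():
        raise ConfigError(
            "population stratum with zero count after grouping; use a coarser grouping"
        )
    exp = pop / pop.sum() * obs.sum()
    if (exp <= 0).any():
        raise ConfigError("expected count of zero; use a coarser grouping")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _group_ports(
    port: str, port_grouping: Mapping[str, str] | None
) -> str:
    if port_grouping is None:
        return port
    return port_grouping.get(port, port)


@dataclass
class RepresentativenessReport:
    length_test: tuple[float, int, float]
    port_test: tuple[float, int, float]
    gear_test: tuple[float, int, float]
    coverage: pd.DataFrame  # stratum kind, stratum, active n, interviewed n, percent

    def to_text(self) -> str:
        t, df, p = self.length_test
        lines = [
            f"length t-test: t = {t:.3f}, df = {df}, p = {p:.3f}",
            "port chi-squared: X2 = {0:.3f}, df = {1}, p = {2:.3f}".format(*self.port_test),
            "gear chi-squared: X2 = {0:.3f}, df = {1}, p = {2:.3f}".format(*self.gear_test),
            "",
            self.coverage.to_string(index=False),
        ]
        return "\n".join(lines)


def representativeness(
    register: Sequence[Vessel],
    port_grouping: Mapping[str, str] | None = None,
) -> RepresentativenessReport:
    """Compare the interviewed sample with the whole active fleet.

    Vessel lengths: pooled two-sided t-test, sample vs population.  Port and
    gear frequencies: chi-squared goodness-of-fit of sample counts against
    population proportions, with small ports merged per ``port_grouping``
    (raw port -> group label) so no expected count is zero.
    """
    active = [v for v in register if v.active]
    sample = [v for v in active if v.interviewed]
    if len(sample) < 2:
        raise ConfigError("need at least 2 interviewed active vessels")

    length_test = pooled_t_test([v.length_m for v in sample], [v.length_m for v in active])

    def counts(key):
        pop = pd.Series([key(v) for v in active]).value_counts().sort_index()
        sam = pd.Series([key(v) for v in sample]).value_counts()
        sam = sam.reindex(pop.index, fill_value=0)
        return sam.to_numpy(float), pop.to_numpy(float), pop.index

    sam_p, pop_p, _ = counts(lambda v: _group_ports(v.port, port_grouping))
    port_test = chi_squared_gof(sam_p, pop_p)
    sam_g, pop_g, _ = counts(lambda v: v.gear)
    gear_test = chi_squared_gof(sam_g, pop_g)

    rows = []
    for kind, key in (("port", lambda v: _group_ports(v.port, port_grouping)),
                      ("gear", lambda v: v.gear)):
        sam, pop, index = counts(key)
        for stratum, n_pop, n_sam in zip(index, pop, sam):
            rows.append(
                {
                    "stratum_kind": kind,
                    "stratum": stratum,
                    "n_active": int(n_pop),
                    "n_interviewed": int(n_sam),
                    "percent": coverage_percent(n_sam, n_pop),
                }
            )
    coverage = pd.DataFrame(rows)
    return RepresentativenessReport(length_test, port_test, gear_test, coverage)


def crew_gear_difference(
    vessels: Sequence[Vessel],
    length_window: tuple[float, float] = (9.0, 10.0),
    gear: str = "pots",
) -> tuple[float, int, float]:
    """Pooled t-test of pro-rata crew: one gear vs the rest, in a length window.

    Used to justify splitting a length class by gear (pot boats of 9-10 m
    carry fewer crew than trawlers or dredgers of the same size).
    """
    lo, hi = length_window
    window = [v for v in vessels if v.interviewed and lo <= v.length_m < hi]
    a = [pro_rata_crew(v) for v in window if v.gear == gear]
    b = [pro_rata_crew(v) for v in window if v.gear != gear]
    if len(a) < 2 or len(b) < 2:
        raise ConfigError(
            f"need >= 2 vessels per group in [{lo}, {hi}) m; got {len(a)} {gear}, {len(b)} other"
        )
    return pooled_t_test(a, b)


# ---------------------------------------------------------------------------
# Within-combination spatial consistency


def jaccard(geom_a, geom_b) -> float:
    """Area Jaccard index |A∩B| / |A∪B| of two footprints."""
    union = geom_a.union(geom_b).area
    if union <= 0:
        return 0.0
    return geom_a.intersection(geom_b).area / union


@dataclass
class OverlapReport:
    table: pd.DataFrame  # port, gear, length_class, n_respondents, mean_jaccard, ...

    def mean_jaccard(self, key: ComboKey) -> float:
        t = self.table
        row = t[
            (t.port == key.port) & (t.gear == key.gear) & (t.length_class == key.length_class)
        ]
        if row.empty:
            raise KeyError(key)
        return float(row.mean_jaccard.iloc[0])


def within_combo_overlap(
    responses: ResponseSet,
    register: Sequence[Vessel],
    scheme: CategoryScheme,
) -> OverlapReport:
    """Mean pairwise Jaccard of respondents' union footprints per combination.

    High overlap within a combination supports up-scaling that combination's
    responses to its uninterviewed vessels; combinations with a single
    respondent are skipped with a note.
    """
    vessels = {v.vessel_id: v for v in register}
    footprints: dict[ComboKey, dict[str, list]] = {}
    for a in responses.areas:
        v = vessels.get(a.vessel_id)
        if v is None:
            raise ConfigError(f"area {a.area_id!r}: unknown vessel {a.vessel_id!r}")
        key = ComboKey(v.port, v.gear, categorize(v, scheme))
        footprints.setdefault(key, {}).setdefault(a.respondent_id, []).append(a.geometry)

    rows = []
    for key in sorted(footprints):
        per_resp = {r: unary_union(gs) for r, gs in footprints[key].items()}
        n = len(per_resp)
        if n < 2:
            logger.info("combo %s has a single respondent; overlap skipped", key)
            continue
        geoms = [per_resp[r] for r in sorted(per_resp)]
        pairs = list(itertools.combinations(geoms, 2))
        mean_j = float(np.mean([jaccard(a, b) for a, b in pairs]))
        all_union = unary_union(geoms)
        inter = geoms[0]
        for g in geoms[1:]:
            inter = inter.intersection(g)
        rows.append(
            {
                "port": key.port,
                "gear": key.gear,
                "length_class": key.length_class,
                "n_respondents": n,
                "mean_jaccard": mean_j,
                "union_km2": all_union.area / 1e6,
                "intersection_km2": inter.area / 1e6,
            }
        )
    return OverlapReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Congruency with an external effort raster


@dataclass
class CongruencyReport:
    """Coverage of externally observed effort by the priority map."""

    coverage_fraction: float
    rank_correlation: float
    n_effort_cells: int


def effort_congruency(
    priority: PriorityRaster, effort: PriorityRaster
) -> CongruencyReport:
    """Fraction of effort-positive cells that carry positive priority.

    If the priority map is sound, every cell where fishing effort was
    observed should hold some access priority; the Spearman rank correlation
    over cells positive in both rasters is reported as a supplementary
    diagnostic (effort and priority need not be proportional).
    """
    if priority.grid != effort.grid:
        raise GridMismatchError(
            f"priority grid {priority.grid} != effort grid {effort.grid}"
        )
    eff_pos = effort.values > 0
    n = int(eff_pos.sum())
    if n == 0:
        return CongruencyReport(0.0, float("nan"), 0)
    covered = (priority.values > 0) & eff_pos
    frac = float(covered.sum()) / n
    both = covered
    p_vals, e_vals = priority.values[both], effort.values[both]
    if both.sum() >= 3 and np.ptp(p_vals) > 0 and np.ptp(e_vals) > 0:
        rho = float(stats.spearmanr(p_vals, e_vals).statistic)
    else:
        rho = float("nan")
    return CongruencyReport(frac, rho, n)
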