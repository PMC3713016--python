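# Methods

## Model

Spatial access priority (SAP) is an interview-derived currency of how much a
sea area matters to a fleet. Its unit convention is fixed by two identities:

1. every full-time fisher carries a total SAP of 100, distributed over the
   areas their vessel's respondent drew;
2. the density of one area is `d = C·I/A` (SAP km⁻²), with `C` the vessel's
   pro-rata crew (FTE), `I` the area's importance in percent and `A` its
   area in km².

Pro-rata crew counts seasonal members as `months/12` of a full-time member.
Importance is either months-of-year (converted to percent and renormalized
so each respondent-vessel sums to exactly 100, which also absorbs stated
months that do not fill the year) or positive rank weights (scaled
proportionally). A single area with no stated value receives 100. Both
renormalizations enforce identity (1) exactly; overlapping polygons from one
respondent are allowed because the per-respondent total-100 constraint
already prevents double counting of that fisher's mass.

## Up-scaling

The fleet is stratified into port × gear × length-class combinations. The
default category scheme has eight classes: <7, 7–<9, 9–<10 pots,
9–<10 non-pots, 10–<15, 15–<20, ≥20 (non-pelagic), and pelagic at any
length. The 9–<10 split exists because pot boats of that size carry
significantly fewer crew than trawlers or dredgers; pelagic vessels are
separate because their crews (8–10) dwarf every other class. The scheme is
configuration: any ordered list of half-open length intervals with gear
predicates that partitions the fleet is accepted, and gaps or overlaps are
reported as configuration errors.

Per combination, `E = n_vessels × (category mean crew from the interview
sample)` estimates total crew and `S` sums the interviewed crew. Weights are
`W = E/S`. Combinations with `E > 0` but `S = 0` are represented by a donor:
the sampled combination with the same port and gear and minimal length-class
rank distance (ties broken toward the smaller class — smaller vessels are
the chronically under-sampled stratum, and a deterministic rule is
required); failing that, the same gear at the nearest port, measured by
Euclidean distance between configured port coordinates (they live in a
projected metric CRS, where great-circle and planar distance are
indistinguishable at fleet scale) or, absent coordinates, by position in a
configured coastal port sequence. Donor weights become
`(E_donor + Σ E_assigned)/S_donor`, so `Σ W·S = Σ E` holds exactly — the
pipeline's central conservation law, asserted in the tests at 10⁻⁶ relative
and typically exact to machine precision. A gear with no interviews
anywhere cannot be up-scaled and is a hard error.

Two optional re-weightings: processor employment (a fishery's shore-side
FTE is split over its combinations proportionally to their share of the
fishery's `E` and added before weights are recomputed, conserving
`Σ E + Σ FTE`), and landings value (each layer's weight is multiplied by the
fishery's value per fisher, producing currency-scaled SAP).

## Gridding

Rasters are axis-aligned in the projected CRS with 1000 m cells (half-open
`[x, x+1000) × [y, y+1000)`), origin snapped to the 1 km lattice by default.
Two modes:

- `exact_area` (default): a cell receives `density × (polygon∩cell area /
  cell area)`, computed with vectorized polygon-box intersections. The
  raster total equals the vector total to float precision for any grid
  origin. This is the mode consistent with treating SAP km⁻² as a density.
- `cell_center`: a cell receives the full density when its centre falls
  inside the polygon, mimicking a plain GIS rasterizer; totals are then
  origin-dependent. Differences between the modes are visible in the audit
  output.

Never-touched cells are no-data, distinct from true zeros, in the ESRI
ASCII grid writer. Raster export is plain-text ASCII grid; vector IO is
GeoJSON carrying a legacy `crs` member with an authority code (GeoJSON's
default WGS84 convention cannot express the projected equal-area CRS the
method requires, so the reader insists on a declared projected code and
refuses geographic ones). Combining rasters requires identical grids — no
silent resampling.

Relative priority divides a raster by a group's total SAP; with the
raster's own total it integrates to exactly 1. Closure impact is computed in
vector space (polygon intersections), so fractions are exact, in [0, 1], and
monotone in closure growth; groups can be the fleet, fisheries or
combinations. Marxan export aggregates the same vector-exact SAP mass onto
planning-unit polygons as an `id,cost` table whose costs sum to the total
SAP in the tiled region.

## Validation statistics

- Length representativeness: two-sided two-sample t-test, interviewed
  vessels vs the active fleet, with pooled variance (`df = n₁+n₂−2`).
  Pooled rather than Welch because the stratified design compares a
  subsample against its own population; Welch is a one-line switch.
- Port and gear representativeness: chi-squared goodness-of-fit of sample
  stratum counts against population proportions (`df = k−1`, no continuity
  correction). Small ports are merged via an explicit grouping map; any
  expected count of zero raises an error recommending coarser grouping.
- Crew-by-gear difference: pooled t-test of pro-rata crews, one gear vs the
  rest, within a length window (default 9–10 m pots vs others) — the test
  that justifies splitting a length class by gear.
- Within-combination consistency: mean pairwise area-Jaccard of
  respondents' union footprints per combination; singletons are skipped
  with a log note. High overlap supports up-scaling.
- Effort congruency: given an external gridded effort raster on the same
  grid, the fraction of effort-positive cells with positive priority. The
  underlying check is qualitative ("everywhere fished should carry some
  priority"); the fraction operationalizes it, with a supplementary
  Spearman rank correlation over cells positive in both rasters (effort and
  priority need not be proportional, so this is diagnostic only).

## Synthetic scenarios

The generator emulates the fleet structure the method was designed around:
246 active vessels across 20 ports on a synthetic straight coastline, three
major ports hosting the trawl/dredge/pelagic fleets and ~17 minor ports of
mostly pot boats; lengths drawn per gear (pots 4.5–9.9 m, nephrops trawl
9–24 m, dredge 10–22 m, whitefish 12–20 m, pelagic 28–36 m); full-time crew
increasing with length class, pot boats offset downward, pelagic 8–10;
seasonal members on 25% of vessels; fishing range from port increasing with
length (pots 2 + 0.6·L km, others 4 + 1.6·L km). Priority polygons are
buffered discs anchored on a per-(port, gear) core bearing and distance with
small respondent jitter, so within-combination overlap is high while pot
fleets at different ports are spatially separate — the qualitative overlap
structure the validation module is meant to detect. Importance is a
Dirichlet(2) split of the year over 1–4 areas per respondent. Interviews are
stratified Bernoulli draws at 48% inclusion; by default each populated
category is guaranteed at least one interview (the paper-scale survey also
secured its rare strata, e.g. the single pelagic respondent), which keeps
category means estimable at any seed — this floor can be disabled for
sampling-theory tests. All draws flow from the scenario seed; identical
seeds give bit-identical registers, geometries and samples.

What the generator does not emulate: real coastline geometry and
bathymetry-driven ground shapes, inter-fishery spatial competition,
temporal/seasonal structure, and digitizing error in respondent polygons.
Passing tests therefore demonstrate the pipeline's arithmetic, conservation
and statistical machinery on realistically structured data, not the
ethnographic fidelity of any real survey.

## Numerical choices and problem sizes

Zero-buffer repair is applied to invalid input polygons, then still-invalid
or zero-area geometries are rejected by id. Exact-area rasterization uses
shapely's vectorized C API over the polygon's bounding-box cell window.
Conservation assertions use 10⁻⁶ relative tolerance; observed discrepancies
are at machine precision. The test suite and the default scenario (246
vessels, ~450 polygons, ~20 000 grid cells) run the full pipeline in a few
seconds; the rasterization oracle compares exact-area fractions against a
32×32 sub-grid point-sampling estimate on 100 random polygons, with the
sub-grid's binomial sampling error as the agreement bound.

## Known limitations

- Shapefile and GeoTIFF IO are not provided; GeoJSON and ESRI ASCII grid
  cover the same information losslessly in plain text.
- No on-the-fly reprojection: all inputs must share one projected CRS.
- The chi-squared representativeness test treats the sample as independent
  draws from the register; for samples approaching a census the
  goodness-of-fit framing becomes conservative.
- Donor fallback transfers all of an unsampled combination's E to a single
  donor; splitting across equidistant donors would be a defensible
  alternative and would conserve E equally.
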