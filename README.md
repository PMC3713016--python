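# sapmap — Spatial Access Priority Mapping for fishing fleets

`sapmap` turns fishers' interview-drawn priority polygons into quantitative,
fleet-wide maps of spatial access priority (SAP), for use in marine spatial
planning, marine-protected-area design and closure-impact assessment. It is
aimed at planners and fisheries scientists who run participatory mapping
surveys and need to scale a sample of interviews up to a whole fleet in a
transparent, conservation-checked way.

## The method

Each respondent (a skipper or owner) draws polygons over the sea and states
how important each one is — either the fraction of the year fished there or a
rank weight. Importances are normalized to sum to 100 per respondent-vessel,
so **each full-time fisher carries a total SAP of 100**. The priority density
of an area is

```
SAP km⁻² = C × I / A
```

where `C` is the vessel's pro-rata crew in full-time equivalents (seasonal
members count as months/12, so 4 full-time crew plus one member for six
months gives C = 4.5), `I` is the importance (percent) and `A` the polygon
area in km². A boat with C = 4.5 therefore carries a total SAP of 450, and a
lone fisher spreading the year over 10 km² leaves 10 SAP km⁻² — a tenth of a
fisher per square kilometre.

To represent the whole fleet, vessels are stratified into port × gear ×
length-class *combinations* (default: eight length/gear categories, with the
9–<10 m bin split into pots / non-pots and pelagic vessels their own class).
For each combination, the estimated crew `E = n_vessels × mean crew of the
category` is divided by the sampled crew `S` to give the up-scaling weight
`W = E/S`; unsampled combinations donate their `E` to the most similar
sampled one (same port and gear, nearest length class, else nearest port), so
total estimated crew is conserved: `Σ W·S = Σ E`. Weighted layers are
rasterized onto an equal-area 1 km² grid with an exact-area rule that
conserves total SAP to float precision, and summed into fleet, per-fishery
and relative (sum-to-one) maps. Validation statistics (length t-test, port
and gear chi-squared, within-combination Jaccard overlap, congruency with an
external effort raster), closure-impact fractions and Marxan planning-unit
cost tables complete the pipeline.

## Worked example

Simulate a realistic fleet (246 vessels, 20 ports, ~48% interviewed), build
the maps, and check representativeness:

```
$ sapmap simulate --seed 0 --out-dir demo
wrote synthetic fleet of 246 vessels to demo

$ sapmap map --register demo/register.csv --responses demo/responses.geojson \
             --ports demo/ports.csv --out-dir demo/maps
fleet total SAP 73007.6 (vector) / 73007.6 (raster, exact_area); 6 rasters written to demo/maps

$ sapmap validate --register demo/register.csv --responses demo/responses.geojson \
                  --out-dir demo/val
length t-test: t = 0.304, df = 358, p = 0.761
port chi-squared: X2 = 12.601, df = 19, p = 0.858
gear chi-squared: X2 = 0.148, df = 4, p = 0.997
...
```

The map step writes the fleet raster, one raster per fishery (ESRI ASCII
grid), the full weighting scheme (`weights.csv`) and a conservation audit:
the vector-space total (100 × Σ estimated crew = 73007.6 SAP here) equals
the raster total, confirming nothing was lost in gridding. The two p-values
near 1 say the interview sample is statistically indistinguishable from the
fleet in length, port and gear composition — the precondition for up-scaling.

Closure impact, for a closure over the western third of the mapped area:

```
$ sapmap impact --register demo/register.csv --responses demo/responses.geojson \
                --ports demo/ports.csv --closure demo/closure.geojson \
                --groups fishery --out demo/impact.csv
group,sap_inside,sap_total,fraction
nephrops,16116.5,41407.2,0.389
pots,4485.4,13079.0,0.343
whitefish,2494.3,2811.4,0.887
...
```

i.e. this closure would remove 38.9% of the nephrops fleet's access priority
but 88.7% of the whitefish fleet's — exactly the equity comparison the maps
are built for. `sapmap export-marxan` writes the same SAP mass aggregated
onto planning-unit polygons as a Marxan `id,cost` table.

The same operations are available as library functions
(`sapmap.build_maps`, `sapmap.closure_impact`, `sapmap.export_marxan`, ...)
and give bit-identical results.

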