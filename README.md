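# commute-exposure

Population-based simulation of commuter exposure to traffic-related NO2,
built to run entirely on synthetic data with known ground truth.

The pipeline mirrors a typical in-transit exposure assessment:

1. **simulate** — generate a grid-of-streets road network with main/side
   classes, multi-resolution annual-mean NO2 rasters (25/50/100 m) that
   share one latent concentration field, a commuter population with
   geo-coded multi-leg trips, and 30-min weekday time series for a street
   and a background monitoring station.
2. **route** — shortest routes by distance (lexicographic tie-breaking),
   duplication of uneven home/work trip sets, and inclusion filtering
   (inside study area, home ≠ work, ≥ 1 trip, geocode quality).
3. **classify** — each leg gets a single main/side road class from the
   longest overlapped segment; off-network legs use a 15 m buffer rule.
4. **ratios** — hour-of-day temporal adjustment factors per road class:
   annual weekday hourly means divided by the weekday annual mean at the
   street (main) and background (side) stations.
5. **expose** — exact polyline/cell clipping, length-weighted leg
   concentrations, duration-weighted subject concentration and cumulative
   exposure including waiting times, time-weighted exposure, and
   ventilation-adjusted inhaled dose (walking ×1.7, bicycle ×2.0).
6. **compare** — inter-model statistics: summary tables, Spearman
   correlation, polynomial relation fits, Bland–Altman limits of
   agreement (mean ± 2 SD), Wilcoxon signed-rank, and a Fisher–Pitman
   permutation test of spread differences, plus validation of a raster
   against point measurements.

All formats are plain text: ESRI ASCII grids, GeoJSON, CSV, and a JSON
run manifest with seeds and output hashes. Two runs with the same seed
produce byte-identical outputs.

## CLI

Run the whole pipeline on the bundled demo scenario:

```sh
commute-exposure run --config examples/scenario.yaml --out pipeline_out --seed 1
```

or stage by stage:

```sh
commute-exposure simulate --out out --seed 1
commute-exposure route    --network out/network.geojson --population out/population.geojson --out out/legs.geojson
commute-exposure classify --legs out/legs.geojson --network out/network.geojson
commute-exposure ratios   --stations out/stations.csv --out out/ratios.csv
commute-exposure expose   --legs out/legs.geojson --ratios out/ratios.csv --grids out --out out/exposure.csv
commute-exposure compare  --exposures out/exposure.csv --out out --n-perm 9999 --seed 1
```

## Package layout

```
src/commute_exposure/
  models.py          shared domain types (legs, trips, grids, records)
  synthetic.py       scenario generation with ground truth
  routing.py         shortest routes, trip completion, inclusion filters
  classification.py  main/side road classification rules
  temporal.py        hour-of-day adjustment factors
  exposure.py        the exposure engine (clipping, Eqs, dose)
  comparison.py      inter-model statistics
  io.py              ASCII grid / GeoJSON / CSV round-tripping
  pipeline.py        stage orchestration and manifest
  cli.py             click entry point
```
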