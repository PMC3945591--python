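# hazpop

Gridded multi-hazard population-exposure model. From raw hazard event
records — cyclone tracks, flood footprint boxes, and a monthly
precipitation cube — it builds per-hazard event-frequency grids, bins them
into global relative-frequency deciles over sufficiently populated or
agricultural cells, classifies every cell urban or rural against national
urban proportions, and computes, ranks and stratifies country-level
population exposure scores (per hazard in [0, 1]; the equally weighted
three-hazard total in [0, 3]).

## Model outline

1. **Hazard frequency.** One tally per event per cell: cyclone events
   cover cells within a per-intensity-category great-circle buffer of the
   track; flood events cover cells whose center falls inside a
   whole-degree bounding box; drought events are maximal runs of ≥3
   consecutive months at ≤50 % of that calendar month's long-term median.
2. **Deciles and weights.** Cells with density < 5 persons/km² and no
   significant agriculture are excluded; remaining cells with ≥1 event are
   sorted into global deciles 1–10 (nearest-rank boundaries, ties share a
   decile), giving hazard weights H = decile/10.
3. **Urban/rural.** Per country, cells sorted by population descending;
   the prefix whose cumulative population best matches the national urban
   proportion is urban, the rest rural.
4. **Exposure.** Cell exposure = population × H; a country's score is the
   summed cell exposure divided by the population of the same cell set,
   for the total, urban and rural strata, plus person-weighted averages by
   development (HDI) class.
5. **Ranking.** Descending competition ranks (tied countries share
   1 + the number of strictly better countries) and quintile display
   classes.

A synthetic-world generator (`hazpop.synthetic`) produces complete,
seeded, statistically controlled inputs — rectangular countries, clustered
integer populations, hazard events, seasonal precipitation with injected
deficit runs and a ground-truth sidecar — so the whole pipeline is
testable without licensed datasets.

## CLI

```sh
# full synthetic run: inputs/ -> hazards/ -> classify/ -> exposure/ -> report/
hazpop run-all --synthetic --seed 7 --outdir out/

# stages can be run individually; outputs are ordinary files, so any
# input dataset can be swapped and only downstream stages re-run:
hazpop simulate --outdir out/ --seed 7
# ... edit out/inputs/flood_events.csv ...
hazpop hazards  --outdir out/
hazpop classify --outdir out/
hazpop exposure --outdir out/
hazpop rank     --outdir out/
```

A YAML config (`--config cfg.yaml`) can set the world parameters,
per-category cyclone buffer radii (`radii_km`), the drought median floor
(`min_median_mm`), and the stage list; flags override the file.

## Layout

```
src/hazpop/
  raster.py     grid model, ASCII I/O, resampling, cell areas, zonal sums
  hazards.py    event records -> frequency -> deciles -> weights
  urban.py      per-country urban population threshold + classification
  exposure.py   cell/country exposure, strata, HDI-class averages
  ranking.py    competition ranks, quintiles, CSV report export
  synthetic.py  seeded synthetic worlds and the extreme-country fixture
  pipeline.py   staged, file-backed orchestration
  cli.py        click CLI (`hazpop`)
```
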