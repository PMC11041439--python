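# passivesense

Server-side processing core for a smartphone passive-sensing platform:

* **raw_io** — per-sensor raw text logs (accelerometer, GPS, call log,
  screen on/off, per-app exchanged kB) as plain CSV files with an
  epoch-millisecond time column; validated, time-sorted in-memory streams.
* **synthetic_data** — a multi-week single-user stream simulator with
  workday / weekend / holiday behavioral regimes, a power-saving policy
  model (subgroup A: continuous acquisition; subgroup B: embedded sensors
  killed while the screen is off and the device is stationary), and a
  ground-truth record for every downstream oracle.
* **integrity** — acquisition-gap detection (maximal sample runs with no
  inter-sample interruption > 1 s), the data-integrity percentage
  (100 · acquired hours / running hours), and power-saving subgroup
  classification from gap/screen-off coincidence.
* **daily_features** — per-calendar-day behavioral features: call
  aggregates, screen sessions with hourly seconds-of-use slots,
  per-category app traffic, hourly acceleration amplitude and
  high/low-activity seconds.
* **gps_features** — stay-point clustering of GPS fixes into visited
  places, home inference from night-time dwell, and daily mobility
  features (places visited, % time outside home, location variance,
  location entropy and its normalized form, visited places by distance
  from home).
* **anomaly** — day × feature matrix assembly (z-standardized, median
  imputation), PCA feature screening by component loadings, day ranking
  by the k-Nearest-Neighbor Global Anomaly Score, and regime-recovery
  metrics against synthetic ground truth.
* **cli** — a `passivesense` command orchestrating the stages.

## CLI

```bash
# full pipeline: simulate -> extract -> integrity -> anomaly
passivesense run --outdir out --n-days 60 --seed 1

# stages individually
passivesense simulate --outdir raw --n-days 14 --seed 1 --holidays 9
passivesense extract   --indir raw --outdir out
passivesense integrity --indir raw --outdir out
passivesense anomaly   --features-csv out/features.csv --outdir out --plot out/gas.png
passivesense report    --outdir out
```

All thresholds and simulation parameters can be overridden with a YAML
config (`--config`); the defaults live in `passivesense.cli.DEFAULTS`.
Outputs are plain CSV/JSON: `features.csv` (one row per day, plus
missing-mask columns), `integrity_report.json`, `gaps.csv`,
`anomaly.csv`, `selected_features.txt`, `clusters.json`,
`ground_truth.json`.

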