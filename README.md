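# homesense

Household sleep and time-at-home indicators inferred from smart-thermostat
motion-sensor streams, with a stratified inferential layer and a synthetic
data generator that makes the whole chain runnable — and checkable against a
known ground truth — without any external data.

## What it does

1. **Preprocessing** — 5-minute per-sensor motion readings are aggregated into
   48 half-hour slots per day; a slot is *active* when its activation score
   (count of sensor × 5-minute activations) reaches a threshold (default 4).
   Households qualify with ≥ 300 days of data, ≥ 6 sensors and ≤ 4 occupants.
2. **Sleep cycles** — each pair of consecutive days yields a 32-slot vector
   spanning 20:00 of day 0 to noon of day 1 (noon–20:00 is disregarded).
3. **Sleep inference** — per household and stratum, cycle vectors are
   segmented with a BIC-selected diagonal Gaussian mixture; each cluster is
   reduced to a binary pattern (mean activation > 0.5) and the longest
   inactive run terminated by an activation gives sleep time, wake-up time
   and duration.  Household values are cluster-weighted averages.
4. **Occupancy** — the same machinery on the 48-slot daily vectors; time at
   home is 30 minutes per active pattern slot (sensor-observed active time,
   which excludes sleeping hours).
5. **Stratification** — weekday, season (winter Jan 1–Mar 21, spring
   Mar 22–Jun 21, summer Jun 22–Sep 21, fall Sep 22–Dec 21; Dec 22–31 is
   unassigned and dropped from season schemes), and season × weekday.
   Sleep time/duration count on the falling-asleep day, wake-up time on the
   next day.
6. **Inference** — Levene's test, one-way ANOVA and Tukey–Kramer post hoc
   comparisons (additive two-way ANOVA with Type II sums of squares for the
   season × weekday scheme).  Every test also runs directly from published
   per-group `(n, mean, sd)` summaries, which is how the reference F and q
   statistics are reproduced without raw data (see `homesense.datasets`).

## CLI

```sh
# full synthetic run: simulate + analyze in memory
homesense all --config examples/cohort.yaml --scheme weekday --out out/

# or stage by stage
homesense simulate   --config examples/cohort.yaml --out sim/
homesense preprocess --input sim/stream.csv --out pre/
homesense stratify   --cycles pre/cycles.csv --scheme weekday --out strata.csv
homesense infer      --daily pre/daily.csv --cycles pre/cycles.csv \
                     --households sim/households.csv --scheme weekday --out ind/
homesense test       --indicators ind/indicators_long.csv --scheme weekday --out stats/

# ANOVA + Tukey straight from a published summary table (label,n,mean,sd)
homesense report --summaries summaries.csv --out report/
```

Common flags: `--scheme {overall,weekday,season,season_weekday}`,
`--threshold` (activation score, default 4), `--k-max` (mixture components,
default 6), `--min-cycles` (default 10), `--seed`, `--alpha`, `--min-days`.

Input stream CSV dialect: `household_id,timestamp,sensor_id,motion` with ISO
timestamps on the 5-minute grid and motion ∈ {0,1}.  The simulator also
writes a truth ledger (`household_id,date,sleep_onset_min,wake_min,away_min`)
and a metadata sidecar (`household_id,n_sensors,n_occupants`).

## Layout

```
src/homesense/
  synth.py        synthetic cohort generator + truth ledger
  preprocess.py   stream parsing, slot aggregation, cycles, eligibility
  clustering.py   GMM segmentation and binary cluster patterns
  sleep.py        sleep-interval detection and weighted indicators
  occupancy.py    time-at-home indicators
  strata.py       calendar stratification rules
  stats.py        Levene / ANOVA / Tukey-Kramer (raw and summary routes)
  datasets.py     bundled reference summary tables
  pipeline.py     orchestration, run log, CSV writers
  cli.py          click-based CLI
```
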