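# addhrv

Detection of episodes of **reduced additional heart rate variability** —
HRV reductions not explained by concurrent physical activity — in
ambulatory recordings, for psychophysiology labs that pair wearable
ECG/accelerometry with hourly experience sampling.

Chronically low HRV predicts cardiovascular disease, and psychological
stress is a candidate driver. In ambulatory data, however, most HRV change
is metabolic: movement raises heart rate and lowers HRV. The approach
implemented here separates the two with an *individualized inverse
regression model*. For participant *i* and 30-s window *j*,

```
expected_RMSSD[i, j] = B0[i] + B1[i] * acceleration[i, j]
```

where RMSSD is the root mean square of successive RR-interval differences
(ms) over the window, acceleration is the tri-axially averaged movement (g),
`B0` is the RMSSD expected at rest and `B1` the (negative) change per g.
Whenever observed RMSSD falls **two standard errors of the mean (SEM)** of
the fitting data below the movement-expected level, and the deficit lasts
**at least 7.5 consecutive minutes**, the run is an episode of reduced
additional HRV — a candidate physiological stress marker. Episodes with
onset during sleep are excluded and only the first episode per clock hour
enters analysis.

The open question the package operationalizes is *which data should fit the
model*. Seven subset strategies are implemented:

| method | fitting subset |
| --- | --- |
| `calibration` | scripted lab activities (sit, stand, lie, cycle, stairs) |
| `calibration_extended` | the same plus isometric clenching and reading aloud |
| `hourly10` | first 10 min of every hour |
| `full` | the entire day (or session) |
| `threehour10` | first 10 min of hours h−1, h, h+1 |
| `bins` | first 5-min run inside each per-participant movement quartile |
| `nextday` | all of day *n*−1, applied to day *n* |

Detected episodes are then evaluated three ways: episode-count tables,
between-day Pearson correlations (temporal reliability), and matching
against hourly self-reported stress/worry — the share of participants with
at least one physiological–psychological match and the mean
within-participant match percentage.

Because ambulatory datasets of this kind are not publicly deposited, the
package ships a synthetic-cohort generator (`addhrv.simulate`) with known
ground truth: per-participant baselines, a movement Markov chain, circadian
drift, sleep, a scripted calibration block, injected movement-independent
RMSSD dips, and deliberately incomplete self-reports.

## Worked example

`examples/compare_methods.py` simulates the default cohort (6 participants,
three 24-h sessions) and runs the full comparison:

```
              method  mean_episodes_per_day  pct_participants_with_match  mean_match_pct
         calibration                    5.8                        100.0            33.1
            hourly10                    5.2                        100.0            30.6
                full                    9.5                        100.0            25.6
         threehour10                    6.5                        100.0            31.4
                bins                    5.8                        100.0            27.7
calibration_extended                    3.9                        100.0            35.5
             nextday                    5.9                         83.3            27.9
```

`mean_episodes_per_day` is the detected episode count averaged over
participants and days: the full-dataset method detects the most episodes
because its large-n fit makes the 2-SEM threshold tight. The match columns
compare episode onsets with stress/worry reports for the same clock hour;
every method finds more episodes than participants report, reproducing the
underreporting pattern the generator builds in (each injected episode is
self-reported with probability 0.3). `nextday` covers only days 2–3, so
fewer participants can match.

Other entry points, one capability each, live in `examples/`:
`simulate_cohort.py`, `preprocess_raw_streams.py`, `fit_methods.py`,
`detect_episodes.py`. A thin CLI wraps the same pipeline for CSV-based use:

```
addhrv all --seed 5 --out results/            # simulate + all methods
addhrv preprocess --beats beats.csv --accel accel.csv --out grid.csv
addhrv detect --grid grid.csv --method full --out episodes.csv
```

## Layout

- `src/addhrv/preprocessing.py` — RR/acceleration streams → aligned 30-s grid
- `src/addhrv/modeling.py` — inverse regression fits, seven subset strategies
- `src/addhrv/detection.py` — 2-SEM / ≥7.5-min run detector, reporting filters
- `src/addhrv/evaluation.py` — counts, day correlations, self-report matching
- `src/addhrv/simulate.py` — synthetic cohorts with ground truth
- `src/addhrv/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, CSV round-trips

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
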