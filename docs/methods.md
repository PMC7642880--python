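# Methods

## The construct

"Additional" HRV change is the part of heart-rate-variability change not
attributable to concurrent physical activity. The package quantifies it per
participant: a linear model of windowed RMSSD on movement supplies a
movement-expected RMSSD for every 30-s window, and sustained shortfalls
below that expectation are flagged as episodes. The assumptions are:

1. **Within a fitting subset, RMSSD is linear in movement.** The "inverse"
   in *inverse regression model* refers to the inverse (negative)
   HRV–movement relation, not to a reciprocal predictor: the intercept is
   read as RMSSD at zero acceleration and the slope as the change due to
   acceleration, which only a straight line supports. A reciprocal
   sensitivity form `b0 + b1/(acc + eps)` (`eps` = 0.01 g) is available via
   `MethodConfig.model_form` but is not the default and is not used in any
   headline analysis.
2. **The threshold unit is the SEM of the observed RMSSD over the fitting
   subset** (sample SD with n−1 denominator divided by √n), not the
   regression standard error. Large fitting subsets therefore give tight
   thresholds: the full-day method (n ≈ 2880) flags any 7.5-min run that
   sits essentially below the regression line, while 10-min subsets
   (n = 20) require a much deeper deficit.
3. **Deficits must be sustained.** A window is deficient when
   `rmssd ≤ expected − k_sem·sem` (inclusive, so exactly k SEM counts —
   this makes the threshold exactly recoverable in tests); an episode is a
   maximal run of ≥ `ceil(min_episode_min·60/window_s)` consecutive
   deficient windows (7.5 min = 15 windows at 30 s). Missing windows break
   runs (conservative choice; brief gaps could plausibly be bridged, but
   bridging rules add free parameters). Runs may cross hour and day
   boundaries — the governing fit simply changes at scope boundaries — and
   are attributed to the day and clock hour of onset.

## Windowing

Windows are half-open `[k·w, (k+1)·w)` seconds from session start; beats are
assigned by beat time and RMSSD uses only successive-difference pairs whose
two beats both lie in the window, keeping windows independent. Implausible
RR intervals (outside 300–2000 ms by default) are masked, not dropped: a
masked beat contributes no difference pair on either side. Windows with
fewer than 3 plausible beats (or no usable pair) are missing. Acceleration
is reduced per raw sample to the mean of the three axes' absolute values
(Euclidean norm available as a switch) and averaged per window. No
operation ever deletes a window; missingness is flagged with NaN and row
counts are conserved, so window indices remain a valid global clock.

## Fitting-subset strategies

* `hourly10` / `threehour10` fit per (day, hour); the three-hour variant
  pools the first `lead_min` minutes of hours h−1, h, h+1, with the first
  hour of a day using hours 0–1 and the last using the penultimate and
  final hours (40 windows instead of 60).
* `full` fits per day by default (`full_scope="day"`), matching per-day
  episode tables for multi-day recordings; `full_scope="session"` pools
  everything.
* `bins` computes per-participant movement quartiles over the whole session
  (the 25/50/75th percentiles of non-missing acceleration) and takes, per
  day and per quartile, the first run of 5 consecutive minutes lying
  entirely inside the quartile's range — half-open ranges with boundary
  values going to the upper quartile, the top quartile closed above. At most
  4 × 10 windows (20 min) fit the model; quartiles without a qualifying run
  are simply absent.
* `calibration` pools all windows of the scripted lab activities except the
  two stress tasks (isometric clenching, reading aloud);
  `calibration_extended` includes them. Activities are pooled unweighted —
  with equal 3-min segments, duration weighting would be a no-op anyway.
* `nextday` fits on all of day d−1 (sleep included) and governs day d; day 1
  is never governed, so a one-day recording yields no fits and a warning.

A subset with fewer than two samples or constant acceleration produces a
`valid=False` fit rather than an error; its scope simply detects nothing.
Subset *positions* depend only on the window lattice and missingness
pattern, never on data values.

## Evaluation

Matching granularity is the clock hour: an episode matches when a
stressed-or-worried report covers the hour of its onset on the same day
(`match_window_hours` widens this; stress and worry are pooled with OR).
The cohort summary reports (a) the percentage of participants with at least
one match — denominator all participants by default, configurable to
participants with ≥ 1 detected episode — and (b) the mean within-participant
match percentage over participants that have at least one match. The detail
table also carries the reverse reading (fraction of positive report-hours
matched by any episode) for sensitivity checks. Day-pair Pearson
correlations get 95% CIs via the Fisher z transform and are flagged
undefined for fewer than three participants or constant counts.

## The synthetic cohort

The generator's defaults describe a 6-participant study with three 24-h
sessions per participant (one day can be marked missing to emulate a 48-h
recording):

| parameter | default | meaning |
| --- | --- | --- |
| `b0_range`, `b1_range` | 40–70 ms, −30…−10 ms/g | participant baseline and movement slope |
| `noise_sd` | 3 ms | iid Gaussian window noise |
| `circadian_amp` | 5 ms | sinusoid on the baseline, trough 03:30 |
| `sleep_hours`, `sleep_b0_bonus` | 00–07, +10 ms | rest state, elevated nocturnal RMSSD |
| `episode_rate` | 8 / waking day | Poisson count of injected dips |
| `episode_depth_sd` | 3 | dip depth in units of the day's waking RMSSD SD |
| `episode_dur_min` | 8–25 min | uniform dip duration |
| `report_prob` | 0.3 | chance an injected dip is self-reported |
| `spurious_report_rate` | 0.5 / day | stress reports tied to no dip |

Movement comes from a Markov chain over rest/walk/cycle/stairs
(0.02/0.25/0.45/0.8 g) with mean dwell times of 8/4/4/1 minutes and
re-entry weights favouring rest — enough movement variety that every
subsetting strategy sees a usable design matrix within a day. A scripted
21-min calibration block (seven activities, 3 min each) starts at the first
waking hour of day 1; the two stress tasks multiply RMSSD by 0.8 without
movement, mirroring their purpose in the extended calibration protocol.

**Episode depth** is parameterized in multiples of the day's realized waking
RMSSD standard deviation. This makes detectability controllable
independently of the noise setting: at the default depth of 3 SD
(≈ 15–25 ms), every window of a dip clears the 2-SEM threshold by a wide
margin, so the full-day detector recovers essentially all injected episodes,
while depth ≈ 0.5 SD dips disappear into the noise. Scaling by the SEM of a
full-day subset instead would make depth meaningless (a "3-SEM" dip would be
~0.5% of the noise SD), so the SD is the only scale on which a depth
parameter does what it says.

Optionally (`emit_beats`) the generator also emits a beat-level RR series
from an AR(1) interbeat process (mean 800 ms, φ = 0.3) whose innovation SD
is matched per window so that windowed RMSSD tracks the grid target; this
exercises the preprocessing path end to end.

**What the generator does not emulate.** Window noise is iid, whereas real
RMSSD is strongly autocorrelated; real recordings therefore produce more
borderline sub-threshold runs (and thus more unmatched episodes for the
tight full-day threshold) than the simulation does. Respiratory sinus
arrhythmia, heart-rate dependence of RMSSD, posture without movement, and
artifact structure from electrode noise are all absent. Passing tests
establish that the pipeline's logic is correct and that the detector
recovers injections under the stated statistical structure — not that any
method's match percentages on real cohorts are reproduced.

## Numerical and test-condition choices

* OLS is delegated to `scipy.stats.linregress`; tests verify agreement with
  the closed-form two-parameter solution to 1e-9 relative tolerance.
* Parameter-recovery checks run on a movement-only generative world
  (circadian amplitude, sleep elevation and episode rate set to zero):
  with the confounds active the generative model is not the fitted line —
  nocturnal elevation alone shifts the estimated intercept by about
  +10·(7/24) ≈ +3 ms — so "recovery of (b0, b1)" is only well-posed without
  them. Confounded fits are exercised by the detection and end-to-end tests
  instead.
* Detection recall is measured on raw runs after sleep exclusion but before
  the first-per-hour rule, and an injected episode counts as recovered when
  any detected run overlaps it: recall is a detector property, while
  first-per-hour is a reporting convention that can hide an
  otherwise-detected episode behind an unrelated earlier run.
* Matched-fraction convergence to `report_prob` is checked with ground-truth
  episodes (perfect detection) and spurious reports off, isolating the
  reporting mechanism; with spurious reports on, hour collisions inflate
  the fraction by a few points.
* Problem sizes used by the test suite — 1,000 detector-oracle cases of
  ≤ 200 windows, 100 recovery seeds, a 20-participant recall cohort, a
  200-participant matching cohort, and the 6 × 3-day end-to-end run — keep
  the whole suite under half a minute on one CPU while leaving each
  stochastic check well-powered.

## Known limitations

* Bit-compatibility with proprietary sensor software (windowing and artifact
  handling) is not attempted; the grid is the interface.
* The `bins` method's quartiles are computed per session, not per day, for
  multi-day recordings; per-day quartiles would change which runs qualify.
* The 7.5-min rule requires strict consecutiveness; tolerance for single
  missing windows inside a run is not offered.
* Repeated-measures ANOVA and pairwise t-tests over the count tables are out
  of scope; the exported `summary_counts.csv` is the input users would feed
  to their preferred statistics package.
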