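# Methods

`stdd` implements a two-block pipeline that infers a person's
depression-severity group (normal, mild, moderate, severe) from smartphone
and smartwatch passive sensing combined with ecological momentary
assessment (EMA) self-reports, and a synthetic-study generator that makes
the whole pipeline testable end to end with known ground truth.

## The two-block model

**Block I — per-participant symptom levels.** Five DSM-5-derived symptom
clusters are tracked on a 1–10 ordinal scale, one level per answered EMA
check-in (six scheduled daily at 07:00, 10:00, 13:00, 16:00, 19:00 and
22:00 local time):

* *Physical activity* and *mood* are learned per participant. The 50 Hz
  triaxial accelerometer stream of each device is cut into 50-sample (1 s)
  windows with 50 % overlap; 17 time-domain statistics per axis give 51
  features per device and 102 for the phone + watch pair. Step and
  significant-motion counts over the 30 minutes preceding the check-in are
  broadcast to each window (104 features); mood adds heart-rate mean and
  sample SD over the same period (106). Every window starting inside the
  half-open look-back interval `[t − 30 min, t)` of an answered check-in
  inherits that answer as its label (label duplication). A random forest
  (100 trees; an RBF-kernel SVM is the alternative) is trained per
  participant and per cluster, treating the ten levels as unordered
  classes; a period's level is the majority vote over its windows, with
  ties broken toward the lower level.
* *Sleep* is rule based. Within the nocturnal window 22:00–10:00, a minute
  is sleep-eligible iff no screen-on event falls in it, all ambient-light
  samples in it are ≤ 10 lux, and the per-minute phone-acceleration
  magnitude SD is ≤ 0.3 m/s² — with *no data counting as eligible* for each
  signal (a phone left untouched looks exactly like this). The longest
  contiguous eligible run is the night's sleep duration. The level is
  `clamp(round(10 − (9/4)·|duration − 7 h|), 1, 10)`: the 7-hour baseline
  scores 10 and deviations of 4 h or more (3 h or 11 h of sleep) score 1,
  linearly interpolated and symmetric about the baseline. Linearity is the
  minimal interpolation consistent with those anchors.
* *Social activity* is the daily weighted sum
  `10·(n_incoming + n_outgoing + n_social_app_opens) + minutes_incoming +
  minutes_outgoing + minutes_social_apps`. Applying the constant weight to
  the counts (not the durations) keeps counts and minutes at comparable
  magnitudes. Daily raw scores are min–max scaled to 1–10 within the
  participant (round half-up; a constant series maps to the neutral 5) —
  a deliberate within-person normalisation, which also means the social
  level carries little *between*-person information.
* *Food intake* has no passive proxy and passes straight through from the
  EMA answer.

**Block II — group classification.** Each answered-EMA period yields one
five-element sample (physical, mood, sleep, social, food); all samples of a
participant carry the participant's group as label, groups being treated as
stable over the study. Group assignment from the intake manifest is
rule based: PHQ-9 ≤ 9 with no depressive interview finding → normal;
PHQ-9 ≥ 10 with remission/partial episode → mild, other depressive
disorder → moderate, confirmed MDD → severe (a score of exactly 10 counts
as depressive-range, following the conventional screening cutoff;
inconsistent pairs are an explicit error). A 100-tree random forest is
evaluated by repeated stratified 70/30 splits with the test partition
subsampled to equal per-group counts (default 150 per group, lowered to the
smallest group's test count when necessary). Counts are accumulated across
repeats so the per-group TP-rate arithmetic stays exact; the accuracy SD is
taken across the repeated splits, which is also where the reported SD comes
from.

Splitting at the *sample* level means periods of the same person appear in
both partitions; this mirrors the pooled-period protocol the architecture
was designed around and overstates generalisation to unseen people. The
stricter alternative — holding out whole participants
(`split_by="participant"` / `--split-by participant`) — is provided and is
the honest generalisation test; with only five participants per group it is
also much noisier.

Feature importance for the five-feature group model is information gain
(entropy reduction of the group label given each discrete level),
normalised to shares summing to 100 %; for the high-dimensional personal
models, forest impurity importances are used instead.

## The synthetic-study generator

The generator's defaults are the study's nominal conditions: five
participants per group, 28 days, six EMA slots daily, with per-slot answer
probabilities (0.38, 0.60, 0.64, 0.61, 0.60, 0.58) taken from observed
field response rates — giving ≈1.9 k complete Block-II samples, the same
order as a real four-week cohort after skips and data loss.

Each participant draws per-cluster baseline levels from their group
(normal 8, mild 6, moderate 4, severe 2.5 for physical/mood/social, sleep
one level higher, food 5 except 8 for severe — depressed groups eat more,
move/sleep/socialise less), perturbed by ±0.3 to individuate participants.
Daily levels are the baseline plus N(0, 0.8) jitter, rounded and clipped to
1–10. At each slot a *momentary* level — the daily level plus a bounded
fluctuation of ±1 with probability 0.3 — is what the participant both
reports and physically does: the EMA answer equals the momentary level, and
the momentary level drives the sensor burst before the check-in. Reported
labels therefore never deviate from the daily latent level by more than 1,
while remaining learnable from the sensors.

Sensor emulation:

* **Accelerometer** — duty-cycled 50 Hz bursts (default 30 s, both
  devices) immediately before each *answered* check-in: a 2 Hz oscillation
  of amplitude `0.2 + 0.25·level` m/s² around gravity plus N(0, 0.05)
  sensor noise; the watch amplifies wrist motion by 1.3×. Duty-cycling is
  a realistic battery-saving design and keeps a 20-participant × 28-day
  study at ≈6 M accelerometer rows (≈200 MB of CSV) instead of the ≈2.4
  billion rows of continuous coverage; window/label semantics are
  unaffected because only pre-EMA windows ever receive labels.
* **Steps / significant motion** — Poisson events in the 30-minute
  look-back period at rates `30·level` and `1 + 0.5·level`.
* **Heart rate** — 1 sample/min all day: 52 bpm asleep, 62 awake, and
  `55 + 1.5·physical + 2.5·mood` bpm inside pre-EMA periods, all with
  2–3 bpm noise.
* **Light / screen** — ambient light every 5 min, uniform 0–8 lux during
  the latent sleep interval and 30–400 lux awake; screen sessions are
  Poisson while awake and never occur during sleep; answering an EMA
  lights the screen.
* **Sleep interval** — onset N(23:00, 0.3 h) clipped to 22:15–23:45;
  duration `7 − (10 − sleep level)·4/9` hours, so the sleep level is
  exactly recoverable by the scoring rule. The EMA sleep answer on day *d*
  refers to the night ending that morning (day *d − 1*'s latent night).
* **Calls / apps** — daily Poisson counts `0.4·social` calls and
  `0.6·social` social-app sessions with exponential durations, placed
  uniformly over waking hours.

Everything is driven by a single study seed through per-participant
`SeedSequence` children; identical seeds give byte-identical CSVs
(shortest-round-trip float rendering on write, round-trip parsing on read).

### What the generator does *not* emulate

Real gait spectra and heart-rate dynamics (the bursts are clean sinusoids —
the amplitude–level mapping is nearly noiseless, which is why personal
models score close to 100 % here while field studies report ~90 %);
sensor dropout, clock drift, and device non-wear; within-day circadian
structure beyond the sleep interval; weekend effects; mid-sleep
awakenings (the detector is blind to them by design); and the
counter-intuitive severe-group behaviour that mixed mood states can
produce in real cohorts. Passing recovery tests therefore demonstrates
the pipeline's correctness and internal consistency, not field accuracy.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `WindowingConfig.window_len` / `overlap` / `rate` | 50 / 0.5 / 50 Hz | 1-s windows, 50 % overlap; 30 min ⇒ 3600 windows |
| `EmaLinkConfig.lookback_min` | 30 min | half-open label-duplication interval |
| `SleepConfig.night_start/end` | 22:00 / 10:00 | candidate sleep window (local clock) |
| `SleepConfig.dark_lux_max` | 10 lux | darkness threshold |
| `SleepConfig.baseline_h` / `anchor_deviation_h` | 7 h / 4 h | scoring anchors (7 h → 10; ±4 h → 1) |
| `SleepConfig.static_threshold` | 0.3 m/s² | per-minute magnitude-SD ceiling for "static" |
| `SocialConfig.weight` | 10 | count weight in the social sum |
| `GroupModelConfig.n_trees` | 100 | forest size for Block II |
| `GroupModelConfig.test_fraction` / `per_group_test_n` | 0.30 / 150 | split and equal-n test subsampling |
| `GroupModelConfig.n_repeats` | 10 | repeated splits behind mean ± SD |
| `StudyConfig.compliance` | per-slot field rates | EMA answer probabilities |
| `StudyConfig.burst_s` | 30 s | duty-cycled accelerometer coverage per check-in |

All of these live in `PipelineConfig` and serialise to YAML
(`stdd run --config`), so no method constant is hard-coded in the stages.

## Numerical choices and degenerate inputs

* Statistic conventions (fixed so the brute-force oracle is unambiguous):
  sample SD (n−1); energy = mean of squares; skewness `m₃/m₂^1.5` and
  excess kurtosis `m₄/m₂² − 3` from central moments, both defined as 0 for
  zero-range windows; quartiles by linear interpolation at `q·(n−1)` on
  the sorted window; MAD unscaled.
* Window counts follow `floor(n/step)` per contiguous segment; gaps larger
  than twice the nominal sampling interval split the stream so no window
  spans a data gap; tail windows are kept when at least `step` samples
  long — this convention reproduces the 3600-windows-per-30-min identity.
* Rounding of derived levels is round-half-up (`floor(x + 0.5)`), so
  5.5 → 6 regardless of platform banker's rounding.
* Single-label training data yields an explicit constant predictor with a
  warning; empty periods are errors; a missing device block is imputed
  with the participant's feature-wise mean and flagged, as are periods
  with no heart-rate coverage.
* Nights whose 22:00 window opens before the participant's first observed
  sample are reported as absent rather than detected — the
  no-data-is-eligible rule would otherwise pad them — so day-0 periods
  drop out of Block II with a logged count.
* All randomness (simulation, splits, forests) descends from explicit
  integer seeds; reruns are bit-identical.

## Problem sizes used in the test suite

The acceptance-style recovery checks run one default synthetic study
(20 participants × 28 days, ≈1.9 k level vectors, ≈115 k labeled windows)
through the full pipeline — about four minutes on one core — and evaluate
Block II with five repeated splits; unit tests use one-participant-per-
group, 3–4-day studies with full compliance and 10-second bursts. These
sizes are the package's own defaults for a fast, fully reproducible
demonstration; nothing in the method depends on them.

## Known limitations

* Sample-level splitting overstates accuracy for unseen people (see
  above); use `split_by="participant"` for the honest generalisation test.
* The sleep detector cannot see awakenings that leave the phone dark and
  untouched, and slightly over-counts sleep when light sampling is sparse
  (eligible no-data minutes adjacent to the true interval).
* Ordinal labels are treated as unordered classes; no ordinal-aware loss.
* The social level is within-person normalised and thus nearly
  uninformative for between-person group classification — visible in its
  low information-gain share.
* EMA answers are taken at face value; no response-quality modelling.
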