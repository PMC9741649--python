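# Methods

This note documents the models and procedures `wearqc` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

A recording holds one series per modality; a series is an ordered list of
contiguous segments (start time + samples at a fixed rate).  Data loss is
structural: absent samples are simply absent, never NaN-filled, because
completeness is defined by the presence and absence of samples.  Sample
timestamps are UTC; a per-recording `utc_offset` (signed hours) carries
local wall-clock time for day/night grouping.  ACC is stored in g (the
on-disk export uses integer counts at 1/64 g), EDA in μS, TEMP in °C, BVP
in the sensor's arbitrary units.

The device clock is trusted as recorded.  Sampling-rate drift (up to
roughly a second per hour on real hardware) is acknowledged, not
corrected; its only visible effect here is completeness ratios marginally
above 1, which are clamped (below).

## Completeness

Per modality: `N_rec / (F_s · (t_end − t_start))`; the recording-level
score is the unweighted mean over the modalities actually present, and the
recording duration is `max(N_rec / F_s)`.  Choices:

* A contiguous n-sample run spans `(n−1)/F_s`, so a gap-free series
  computes marginally above 1; values above 1 are clamped to 1 (a warning
  is logged only when the excess exceeds that bookkeeping, i.e. genuine
  rate drift).  A single-sample series is defined complete.
* The mean is over present modalities only: a channel that never recorded
  anything yields no ratio rather than a zero.
* Duration filters ("at least 1 h" inpatient, "at least 24 h" outpatient)
  are inclusive at the boundary and configurable.

## On-body detection

Per-sample in-range indicators — ACC activity ≥ 0.2 g, EDA ≥ 0.05 μS,
25 °C ≤ TEMP ≤ 40 °C, all boundaries inclusive — are aggregated per
1-minute window: a window is on-body for a modality iff at least
`window_min_fraction` (default 1%) of its *recorded* samples are in range;
a window with no recorded samples is `no_data` (gaps do not dilute the
fraction).  The combined status is `on` if at least one voting modality
says so (`any`; `majority` and `all` are available), `no_data` only when
every modality abstains.  Windows are aligned to wall-clock minutes (UTC)
so the on-body grid, the minute-score grid and the day/night grid
coincide.

* The ACC activity level is the moving standard deviation (population
  form, 10-s centered window, truncated at segment edges and computed per
  segment) of the per-sample sum x+y+z.  The 0.2 threshold is interpreted
  in g; it is configurable since the unit convention is a choice.
* The single rule "on iff ≥1% in range" is applied uniformly to all three
  modalities (equivalently: off iff more than 99% of samples are out of
  range).
* `onbody_fraction` is computed over scoreable (non-`no_data`) windows.

The `any` policy is deliberately sensitive: a still, cool wrist at night
is routinely rescued by the EDA vote.  Expect boundary effects of one to
two windows around off/on transitions — skin temperature decays into and
out of range with a sensor/skin lag, and the centered ACC window sees
across the boundary.

## Signal quality

**EDA/TEMP.**  Good iff the range test passes AND the 2-s-window RAC is
below 0.2 (logical conjunction).  RAC windows are non-overlapping and
aligned to each segment's start; a trailing partial window is evaluated on
the samples it has; all samples of a window inherit its RAC.  Tie-breaks:
a constant window has RAC 0 (max = min); with repeated extremes the first
occurrence index of the maximum is compared against that of the minimum;
a zero denominator with a nonzero swing gives +∞ (always bad).  RAC is
computed on raw values, no detrending.

**BVP.**  Normalized spectral entropy per 4-s window at 50% overlap.  Each
window's power spectrum is a Welch-style average of its own Hann
periodogram and its two 50%-overlapping neighbors (`bvp_spectrum_avg = 3`,
truncated at segment edges).  The in-band (0.1–5 Hz, 20 bins at 64 Hz)
mass is normalized to a probability vector and the entropy
`−Σ p log p / log(#bins)` lies in [0, 1].  Window values sit at window
centers and are linearly interpolated to every sample time with constant
extrapolation at segment edges.  Samples with entropy strictly above 0.8
are poor; segments shorter than one window have no computable entropy and
count as bad rather than missing — unusable signal is the condition the
score measures.

Why the neighbor averaging: with only 20 in-band bins, the plug-in entropy
of a *single* periodogram of white noise concentrates near 0.87, not the
theoretical endpoint 1 (the per-bin power of noise is exponentially
distributed, which depresses `−Σ p log p` by roughly `1 − γ` nats
regardless of window choice).  Averaging three overlapped periodograms
shrinks that bias (white noise ≈ 0.94, minimum ≈ 0.91 across windows)
while leaving a pure in-band tone at ≈ 0.29 and a clean synthetic pulse at
≈ 0.45, and it makes broadband motion windows sit more reliably above the
0.8 cutoff.  A window with zero in-band power (an exactly flat signal) is
assigned entropy 1.0: it has no distinguishable spectral structure and
must not score as a clean tone.

**Minute scores.**  Per worn minute and modality, the score is the
fraction of good samples among recorded samples — equivalently 1 minus the
bad fraction, so aggregation order is irrelevant.  Minutes that are
off-body or `no_data`, and minutes without recorded samples of a modality,
are missing (NaN), never zero: quality is defined only where the device
was worn.

## Aggregation and comparison

Recording summaries carry completeness, on-body and quality percentages
(over non-missing minutes) plus duration and metadata.  Cohort statistics
(mean, median, sample std, min, max) ignore missing values; a single
recording has std 0 by convention.  Every recording weighs equally — no
duration weighting — matching per-participant-then-per-cohort averaging.
Recordings are the default unit; collapsing multiple recordings per
patient is available via `patient_ids`.

Day/night assigns each minute by its local start time, day iff
08:00 ≤ t < 20:00 (half-open, so the partition is exhaustive and
disjoint); the default day/night comparison uses per-recording mean scores
as the samples.  Group comparison is the pooled-variance (Student)
two-sample t-test with `df = n_a + n_b − 2`, two-sided; Welch's form is a
flag.  Degenerate inputs: identical zero-variance groups give t = 0,
p = 1; zero variance with distinct means is an error.

## Synthetic recordings

The generator produces the signal structure the metrics assume, at nominal
rates, from a single seeded generator (identical seed ⇒ bit-identical
output):

* BVP: three harmonics of a 72-bpm beat with slow sinusoidal rate
  variability plus small Gaussian noise (spectral entropy ≈ 0.45).
* EDA: 2 μS tonic level with slow wander, Poisson phasic responses
  (default 2/min, 0.05–0.25 μS, ~0.75-s rise / 4-s recovery) — fast
  enough to look phasic, small enough to stay under the RAC screen.
* TEMP: 33 °C base with a ±0.5 °C two-hour drift.
* ACC: gravity plus small noise at rest; Poisson activity bouts
  (default 6/h, 1–3 min) with 0.3-g noise.

Injectable artifacts with ground-truth extents: `off_body` (EDA → 0, TEMP
relaxes exponentially toward 22 °C ambient with a 60-s time constant —
300 s to re-warm — BVP → broadband noise, ACC frozen; an off interval
starting at t = 0 starts at ambient), `gap` (samples deleted, segments
split), `motion` / `translation_rotation` (broadband and, for the latter,
rhythmic components on BVP and ACC, plus EDA fluctuations), `light`
(broadband plus slow swing on BVP only).  The diurnal preset starts at
local midnight and injects motion bouts only into daytime hours.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: physiologically validated waveform morphology,
skin-color or sensor-hardware effects, ambient-temperature seasonality,
clock drift, device-intrinsic electrical artifacts, or seizure events.
The generator demonstrates that the metrics recover known injected
structure, not that the thresholds are clinically optimal.

## Problem sizes

Tests and the acceptance script run on desk-scale sessions chosen so every
claim is still exercised at its natural scale: 1-hour sessions for
completeness/on-body recovery, a 48-hour diurnal fixture for the day/night
partition (2 × 1440 minutes), a battery of six 24-hour diurnal recordings
for the day/night comparison, and 50–100 seeded series for the windowed
statistic oracles.

## Known limitations

* On-body status and minute scores are undefined (not zero) without
  recorded samples, so heavily gapped recordings can have high quality
  percentages over very little data; always read them next to
  completeness.
* RAC follows the stated formula literally; its denominator is a raw
  signal value, so the screen is scale-dependent (appropriate for μS and
  °C, not for arbitrary units).
* The entropy screen cannot distinguish rhythmic motion artifacts from a
  clean pulse when the artifact is strongly periodic in-band; the
  `translation_rotation` generator kind exists precisely to expose this.
* Timestamps are taken at face value; no clock-drift correction.
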