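# wearqc

Data-quality assessment for multimodal wrist-worn biosignal recordings.

Long-term wearable studies — seizure monitoring in epilepsy being the
motivating case — record four raw modalities from a wrist (or ankle)
device: tri-axial accelerometry (ACC, 32 Hz, ±2 g), electrodermal activity
(EDA, 4 Hz, μS), blood volume pulse (BVP, the raw photoplethysmography
output, 64 Hz) and peripheral skin temperature (TEMP, 4 Hz, °C).  Before
any downstream analysis, three questions need quantitative answers: how
much of the expected data was actually recorded, when was the device
actually worn, and how good is the worn-time signal?  `wearqc` answers all
three for Empatica-E4-style CSV session archives, and ships a seeded
synthetic-recording generator so every metric is testable without patient
data.

## The metrics

**Data completeness** is strictly about the presence of samples.  Per
modality, with `N_rec` recorded samples, sample rate `F_s` and first/last
sample times `t_start`/`t_end`:

    completeness = mean_over_modalities( N_rec / (F_s · (t_end − t_start)) )
    duration     = max_over_modalities( N_rec / F_s )

**On-body detection** estimates, per 1-minute window, whether the device
was worn, from the three modalities with a defined off-body signature:
ACC activity (10-s moving standard deviation of the axis sum) ≥ 0.2 g,
EDA ≥ 0.05 μS, TEMP within 25–40 °C.  A window is on-body for a modality
if at least 1% of its recorded samples are in range; by default the device
counts as worn if at least one modality votes on-body.  BVP is excluded —
off the body its output is a function of ambient light.

**Signal quality** is scored per sample and averaged per worn minute into
scores in [0, 1]:

* *EDA and TEMP* — the range test above, AND a rate-of-amplitude-change
  (RAC) screen: per 2-s window, `RAC = (max − min) / d` with `d` whichever
  extreme occurs first; RAC ≥ 0.2 (a >20% swing in 2 s, faster than
  physiology) marks the window's samples bad.
* *BVP* — normalized spectral entropy of 4-s windows restricted to
  0.1–5 Hz: ≈0 for a clean quasi-periodic pulse, ≈1 for broadband
  motion/light noise.  Entropy > 0.8 marks samples poor.

Minute scores aggregate to one row per recording (the quality percentages
are relative to worn time only) and to cohort tables
(mean/median/std/min/max per metric), with day/night (local 08:00–20:00
vs. the rest) and placement groupings compared by a two-tailed two-sample
t-test.

## Worked example

Generate a 30-minute synthetic session whose first 5 minutes are off-body,
then score it:

```sh
wearqc simulate -o demo_session --duration 1800 --seed 9 --offbody 0:300
wearqc score demo_session -o demo_scores
```

`demo_scores/summary.json` contains (abridged):

```json
{
 "completeness_pct": 100.0,
 "onbody_pct": 83.33333333333334,
 "eda_pct": 100.0,
 "bvp_pct": 100.0,
 "temp_pct": 93.25,
 "duration_s": 1800.0
}
```

Reading: no samples were lost (completeness 100%), 25 of the 30 minutes
were recognized as worn (83.3%), and on those worn minutes EDA and BVP are
fully clean while TEMP scores 93.25% — the skin-temperature sensor needs a
couple of minutes to re-warm from ambient after the device goes back on,
and those below-25 °C samples are flagged.  The per-minute detail is in
`demo_scores/minutes.csv`:

```
window_start_iso,onbody,eda_score,bvp_score,temp_score
2020-09-14 00:04:00+00:00,off,,,
2020-09-14 00:05:00+00:00,on,1.0,1.0,0.0
2020-09-14 00:06:00+00:00,on,1.0,1.0,0.3125
2020-09-14 00:07:00+00:00,on,1.0,1.0,1.0
```

`wearqc report SESSION...` aggregates several sessions into a cohort table
(with duration filtering: ≥1 h inpatient, ≥24 h outpatient) plus
day-vs-night comparisons; `wearqc simulate --preset suite` writes the
annotated fixture battery.  Every report embeds the full effective
configuration — all thresholds are overridable via `--config config.yaml`.

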