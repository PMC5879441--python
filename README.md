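# circarhythm

Non-parametric circadian rhythm analysis for multichannel wrist-worn
(ambulatory circadian monitoring, ACM) recordings, aimed at quantifying the
sleep, motor, and autonomic rhythm disruption seen in Parkinson's disease
(PD) and other chronodisrupted states.

A week of wear produces 30-s epochs of wrist skin temperature (WT),
integrated triaxial acceleration, time in movement, x/y/z tilt, and light
exposure. From these the package computes, per subject:

- **IS** (interdaily stability, 0–1) — day-to-day reproducibility of the
  24-h pattern: `IS = [N Σ_h (x̄_h − x̄)²] / [p Σ_i (x_i − x̄)²]`, with
  `x̄_h` the mean of clock bin *h* across days (`p` bins/day, hourly by
  default) and the denominator over all `N` valid epochs.
- **IV** (intradaily variability, 0–2) — rhythm fragmentation:
  `IV = [N Σ (x_i − x_{i−1})²] / [(N−1) Σ (x_i − x̄)²]` over consecutive
  valid epoch pairs at native 30-s resolution.
- **M10V/M10T, L10V/L10T, M5V/M5T, L5V/L5T** — mean value and midpoint
  timing of the most/least extreme 10- or 5-hour circular windows of the
  mean 24-h waveform (M10/L5 for activity and light, M5/L10 for WT and
  sleep, which peak at night).
- **RA** (relative amplitude) — `(high − low) / (Pc95 − Pc5)` against
  normative 95th/5th percentiles (temperature 35/30 °C, acceleration 40/1,
  time in movement 200/2 counts, light 3/0 log lux, sleep 1/0), clamped to
  [0, 1].
- **CFI** (circadian function index) — `(IS + (2 − IV)/2 + RA) / 3`;
  1 means a high-amplitude, unfragmented, stable rhythm.
- **A/T ratio** — acceleration M10V ÷ time-in-movement L5V: vigorous days
  over quiet nights. Low values combine bradykinesia with fragmented
  sleep, the two hallmark PD alterations.
- **TAP sleep scoring** — the epoch-wise mean of intra-subject-normalized
  inverted WT (Temperature), time in movement (Activity), and x-tilt
  variability (Position); low TAP marks sleep, from which sleep episodes,
  the main nightly rest interval, actual sleep time, and sleep-probability
  waveforms follow.
- **Classification** — Shannon information-gain feature ranking,
  Fayyad–Irani MDL discretization, decision stumps/trees, and stratified
  k-fold cross-validation (sensitivity, specificity, accuracy, F1, AUROC),
  via scikit-learn-compatible `MDLDiscretizer` and
  `InfoGainTreeClassifier` estimators.

Because device recordings of this kind are not publicly deposited, the
package ships a seeded synthetic-cohort generator
(`circarhythm.synthetic`) whose "control" and "pd" presets encode the
published group contrasts (cool nocturnal WT plateau, reduced diurnal
acceleration, restless fragmented nights, phase jitter); every downstream
stage is tested end-to-end against it.

## Worked example

```python
import circarhythm as cr
from circarhythm.tap_sleep import tap_score, detect_sleep

for name, prof, seed in [("control", cr.control_profile(), 1),
                         ("PD", cr.pd_profile(), 2)]:
    rec = cr.generate_subject(prof, seed=seed, days=7, subject_id=name)
    sleep = detect_sleep(tap_score(rec), start=rec.start)
    idx = cr.compute_indices(rec, sleep=sleep)
    wt = idx.per_channel["wrist_temperature"]
    acc = idx.per_channel["acceleration"]
    tim = idx.per_channel["time_in_movement"]
    print(f"{name}: WT M5V={wt.windows['M5'].value:.2f} degC  "
          f"acc M10V={acc.windows['M10'].value:.2f}  "
          f"tim L5V={tim.windows['L5'].value:.2f}  "
          f"A/T={idx.at_ratio:.2f}  overall CFI={idx.overall_CFI:.2f}  "
          f"sleep={sleep.mean_actual_sleep_hours:.2f} h")
```

prints

```
control: WT M5V=34.56 degC  acc M10V=22.65  tim L5V=6.07  A/T=3.73  overall CFI=0.79  sleep=6.78 h
PD: WT M5V=33.65 degC  acc M10V=13.41  tim L5V=35.84  A/T=0.37  overall CFI=0.62  sleep=6.11 h
```

The PD-like subject has a cooler sleep-time wrist temperature (M5V), about
half the diurnal acceleration (M10V), six times the nocturnal movement
(L5V, in 0.1-s counts/epoch), and consequently an order-of-magnitude lower
A/T ratio and a depressed circadian function index — the same directions
that separate patients from controls clinically. On the default 12 + 12
synthetic cohort a depth-1 tree on A/T alone reaches perfect 10-fold
cross-validated accuracy.

The same pipeline is scriptable from a shell:

```sh
circarhythm simulate --n-pd 12 --n-control 12 --seed 7 --out cohort/
circarhythm indices cohort/*.csv --out indices.csv
circarhythm sleep cohort/*.csv --out sleep.csv
circarhythm report --seed 7 --out report/
```

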