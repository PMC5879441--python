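# Methods

## Data model

A `Recording` holds one subject's week of 30-s epochs: a dict of
equal-length float channels, a boolean validity mask, and a naive local
start timestamp (recordings spanning a DST change are rejected rather than
resampled; subjects are monitored in single one-week windows). Masked
epochs are excluded from every downstream statistic. Day folding
(`to_day_matrix`) is midnight-to-midnight with masked padding for partial
first/last days; because extreme-window searches are circular, the day
boundary does not bias M/L statistics.

Units: wrist temperature in °C (valid range 15–45), time in movement in
seconds per epoch (0–30; files storing the device's native 0.1-s counts
declare so in the dialect and are converted on ingest), acceleration in
the device's integrated per-epoch unit, tilt in degrees, light in lux.
Two analysis-scale transforms are applied inside the metrics layer only:
light is analyzed as log10(lux + 1) (the +1 keeps darkness finite), and
time in movement is converted to 0.1-s counts (×10) so that its window
values and the A/T ratio are commensurate with the normative reference
percentiles (200/2), which are defined on the count scale.

Off-wrist detection: the wearable literature gives no standard rule, so
the package masks runs of ≥ 10 min (20 epochs) in which temperature is
below a configurable floor (default 27 °C) **and** time in movement is
zero. The conjunction avoids masking cold-but-worn periods; masking is
monotone (never unmasks).

## Non-parametric circadian indices

**IS** uses hourly clock bins in the numerator over the raw-epoch total
variance: `IS = [N Σ_h (x̄_h − x̄)²] / [p Σ_i (x_i − x̄)²]`. With hourly
bins each `x̄_h` pools n_days × 120 epochs, so white noise drives IS to
order p/N ≈ 0.001 for a week of 30-s data — matching the "0 for Gaussian
noise" limit — while a day-identical, within-hour-constant template
scores exactly 1. (Had the numerator bins equaled the epoch resolution,
white-noise IS would be pinned at 1/n_days ≈ 0.14 regardless of data.)
Smooth rhythms with within-hour structure score slightly below 1 even
when days repeat exactly; `bin_minutes` is configurable for sensitivity
analyses.

**IV** is computed at native 30-s resolution over consecutive valid
pairs: `IV = [N Σ (x_i − x_{i−1})²] / [(N−1) Σ (x_i − x̄)²]`, clamped to
[0, 2]. Fine sampling matters: the very small IV of a smooth temperature
rhythm (order 10⁻³) is unattainable at hourly sampling. For a sampled
sinusoid the expected value is 2(1 − cos ω); the finite-series boundary
term vanishes exactly when the phase satisfies 2φ − ω = π/2, which the
closed-form test exploits.

**Extreme windows** are searched over all circular start bins of the
across-day mean waveform at 30-s bins, via cumulative sums; ties break
toward the earliest start after midnight (determinism), and the reported
timing is the window midpoint (M5T is conventionally the midpoint of the
sleep period). Missing waveform bins are filled by circular linear
interpolation before the search so that windows remain computable on
masked recordings.

**RA** is (high − low)/(Pc95 − Pc5) with the orientation-appropriate
window pair, clamped to [0, 1]: individuals can exceed normative
percentiles, and clamping keeps CFI within [0, 1]. RA is invariant to
affine rescaling applied simultaneously to data and references.

**CFI** = (IS + (2 − IV)/2 + RA)/3. Linearity makes the group-mean CFI
equal the CFI of group-mean components, which is why published group
tables are internally consistent up to per-subject rounding (two cells in
the source table deviate by 0.01 for exactly that reason).

**A/T** divides acceleration M10V by time-in-movement L5V (count scale).
A perfectly still synthetic sleeper yields L5V = 0; the divisor accepts a
configurable epsilon (default 0, raising instead), used only where
degenerate noise-free profiles are analyzed.

## TAP sleep scoring

Components: inverted WT (distal skin warms during rest via autonomic
vasodilation), time in movement, and per-epoch absolute x-tilt change.
Each is min–max scaled between the subject's own 5th/95th percentiles
(robust to spikes, invariant to channel gain/offset) and clamped; TAP is
their arithmetic mean, 0 = rest, 1 = active wake. The sleep threshold is
configurable with default 0.5 on the normalized scale; this default is
calibrated on the synthetic generator (≥ 95 % epoch agreement against
ground truth on both presets), not a device constant — the originally
validated threshold and normalization constants are not public. TAP is
median-smoothed over 5 min, runs shorter than 10 min are dropped, and the
main rest interval of each noon-to-noon night is the longest cluster of
episodes separated by < 60 min of wake, which keeps "actual sleep time"
(summed sleep inside the interval, excluding latency and terminal wake by
construction) well-defined for fragmented nights.

## Synthetic cohort generator

The generator emulates the study conditions every downstream stage is
tested under: 7-day recordings, 12 + 12 cohorts, and presets whose
contrasts follow the published group directions. Control preset: WT
night plateau 34.6 °C over a 32.3 °C day base with a postprandial bump at
15:30, diurnal acceleration mean 22.6 (targeting M10V ≈ 22.6), nocturnal
time in movement 0.4 s/epoch (L5V near 5 counts), sleep 23:30–07:15 with
15 min day-to-day phase jitter, 1.5 brief arousals/night. PD preset: WT
plateau 33.9 °C (M5V ≈ 33.8), diurnal acceleration 13.6, nocturnal time
in movement 2.2 s/epoch (L5V ≈ 26 counts with arousal load), 40 min
jitter, 8 arousals/night weighted 3:1 to the second half of the night
with early-morning light exposure, and daytime naps — the published
fragmentation phenotype. Where the literature states no value (nap and
arousal durations, tilt levels, light levels, noise scales), values were
chosen once as physiologically plausible and documented here.

Mechanics: nightly sleep intervals are jittered per night and turned into
a continuous sleep drive by logistic ramps of configurable width (default
30 min — the anticipatory WT rise); WT carries AR(1) noise (lag-1 0.9,
temperature is smooth), activity channels carry independent truncated
normal noise (activity is spiky); during arousals activity jumps to
day-like values, WT dips 0.5 °C, and posture varies. The generator can
return its ground-truth sleep mask (programmed sleep plus naps, minus
arousals) for validating sleep scoring. `degrade_to_chronodisrupted`
interpolates every parameter monotonically toward a flat-rhythm extreme
(night = day levels, heavy jitter/arousals/naps), modeling progressive
chronodisruption and, run backwards, rhythm recovery under treatment.

What the generator does *not* model: mechanistic thermoregulation or gait,
raw 10-Hz accelerometry, weekday/weekend structure, seasonal light, or
device artifacts beyond masking. Passing tests therefore demonstrate
correctness of the analysis pipeline and the internal consistency of the
indices under realistic contrast structure — not clinical performance on
real patients; the published cohort's recordings are not available, so
group-level numbers here are a scaled stand-in, and only directions and
separability are asserted.

## Classification

Candidate cuts are Fayyad boundary points (midpoints between adjacent
distinct values with differing class mixtures); a cut is accepted iff
its information gain exceeds `[log2(N−1) + log2(3^k − 2) − k·H(S) +
k1·H(S1) + k2·H(S2)] / N`, recursing on both sides; gain ties break
toward the lower cut value for determinism. The tree is greedy top-down
over (feature, MDL cut) pairs; depth 1 yields the single-attribute
threshold stumps from which clinical cut-offs are read. Cross-validation
is stratified with discretization and splits refit per training fold
(no test leakage, asserted by an outlier-injection test); the pooled
confusion matrix uses PD as the positive class. Because a hard stump's
ROC is degenerate, AUROC ranks subjects by a continuous score — the raw
feature value (orientation learned from the training fold) or the tree's
leaf purity.

Group comparisons are unpaired (distinct patients and controls): Welch
t-test when both groups pass Shapiro–Wilk, Mann–Whitney U otherwise, with
the chosen test recorded in the result. Bonferroni correction takes
`n_tests` explicitly at the call site (0.05/6 ≈ 0.008 for the usual six
comparisons).

## Problem sizes and determinism

Default simulations are 7 days × 2880 epochs per subject and 12 + 12
subjects per cohort — the full study scale, which the vectorized pipeline
analyzes in about a second. All randomness flows from
`numpy.random.default_rng` seeds; cohorts derive per-subject streams from
a `SeedSequence`, so identical specs reproduce byte-identical outputs.

## Known limitations

- IS of smooth rhythms saturates slightly below 1 at hourly binning (see
  above); comparisons across binnings should hold `bin_minutes` fixed.
- The TAP threshold default is generator-calibrated; on real device data
  it should be re-validated (ideally against polysomnography).
- The native export layout of commercial ACM devices is undocumented; the
  epoch-CSV dialect here is the package's own, with a mapping hook for
  other column orders.
- Nap-vs-rest disambiguation relies solely on the TAP threshold; quiet
  wakefulness in bed can score as sleep.
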