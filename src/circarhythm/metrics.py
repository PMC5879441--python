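"""Non-parametric circadian rhythm analysis.

Implements the classical actigraphy indices on masked 30-s epoch data:

* **IS** (interdaily stability): day-to-day reproducibility of the 24-h
  pattern, 0 for Gaussian noise up to 1 when the rhythm repeats exactly.
  ``IS = [N * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2]``
  with ``p`` clock bins per day and ``xbar_h`` the across-day mean of bin h.
* **IV** (intradaily variability): rhythm fragmentation from squared first
  differences, 0 for a smooth rhythm up to ~2 for Gaussian noise.
  ``IV = [N * sum (x_i - x_{i-1})^2] / [(N-1) * sum (x_i - xbar)^2]``
  over valid consecutive epoch pairs.
* **M/L windows**: mean value (V) and midpoint timing (T) of the most
  (M) / least (L) active 10 or 5 consecutive hours of the mean 24-h
  waveform, searched circularly.
* **RA** (relative amplitude): day-night contrast normalized by population
  95th/5th percentile spread — ``(high - low) / (pc95 - pc5)``, using
  M10/L5 for diurnal-active channels (activity, light) and M5/L10 for
  nocturnal-active ones (skin temperature, sleep), clamped to [0, 1].
* **CFI** (circadian function index): ``(IS + (2 - IV)/2 + RA) / 3``,
  1 = high-amplitude, unfragmented, stable rhythm.
* **A/T ratio**: acceleration M10V divided by time-in-movement L5V — high
  when days are vigorous and nights are quiet.

IV is computed on native 30-s epochs (the tiny IV of a smooth temperature
rhythm, order 0.003, is only attainable at that resolution); IS pools
hourly clock bins in its numerator, the classical convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acm_io import (
    ANALYSIS_CHANNELS,
    EPOCHS_PER_DAY,
    DayMatrix,
    Recording,
    to_day_matrix,
)

__all__ = [
    "WaveformProfile", "WindowStat", "ReferenceRange", "CircadianIndices",
    "DEFAULT_REFERENCES", "mean_waveform", "interdaily_stability",
    "intradaily_variability", "extreme_window", "relative_amplitude",
    "circadian_function_index", "at_ratio", "compute_indices",
]


class DegenerateInputError(ValueError):
    """The input carries no usable variance (constant or empty)."""


@dataclass
class WaveformProfile:
    """Mean 24-h waveform of one channel: per-clock-bin mean and SEM."""

    channel: str
    bin_minutes: float
    mean: np.ndarray
    sem: np.ndarray
    n_days: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if len(self.mean) * self.bin_minutes != 1440:
            raise ValueError("waveform length inconsistent with binning")

    @property
    def n_bins(self) -> int:
        return len(self.mean)


@dataclass
class WindowStat:
    """Mean value and midpoint clock time of an extreme circadian window."""

    kind: str  # "M10" | "L10" | "M5" | "L5"
    value: float
    midpoint_hours: float  # clock time of the window center, [0, 24)

    @property
    def midpoint_hhmm(self) -> str:
        h = int(self.midpoint_hours) % 24
        m = int(round((self.midpoint_hours % 1) * 60)) % 60
        return f"{h:02d}:{m:02d}"


@dataclass(frozen=True)
class ReferenceRange:
    """Population 95th/5th percentile constants normalizing RA.

    ``orientation`` selects the window pair: ``"diurnal-active"`` channels
    (activity, light) peak by day, so RA = (M10V - L5V)/(pc95 - pc5);
    ``"nocturnal-active"`` channels (skin temperature, sleep) peak at night,
    so RA = (M5V - L10V)/(pc95 - pc5).
    """

    channel: str
    pc95: float
    pc5: float
    orientation: str = "diurnal-active"

    def __post_init__(self):
        if self.pc95 <= self.pc5:
            raise ValueError("pc95 must exceed pc5")
        if self.orientation not in ("diurnal-active", "nocturnal-active"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


#: Reference percentiles from a 90-adult normative population, as used to
#: normalize relative amplitude.  Light is on the log10(lux + 1) scale and
#: time in movement on the device's 0.1-s count scale (see compute_indices).
DEFAULT_REFERENCES: dict[str, ReferenceRange] = {
    "wrist_temperature": ReferenceRange(
        "wrist_temperature", 35.0, 30.0, "nocturnal-active"),
    "acceleration": ReferenceRange("acceleration", 40.0, 1.0),
    "time_in_movement": ReferenceRange("time_in_movement", 200.0, 2.0),
    "light_visible": ReferenceRange("light_visible", 3.0, 0.0),
    "sleep_probability": ReferenceRange(
        "sleep_probability", 1.0, 0.0, "nocturnal-active"),
}


@dataclass
class ChannelIndices:
    """All indices of one channel."""

    channel: str
    IS: float
    IV: float
    windows: dict[str, WindowStat]
    RA: float
    CFI: float
    mean: float


@dataclass
class CircadianIndices:
    """Per-channel and overall circadian indices of one recording."""

    subject_id: str
    per_channel: dict[str, ChannelIndices]
    overall_IS: float
    overall_IV: float
    overall_RA: float
    overall_CFI: float
    at_ratio: float
    label: str | None = None


def mean_waveform(matrix: DayMatrix, bin_minutes: float = 0.5) -> WaveformProfile:
    """Average a day matrix over days into one 24-h profile (mean +- SEM).

    SEM is across days within each clock bin (sd/sqrt(n_days with data));
    bins with no valid epoch are NaN.
    """
    epochs_per_bin = int(round(bin_minutes * 2))
    if (bin_minutes <= 0 or abs(epochs_per_bin - bin_minutes * 2) > 1e-9
            or EPOCHS_PER_DAY % epochs_per_bin != 0):
        raise ValueError("bin_minutes must divide 1440 in 30-s steps")
    n_bins = EPOCHS_PER_DAY // epochs_per_bin

    vals = np.where(matrix.mask, matrix.values, np.nan)
    # (days, bins, epochs_per_bin)
    v = vals.reshape(matrix.n_days, n_bins, epochs_per_bin)
    with np.errstate(invalid="ignore"):
        day_bin = np.nanmean(v, axis=2)  # per-day per-bin mean
        counts = np.isfinite(vals).reshape(
            matrix.n_days, n_bins, epochs_per_bin).sum(axis=2)
        # pooled mean over all valid epochs of all days (weights = counts)
        tot = np.nansum(np.where(np.isfinite(day_bin), day_bin * counts, 0.0),
                        axis=0)
        n_ep = counts.sum(axis=0)
        mean = np.where(n_ep > 0, tot / np.maximum(n_ep, 1), np.nan)
        n_days_bin = np.isfinite(day_bin).sum(axis=0)
        sd = np.full(n_bins, np.nan)
        ok = n_days_bin > 1
        if ok.any():
            sd[ok] = np.nanstd(day_bin[:, ok], axis=0, ddof=1)
        sem = np.where(n_days_bin > 1, sd / np.sqrt(np.maximum(n_days_bin, 1)),
                       np.where(n_days_bin == 1, 0.0, np.nan))
    return WaveformProfile(
        channel=matrix.channel,
        bin_minutes=bin_minutes,
        mean=mean,
        sem=sem,
        n_days=matrix.n_days,
    )


def interdaily_stability(matrix: DayMatrix, bin_minutes: float = 60.0) -> float:
    """Day-to-day stability of the 24-h pattern, clamped to [0, 1].

    ``IS = [N * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2]``
    where ``xbar_h`` is the pooled mean of clock bin h across days
    (``p = 1440/bin_minutes`` bins, hourly by default as in the classical
    non-parametric literature) and the denominator runs over all N valid
    epochs.  1 when every day repeats the same hourly pattern; for white
    noise the hourly bin means shrink with the epochs behind them, driving
    IS toward 0 (order p/N ~ 0.001 for a week of 30-s epochs).
    """
    epochs_per_bin = int(round(bin_minutes * 2))
    if (bin_minutes <= 0 or abs(epochs_per_bin - bin_minutes * 2) > 1e-9
            or EPOCHS_PER_DAY % epochs_per_bin != 0):
        raise ValueError("bin_minutes must divide 1440 in 30-s steps")
    vals = np.where(matrix.mask, matrix.values, np.nan)
    if np.isfinite(vals).any(axis=1).sum() < 2:
        raise DegenerateInputError("IS needs at least 2 days with data")
    x = vals[np.isfinite(vals)]
    n = x.size
    xbar = x.mean()
    sstot = ((x - xbar) ** 2).sum()
    if sstot == 0:
        raise DegenerateInputError("constant series has undefined IS")
    n_bins = EPOCHS_PER_DAY // epochs_per_bin
    binned = vals.reshape(matrix.n_days, n_bins, epochs_per_bin)
    with np.errstate(invalid="ignore"):
        hbar = np.nanmean(binned.reshape(-1, n_bins, epochs_per_bin)
                          .transpose(1, 0, 2).reshape(n_bins, -1), axis=1)
    hbar = hbar[np.isfinite(hbar)]
    p = hbar.size
    ss_h = ((hbar - xbar) ** 2).sum()
    return float(np.clip((n * ss_h) / (p * sstot), 0.0, 1.0))


def intradaily_variability(
    values: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Fragmentation index from squared first differences, clamped to [0, 2].

    Only consecutive valid epoch pairs contribute to the numerator; ~0 for
    a smooth rhythm, ~2 for white noise.
    """
    x = np.asarray(values, dtype=float)
    m = np.ones_like(x, bool) if mask is None else np.asarray(mask, bool)
    m = m & np.isfinite(x)
    xv = x[m]
    n = xv.size
    if n < 2:
        raise DegenerateInputError("IV needs at least 2 valid epochs")
    xbar = xv.mean()
    sstot = ((xv - xbar) ** 2).sum()
    if sstot == 0:
        raise DegenerateInputError("constant series has undefined IV")
    pair = m[1:] & m[:-1]
    d = x[1:][pair] - x[:-1][pair]
    if d.size == 0:
        raise DegenerateInputError("IV needs consecutive valid epochs")
    return float(np.clip((n * (d ** 2).sum()) / ((n - 1) * sstot), 0.0, 2.0))


def _interpolate_circular(y: np.ndarray) -> np.ndarray:
    """Fill NaN bins by circular linear interpolation."""
    bad = ~np.isfinite(y)
    if not bad.any():
        return y
    if bad.all():
        raise DegenerateInputError("waveform has no valid bins")
    n = len(y)
    idx = np.arange(n)
    good = ~bad
    # unwrap by tiling once on each side
    xg = np.concatenate([idx[good] - n, idx[good], idx[good] + n])
    yg = np.tile(y[good], 3)
    out = y.copy()
    out[bad] = np.interp(idx[bad], xg, yg)
    return out


def extreme_window(
    waveform: WaveformProfile, hours: float, mode: str
) -> WindowStat:
    """Best circular window of the mean waveform (M10/L10/M5/L5 search).

    Scans every circular start bin; the window value is the mean over
    ``hours`` consecutive hours, the reported timing is the window
    *midpoint* clock time.  Ties go to the earliest start after midnight.
    """
    if not 0 < hours < 24:
        raise ValueError("hours must lie in (0, 24)")
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    y = _interpolate_circular(np.asarray(waveform.mean, dtype=float))
    n = len(y)
    w = int(round(hours * 60 / waveform.bin_minutes))
    if w < 1 or w > n:
        raise ValueError("window does not fit the waveform resolution")
    # circular rolling means via cumulative sum of the tiled series
    c = np.concatenate(([0.0], np.cumsum(np.concatenate([y, y[: w - 1]]))))
    means = (c[w:] - c[:-w]) / w  # length n, start position i
    start = int(np.argmax(means) if mode == "max" else np.argmin(means))
    value = float(means[start])
    mid_bins = start + w / 2.0
    midpoint = (mid_bins * waveform.bin_minutes / 60.0) % 24.0
    kind = ("M" if mode == "max" else "L") + f"{int(round(hours))}"
    return WindowStat(kind=kind, value=value, midpoint_hours=midpoint)


def relative_amplitude(
    high: float | WindowStat, low: float | WindowStat, ref: ReferenceRange
) -> float:
    """Day-night contrast normalized by the reference percentile spread.

    ``high`` is M10V (diurnal-active) or M5V (nocturnal-active); ``low`` is
    the opposing L5V / L10V.  Clamped to [0, 1]: an individual may exceed
    the normative percentiles.
    """
    hv = high.value if isinstance(high, WindowStat) else float(high)
    lv = low.value if isinstance(low, WindowStat) else float(low)
    return float(np.clip((hv - lv) / (ref.pc95 - ref.pc5), 0.0, 1.0))


def circadian_function_index(IS: float, IV: float, RA: float) -> float:
    """Integrated chronodisruption score: mean of IS, inverted IV, and RA.

    IV is first inverted and rescaled from [0, 2] to [0, 1]; the result is
    (IS + (2 - IV)/2 + RA)/3, so 1 indicates a high-amplitude,
    non-fragmented, stable rhythm and values near 0 heavy chronodisruption.
    """
    if not 0 <= IS <= 1:
        raise ValueError("IS must lie in [0, 1]")
    if not 0 <= IV <= 2:
        raise ValueError("IV must lie in [0, 2]")
    if not 0 <= RA <= 1:
        raise ValueError("RA must lie in [0, 1]")
    return (IS + (2.0 - IV) / 2.0 + RA) / 3.0


def at_ratio(acc_m10v: float, tim_l5v: float, epsilon: float = 0.0) -> float:
    """A/T ratio: acceleration M10V over time-in-movement L5V.

    High values mean vigorous days and quiet nights.  A perfectly still
    sleeper yields L5V = 0; pass a small ``epsilon`` to regularize, or the
    call raises.
    """
    denom = tim_l5v + epsilon
    if denom == 0:
        raise ZeroDivisionError(
            "time-in-movement L5V is zero; pass epsilon > 0 to regularize"
        )
    return float(acc_m10v) / denom


_TRANSFORMS = {
    # light is analyzed in log lux; +1 keeps darkness (0 lux) finite
    "light_visible": lambda x: np.log10(x + 1.0),
    # metrics operate on the device's 0.1-s count scale for time in movement
    "time_in_movement": lambda x: x * 10.0,
}


def _window_pair(orientation: str) -> tuple[tuple[str, str], tuple[str, str]]:
    if orientation == "nocturnal-active":
        return ("M5", "max", 5), ("L10", "min", 10)
    return ("M10", "max", 10), ("L5", "min", 5)


def channel_day_matrix(recording: Recording, channel: str) -> DayMatrix:
    """Day matrix of an analysis channel on its analysis scale."""
    dm = to_day_matrix(recording, channel)
    f = _TRANSFORMS.get(channel)
    if f is not None:
        dm = DayMatrix(channel, f(dm.values), dm.mask)
    return dm


def compute_channel_indices(
    recording: Recording, channel: str, ref: ReferenceRange
) -> ChannelIndices:
    dm = channel_day_matrix(recording, channel)
    wf = mean_waveform(dm, bin_minutes=0.5)
    (hk, hmode, hh), (lk, lmode, lh) = _window_pair(ref.orientation)
    high = extreme_window(wf, hh, hmode)
    low = extreme_window(wf, lh, lmode)
    windows = {high.kind: high, low.kind: low}
    IS = interdaily_stability(dm)
    flat = dm.values.ravel()
    IV = intradaily_variability(flat, dm.mask.ravel())
    RA = relative_amplitude(high, low, ref)
    CFI = circadian_function_index(IS, IV, RA)
    valid = dm.values[dm.mask]
    return ChannelIndices(
        channel=channel, IS=IS, IV=IV, windows=windows, RA=RA, CFI=CFI,
        mean=float(valid.mean()) if valid.size else float("nan"),
    )


def compute_indices(
    recording: Recording,
    refs: dict[str, ReferenceRange] | None = None,
    sleep=None,
    at_epsilon: float = 0.0,
) -> CircadianIndices:
    """All circadian indices of one recording.

    The five analysis channels are wrist temperature, acceleration, time in
    movement, visible light (log10(lux+1)) and sleep probability.  The
    sleep channel is taken from ``sleep`` (a ``SleepScore``) if given, else
    from a precomputed ``sleep_probability`` channel on the recording; if
    neither exists it is TAP-scored on the fly.

    Overall indices are arithmetic means across the five channels; CFI is
    linear in (IS, IV, RA), so the overall CFI is also the CFI of the
    overall IS/IV/RA.
    """
    refs = dict(DEFAULT_REFERENCES if refs is None else refs)
    rec = recording
    if "sleep_probability" not in rec.channels:
        if sleep is None:
            from .tap_sleep import tap_score, detect_sleep
            sleep = detect_sleep(tap_score(rec))
        rec = rec.copy()
        rec.channels["sleep_probability"] = sleep.sleep.astype(float)
    elif sleep is not None:
        rec = rec.copy()
        rec.channels["sleep_probability"] = sleep.sleep.astype(float)

    per_channel: dict[str, ChannelIndices] = {}
    for ch in ANALYSIS_CHANNELS:
        if ch not in rec.channels:
            continue
        per_channel[ch] = compute_channel_indices(rec, ch, refs[ch])

    def _mean(attr: str) -> float:
        return float(np.mean([getattr(ci, attr) for ci in per_channel.values()]))

    acc = per_channel.get("acceleration")
    tim = per_channel.get("time_in_movement")
    at = float("nan")
    if acc is not None and tim is not None:
        at = at_ratio(acc.windows["M10"].value, tim.windows["L5"].value,
                      epsilon=at_epsilon)
    return CircadianIndices(
        subject_id=recording.subject_id,
        per_channel=per_channel,
        overall_IS=_mean("IS"),
        overall_IV=_mean("IV"),
        overall_RA=_mean("RA"),
        overall_CFI=_mean("CFI"),
        at_ratio=at,
        label=recording.label,
    )
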