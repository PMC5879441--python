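"""TAP sleep-wake scoring from wrist temperature, activity, and posture.

TAP averages three intra-subject-normalized signals per 30-s epoch:
inverted wrist skin Temperature (distal skin warms during rest through
autonomic vasodilation), time in movement (Activity), and the epoch-to-epoch
variability of the x-axis tilt (Position).  Each component is robustly
min-max scaled between the subject's own 5th and 95th percentiles, so 0
means complete rest and 1 full wakefulness; epochs where smoothed TAP falls
below a threshold are scored as sleep.

From the binary sleep series the module derives sleep episodes, the main
nightly rest interval (searched noon-to-noon so fragmented nights stay
well-defined), actual sleep time (excluding latency and terminal wake by
construction), and sleep-probability waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .acm_io import EPOCHS_PER_DAY, EPOCH_SECONDS, DayMatrix, Recording
from .metrics import DegenerateInputError, WaveformProfile, mean_waveform

__all__ = [
    "TapSeries", "SleepScore", "normalize_component", "tilt_variability",
    "tap_score", "detect_sleep", "sleep_probability",
]


@dataclass
class TapSeries:
    """Epoch-wise TAP values in [0, 1] with the three components."""

    values: np.ndarray  # NaN where masked
    components: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SleepScore:
    """Binary sleep series plus episode- and night-level summaries."""

    sleep: np.ndarray  # bool per epoch
    episodes: list  # (start_idx, end_idx_exclusive, duration_hours)
    main_rest_intervals: list  # per night: (start_idx, end_idx_exclusive)
    actual_sleep_hours: list  # per night
    mean_actual_sleep_hours: float
    start: pd.Timestamp = None
    probability_waveform: WaveformProfile | None = None


def normalize_component(
    series: np.ndarray,
    invert: bool = False,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Robust intra-subject min-max scaling to [0, 1].

    Values are scaled between the subject's own ``lo_pct`` and ``hi_pct``
    percentiles and clamped, which makes the result invariant to affine
    rescaling of the raw signal; ``invert=True`` returns 1 - scaled (used
    for temperature, which moves opposite to activity).
    """
    x = np.asarray(series, dtype=float)
    m = np.ones_like(x, bool) if mask is None else np.asarray(mask, bool)
    valid = x[m & np.isfinite(x)]
    if valid.size < 2 or np.unique(valid).size < 2:
        raise DegenerateInputError("constant series cannot be normalized")
    lo, hi = np.percentile(valid, [lo_pct, hi_pct])
    if hi == lo:  # degenerate percentile spread: fall back to full range
        lo, hi = valid.min(), valid.max()
    scaled = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return 1.0 - scaled if invert else scaled


def tilt_variability(tilt_x: np.ndarray) -> np.ndarray:
    """Per-epoch absolute change of the x-axis tilt angle (degrees).

    The first epoch is 0 by convention; the series sums to the total
    variation of the input.  Devices that already integrate tilting change
    per epoch can pass that channel straight to TAP instead.
    """
    t = np.asarray(tilt_x, dtype=float)
    if t.size < 2:
        raise DegenerateInputError("tilt variability needs >= 2 epochs")
    out = np.empty_like(t)
    out[0] = 0.0
    out[1:] = np.abs(np.diff(t))
    return out


def tap_score(
    recording: Recording,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> TapSeries:
    """Epoch-wise TAP: mean of normalized (1 - WT), activity, and posture.

    Masked epochs yield NaN TAP.  Raises if any component is constant,
    naming the offending signal.
    """
    mask = recording.mask
    comps = {}
    for name, raw, invert in (
        ("temperature", recording.channel("wrist_temperature"), True),
        ("activity", recording.channel("time_in_movement"), False),
        ("position", tilt_variability(recording.channel("tilt_x")), False),
    ):
        try:
            comps[name] = normalize_component(
                raw, invert=invert, lo_pct=lo_pct, hi_pct=hi_pct, mask=mask)
        except DegenerateInputError as err:
            raise DegenerateInputError(
                f"TAP component {name!r} is constant") from err
    values = (comps["temperature"] + comps["activity"] + comps["position"]) / 3.0
    values = np.where(mask, values, np.nan)
    return TapSeries(values=values, components=comps, mask=mask.copy())


def _runs(binary: np.ndarray):
    """(start, end-exclusive) index pairs of True runs."""
    padded = np.concatenate(([False], binary, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_sleep(
    tap: TapSeries,
    threshold: float = 0.5,
    smooth_epochs: int = 10,
    min_episode_epochs: int = 20,
    start: pd.Timestamp | None = None,
    merge_gap_minutes: float = 60.0,
) -> SleepScore:
    """Score sleep from TAP and summarize episodes and nightly rest.

    TAP is median-smoothed over ``smooth_epochs`` (suppressing single-epoch
    flicker at 30-s resolution); epochs below ``threshold`` are sleep; runs
    shorter than ``min_episode_epochs`` are dropped.  The main rest
    interval of each noon-to-noon night is the longest cluster of episodes
    separated by less than ``merge_gap_minutes`` of wake; actual sleep time
    is the summed sleep (not the cluster span) inside it, so latency and
    terminal wake are excluded by construction.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if smooth_epochs < 1 or min_episode_epochs < 0:
        raise ValueError("smoothing parameters must be positive")
    x = tap.values.copy()
    # median filter ignores NaN poorly; fill masked epochs with wake (1)
    filled = np.where(np.isfinite(x), x, 1.0)
    smooth = median_filter(filled, size=smooth_epochs, mode="nearest")
    sleep = smooth < threshold
    sleep &= tap.mask

    episodes = []
    keep = np.zeros_like(sleep)
    hours_per_epoch = EPOCH_SECONDS / 3600.0
    for s, e in _runs(sleep):
        if e - s >= min_episode_epochs:
            keep[s:e] = True
            episodes.append((int(s), int(e), (e - s) * hours_per_epoch))
    sleep = keep

    # nightly main rest intervals in noon-to-noon frames
    n = len(sleep)
    start = pd.Timestamp(start) if start is not None else None
    if start is not None:
        first_noon_off = (
            (start.normalize() + pd.Timedelta(hours=12) - start)
            .total_seconds() / EPOCH_SECONDS
        )
        first_noon = int(first_noon_off) if first_noon_off > 0 else 0
    else:
        first_noon = 0
    gap_epochs = int(merge_gap_minutes * 60 / EPOCH_SECONDS)
    main_rest, actual = [], []
    bounds = list(range(first_noon, n, EPOCHS_PER_DAY))
    if not bounds or bounds[0] > 0:
        bounds = [0] + bounds
    for i, lo in enumerate(bounds):
        hi = bounds[i + 1] if i + 1 < len(bounds) else n
        eps = [(s, e) for s, e in _runs(sleep[lo:hi])]
        if not eps:
            continue
        # cluster episodes separated by < gap_epochs
        clusters, cur = [], [eps[0]]
        for s, e in eps[1:]:
            if s - cur[-1][1] < gap_epochs:
                cur.append((s, e))
            else:
                clusters.append(cur)
                cur = [(s, e)]
        clusters.append(cur)
        best = max(clusters, key=lambda c: sum(e - s for s, e in c))
        span = (lo + best[0][0], lo + best[-1][1])
        main_rest.append((int(span[0]), int(span[1])))
        actual.append(sum(e - s for s, e in best) * hours_per_epoch)

    waveform = None
    if start is not None:
        from .acm_io import Recording, to_day_matrix

        helper = Recording(
            subject_id="", start=start,
            channels={"sleep_probability": sleep.astype(float)},
            mask=tap.mask.copy())
        waveform = mean_waveform(
            to_day_matrix(helper, "sleep_probability"), bin_minutes=0.5)

    return SleepScore(
        sleep=sleep,
        episodes=episodes,
        main_rest_intervals=main_rest,
        actual_sleep_hours=actual,
        mean_actual_sleep_hours=float(np.mean(actual)) if actual else 0.0,
        start=start,
        probability_waveform=waveform,
    )


def sleep_probability(
    matrices: DayMatrix | list[DayMatrix], bin_minutes: float = 0.5
) -> WaveformProfile:
    """Fraction of valid days (or subjects) asleep per clock bin.

    Accepts one binary-sleep day matrix (per-subject waveform across days)
    or a list of them (group curve: unweighted mean of per-subject
    probability waveforms).
    """
    if isinstance(matrices, DayMatrix):
        return mean_waveform(matrices, bin_minutes=bin_minutes)
    profiles = [mean_waveform(m, bin_minutes=bin_minutes) for m in matrices]
    stack = np.vstack([p.mean for p in profiles])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        k = np.isfinite(stack).sum(axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
        sem = np.where(k > 1, sd / np.sqrt(np.maximum(k, 1)), 0.0)
    return WaveformProfile(
        channel="sleep_probability",
        bin_minutes=bin_minutes,
        mean=mean,
        sem=sem,
        n_days=len(profiles),
    )
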