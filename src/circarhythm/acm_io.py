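"""Recording data model, epoch CSV IO, off-wrist masking, and day alignment.

An ambulatory circadian monitoring (ACM) device integrates its raw sensor
streams into fixed 30-s epochs; a week of wear yields 20160 epochs per
channel.  Everything downstream (waveforms, circadian indices, sleep
scoring) operates on the :class:`Recording` produced here, with a boolean
validity mask that silently excludes off-wrist or unparseable epochs from
every statistic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_SECONDS = 30
EPOCHS_PER_DAY = 24 * 60 * 60 // EPOCH_SECONDS  # 2880
EPOCHS_PER_HOUR = 3600 // EPOCH_SECONDS  # 120

#: Channels every recording may carry.  ``sleep_probability`` is derived
#: (by TAP scoring), never read from a device file.
CHANNEL_NAMES = (
    "wrist_temperature",
    "acceleration",
    "time_in_movement",
    "tilt_x",
    "tilt_y",
    "tilt_z",
    "light_visible",
    "light_blue",
    "light_infrared",
    "sleep_probability",
)

#: The five channels on which the circadian characterization is based.
ANALYSIS_CHANNELS = (
    "wrist_temperature",
    "acceleration",
    "time_in_movement",
    "light_visible",
    "sleep_probability",
)

#: Default epoch-CSV column layout: CSV column name -> channel name.
DEFAULT_DIALECT = {
    "timestamp": "timestamp",
    "wt": "wrist_temperature",
    "acc": "acceleration",
    "tim": "time_in_movement",
    "tilt_x": "tilt_x",
    "tilt_y": "tilt_y",
    "tilt_z": "tilt_z",
    "lux_vis": "light_visible",
    "lux_blue": "light_blue",
    "lux_ir": "light_infrared",
    "mask": "mask",
}

_PHYSIO_RANGES = {
    "wrist_temperature": (15.0, 45.0),
    "time_in_movement": (0.0, 30.0),
}
_NONNEG = ("acceleration", "light_visible", "light_blue", "light_infrared")


class FormatError(ValueError):
    """A mandatory column is missing or a cell cannot be interpreted."""


class AlignmentError(ValueError):
    """Epoch timestamps are not on a 30-s grid."""


@dataclass
class Recording:
    """A masked, epoch-level multichannel recording for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the wearer.
    start : pandas.Timestamp
        Local clock time of the first epoch (naive; one recording never
        spans a DST change).
    channels : dict of str -> numpy.ndarray
        Equal-length float series, one per recorded channel.
    mask : numpy.ndarray of bool
        True where the epoch is valid (worn, parseable).
    label : str or None
        Optional class tag, e.g. ``"PD"`` or ``"control"``.
    """

    subject_id: str
    start: pd.Timestamp
    channels: dict[str, np.ndarray]
    mask: np.ndarray
    label: str | None = None
    epoch_seconds: int = EPOCH_SECONDS
    extras: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.mask)
        for name, series in self.channels.items():
            arr = np.asarray(series, dtype=float)
            if len(arr) != n:
                raise ValueError(
                    f"channel {name!r} has length {len(arr)}, mask has {n}"
                )
            self.channels[name] = arr
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError("epoch_seconds is fixed at 30")

    @property
    def n_epochs(self) -> int:
        return len(self.mask)

    @property
    def duration_days(self) -> float:
        return self.n_epochs * self.epoch_seconds / 86400.0

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=self.n_epochs, freq=f"{self.epoch_seconds}s"
        )

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not present in recording")
        return self.channels[name]

    def valid(self, name: str) -> np.ndarray:
        """Valid values of a channel (mask applied, NaN dropped)."""
        x = self.channel(name)
        return x[self.mask & np.isfinite(x)]

    def copy(self) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            start=self.start,
            channels={k: v.copy() for k, v in self.channels.items()},
            mask=self.mask.copy(),
            label=self.label,
            extras=dict(self.extras),
        )

    def validate(self) -> None:
        """Check physiological range invariants on valid epochs."""
        for name, (lo, hi) in _PHYSIO_RANGES.items():
            if name in self.channels:
                v = self.valid(name)
                if v.size and (v.min() < lo or v.max() > hi):
                    raise ValueError(
                        f"{name} outside [{lo}, {hi}] on valid epochs"
                    )
        for name in _NONNEG:
            if name in self.channels:
                v = self.valid(name)
                if v.size and v.min() < 0:
                    raise ValueError(f"{name} has negative valid values")


@dataclass
class DayMatrix:
    """One channel folded to (day, epoch-of-day), midnight at column 0."""

    channel: str
    values: np.ndarray  # (n_days, 2880)
    mask: np.ndarray  # same shape, True = valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 2 or self.values.shape[1] != EPOCHS_PER_DAY:
            raise ValueError(f"expected 2880 columns, got {self.values.shape}")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]


def read_recording(
    path,
    dialect: dict[str, str] | None = None,
    subject_id: str | None = None,
    label: str | None = None,
    tim_in_counts: bool = False,
) -> Recording:
    """Read an epoch-level delimited text file into a :class:`Recording`.

    Rows must be 30 s apart; a gap that is a larger multiple of 30 s is
    filled with masked epochs, any other spacing raises
    :class:`AlignmentError`.  Non-numeric cells mask their epoch.

    Parameters
    ----------
    path : path-like
        CSV file, optionally gzip-compressed (by extension).
    dialect : dict, optional
        CSV-column -> channel-name mapping; must map one column to
        ``"timestamp"``.  Defaults to the package's native layout.
    tim_in_counts : bool
        If True the file stores time in movement as 0.1-s counts
        (the device's native accumulator); converted to seconds on ingest.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    ts_cols = [c for c, ch in dialect.items() if ch == "timestamp"]
    if len(ts_cols) != 1:
        raise FormatError("dialect must map exactly one column to 'timestamp'")
    ts_col = ts_cols[0]

    df = pd.read_csv(path, dtype=str)
    for col in (ts_col,):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {ts_col!r}")

    times = pd.to_datetime(df[ts_col], format="ISO8601")
    if len(times) == 0:
        raise FormatError("empty recording file")
    start = times.iloc[0]

    offsets_s = (times - start).dt.total_seconds().to_numpy()
    steps = np.diff(offsets_s)
    if np.any(steps <= 0):
        raise AlignmentError("timestamps not strictly increasing")
    if np.any(np.mod(offsets_s, EPOCH_SECONDS) != 0):
        raise AlignmentError("epoch spacing is not a multiple of 30 s")
    idx = (offsets_s // EPOCH_SECONDS).astype(int)
    n = int(idx[-1]) + 1

    mask_col = next((c for c, ch in dialect.items() if ch == "mask"), None)
    mask = np.zeros(n, dtype=bool)
    file_mask = np.ones(len(df), dtype=bool)
    if mask_col is not None and mask_col in df.columns:
        file_mask = (
            df[mask_col].astype(str).str.strip().str.lower()
            .isin(("1", "true", "t"))
            .to_numpy()
        )

    def _cell(s) -> float:
        # float() is a correctly-rounded parser, so 17-significant-digit
        # output round-trips bit-exactly
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    channels: dict[str, np.ndarray] = {}
    bad = np.zeros(len(df), dtype=bool)
    for col, ch in dialect.items():
        if ch in ("timestamp", "mask") or col not in df.columns:
            continue
        vals = df[col].map(_cell).to_numpy(dtype=float)
        bad |= ~np.isfinite(vals) & df[col].notna().to_numpy()
        if ch == "time_in_movement" and tim_in_counts:
            vals = vals * 0.1
        full = np.full(n, np.nan)
        full[idx] = vals
        channels[ch] = full

    mask[idx] = file_mask & ~bad
    return Recording(
        subject_id=subject_id or str(path),
        start=start,
        channels=channels,
        mask=mask,
        label=label,
    )


def write_recording(recording: Recording, path) -> None:
    """Write a recording as the native epoch CSV (lossless roundtrip).

    One row per epoch: ISO-8601 timestamp, one column per present channel
    (full float precision via repr), and the mask as 0/1.
    """
    inverse = {ch: col for col, ch in DEFAULT_DIALECT.items()}
    data = {"timestamp": recording.timestamps().strftime("%Y-%m-%dT%H:%M:%S")}
    for ch, series in recording.channels.items():
        data[inverse.get(ch, ch)] = series
    data["mask"] = recording.mask.astype(int)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def apply_offwrist_mask(
    recording: Recording,
    temp_floor: float = 27.0,
    still_epochs: int = 20,
) -> Recording:
    """Mask sustained cold-and-still runs as time off the wrist.

    An epoch is a candidate when wrist temperature < ``temp_floor`` AND time
    in movement is zero; runs of at least ``still_epochs`` consecutive
    candidates are masked.  The conjunction avoids masking cold-but-worn
    periods; masking is monotone (never unmasks).
    """
    if not 15.0 <= temp_floor <= 35.0:
        raise ValueError("temp_floor must lie in [15, 35] degC")
    wt = recording.channel("wrist_temperature")
    tim = recording.channel("time_in_movement")
    cand = (wt < temp_floor) & (tim == 0)
    cand &= np.isfinite(wt) & np.isfinite(tim)

    out = recording.copy()
    # mask runs of >= still_epochs consecutive candidates
    padded = np.concatenate(([False], cand, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= still_epochs:
            out.mask[s:e] = False
    return out


def to_day_matrix(recording: Recording, channel: str) -> DayMatrix:
    """Fold one channel onto a (day, epoch-of-day) grid, midnight first.

    Partial first/last days are padded with masked cells, so flattening
    row-major and dropping the padding reproduces the original series.
    """
    x = recording.channel(channel)
    midnight = recording.start.normalize()
    lead = int((recording.start - midnight).total_seconds()) // EPOCH_SECONDS
    total = lead + recording.n_epochs
    n_days = -(-total // EPOCHS_PER_DAY)

    values = np.full(n_days * EPOCHS_PER_DAY, np.nan)
    mask = np.zeros(n_days * EPOCHS_PER_DAY, dtype=bool)
    values[lead : lead + recording.n_epochs] = x
    mask[lead : lead + recording.n_epochs] = recording.mask & np.isfinite(x)
    return DayMatrix(
        channel=channel,
        values=values.reshape(n_days, EPOCHS_PER_DAY),
        mask=mask.reshape(n_days, EPOCHS_PER_DAY),
    )
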