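"""Seeded synthetic multichannel actigraphy for cohort-level testing.

Real ambulatory circadian monitoring recordings of the kind this package
analyzes are not publicly deposited, so this module simulates them: 7-day,
30-s-epoch recordings of wrist temperature, acceleration, time in movement,
tilt, and light for "control"-like and Parkinson's-like ("pd") subjects.

The presets encode the contrasts that distinguish the two groups: the PD
profile has a cooler nocturnal temperature plateau, lower diurnal
acceleration, markedly more nocturnal time in movement (fragmented sleep,
weighted to the second half of the night, with early-morning light
exposure), larger day-to-day phase jitter, and daytime naps.  Wrist
temperature follows the physiologic shape — rising around bedtime via a
logistic ramp, a stable nocturnal plateau, a postprandial afternoon bump —
with AR(1) noise, while activity channels carry independent truncated-normal
noise.  Everything is deterministic given (profile, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .acm_io import EPOCHS_PER_DAY, Recording

__all__ = [
    "SyntheticProfile", "CohortSpec", "control_profile", "pd_profile",
    "generate_subject", "generate_cohort", "degrade_to_chronodisrupted",
]

_EPH = EPOCHS_PER_DAY / 24.0  # epochs per hour (120)


@dataclass(frozen=True)
class SyntheticProfile:
    """Parameters of one subject archetype.

    Temperatures in degC, clock times in decimal hours, durations in
    minutes, time in movement in seconds per 30-s epoch, acceleration in
    the device's integrated per-epoch unit (calibrated to the normative
    0-40 scale, not a physical g).
    """

    wt_night_plateau: float = 34.6
    wt_day_base: float = 32.3
    wt_bump_amp: float = 0.6
    wt_bump_time: float = 15.5
    wt_arousal_dip: float = 0.5
    acc_day_mean: float = 22.6
    acc_night_mean: float = 0.8
    tim_day_mean: float = 16.0
    tim_night_mean: float = 0.4
    sleep_onset: float = 23.5
    sleep_offset: float = 7.25
    phase_jitter_sd: float = 15.0
    arousal_rate: float = 1.5
    arousal_duration_mean: float = 4.0
    late_arousal_weight: float = 0.5
    nap_rate: float = 0.1
    nap_duration_mean: float = 40.0
    morning_light: bool = False
    light_day_level: float = 150.0
    transition_width: float = 30.0
    noise_sd: dict = field(default_factory=lambda: dict(
        wrist_temperature=0.15, acceleration=7.0, time_in_movement=6.0,
        tilt_x=15.0, light_log=0.5))

    def __post_init__(self):
        if self.wt_night_plateau < self.wt_day_base:
            raise ValueError(
                "physiologic profiles have wt_night_plateau >= wt_day_base")
        for name in ("arousal_rate", "nap_rate", "phase_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tim_day_mean", "tim_night_mean"):
            if not 0 <= getattr(self, name) <= 30:
                raise ValueError(f"{name} must lie in [0, 30] s/epoch")


def control_profile(**overrides) -> SyntheticProfile:
    """Healthy-adult preset: consolidated sleep, vigorous days."""
    return replace(SyntheticProfile(), **overrides)


def pd_profile(**overrides) -> SyntheticProfile:
    """Parkinson's-like preset: cooler nocturnal skin temperature, reduced
    diurnal acceleration, fragmented restless nights (second-half-weighted
    arousals with early light), larger phase jitter, daytime naps."""
    base = SyntheticProfile(
        wt_night_plateau=33.9,
        wt_day_base=32.1,
        wt_bump_amp=0.5,
        acc_day_mean=13.6,
        acc_night_mean=1.0,
        tim_day_mean=14.7,
        tim_night_mean=2.2,
        sleep_onset=23.5,
        sleep_offset=7.0,
        phase_jitter_sd=40.0,
        arousal_rate=8.0,
        arousal_duration_mean=6.0,
        late_arousal_weight=0.75,
        nap_rate=1.0,
        nap_duration_mean=50.0,
        morning_light=True,
    )
    return replace(base, **overrides)


PRESETS = {"control": control_profile, "pd": pd_profile}

#: Between-subject spread (absolute SD per parameter) used by cohorts.
DEFAULT_BETWEEN_SUBJECT_SD = {
    "wt_night_plateau": 0.30,
    "wt_day_base": 0.25,
    "acc_day_mean": 2.0,
    "acc_night_mean": 0.15,
    "tim_day_mean": 1.5,
    "tim_night_mean": 0.25,
    "sleep_onset": 0.3,
    "sleep_offset": 0.3,
    "phase_jitter_sd": 5.0,
    "arousal_rate": 0.5,
    "light_day_level": 30.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """A seeded cohort: ``n_pd`` PD-like plus ``n_control`` control-like."""

    n_pd: int = 12
    n_control: int = 12
    seed: int = 0
    days: int = 7
    between_subject_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD))
    pd_overrides: dict = field(default_factory=dict)
    control_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_pd < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")


def _sigmoid_ramp(t: np.ndarray, center: float, width_epochs: float) -> np.ndarray:
    if width_epochs <= 0:
        return (t >= center).astype(float)
    return expit((t - center) / (width_epochs / 4.0))


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = 0.9) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, sd * np.sqrt(1 - phi ** 2), n)
    e[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], e)


def generate_subject(
    profile: SyntheticProfile,
    seed: int,
    days: int = 7,
    subject_id: str = "synthetic",
    label: str | None = None,
    start: str = "2023-03-06 00:00:00",
    return_truth: bool = False,
):
    """Simulate one subject's multichannel recording.

    Per night, the sleep interval runs from onset to offset, both shifted
    by that night's phase jitter; channel levels ramp between sleep and
    wake values over ``transition_width`` minutes.  Arousals (a per-night
    Poisson count of wake-like interruptions, optionally weighted to the
    second half of the night) and daytime naps interrupt the baseline.

    Returns the :class:`Recording`; with ``return_truth=True`` also returns
    the generator's ground-truth sleep mask (main sleep plus naps, minus
    arousals) for validating sleep-scoring algorithms.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    p = profile
    n = days * EPOCHS_PER_DAY
    t = np.arange(n, dtype=float)  # epoch index from local midnight
    hour = (t % EPOCHS_PER_DAY) / _EPH
    w = p.transition_width / 60.0 * _EPH  # ramp width in epochs

    # --- sleep drive from jittered nightly intervals ------------------
    s = np.zeros(n)
    truth = np.zeros(n, dtype=bool)
    # night k: onset on day k, offset on day k+1 (interval spans midnight
    # when offset < onset); include night -1 to cover the first morning
    for k in range(-1, days):
        jit = rng.normal(0.0, p.phase_jitter_sd) / 60.0  # hours
        onset_h = 24.0 * k + p.sleep_onset + jit
        offset_h = 24.0 * (k + 1) + p.sleep_offset + jit
        onset, offset = onset_h * _EPH, offset_h * _EPH
        s += _sigmoid_ramp(t, onset, w) - _sigmoid_ramp(t, offset, w)
        truth |= (t >= onset) & (t < offset)

        # arousals within this night
        n_ar = rng.poisson(p.arousal_rate)
        for _ in range(n_ar):
            mid = (onset + offset) / 2.0
            if rng.random() < p.late_arousal_weight:
                at = rng.uniform(mid, offset)
            else:
                at = rng.uniform(onset, mid)
            dur = max(1, int(round(
                rng.exponential(p.arousal_duration_mean) * 60 / 30)))
            a0, a1 = int(max(at, 0)), int(min(max(at, 0) + dur, n))
            if a0 >= n or a1 <= 0:
                continue
            truth[a0:a1] = False
    s = np.clip(s, 0.0, 1.0)

    # arousal = inside the nominal night but not asleep
    nominal_night = np.zeros(n, dtype=bool)
    for k in range(-1, days):
        on = (24.0 * k + p.sleep_onset) * _EPH
        off = (24.0 * (k + 1) + p.sleep_offset) * _EPH
        nominal_night |= (t >= on) & (t < off)
    arousal = nominal_night & ~truth

    # --- daytime naps -------------------------------------------------
    nap = np.zeros(n, dtype=bool)
    for k in range(days):
        for _ in range(rng.poisson(p.nap_rate)):
            at = (24.0 * k + rng.uniform(13.0, 17.0)) * _EPH
            dur = max(1, int(round(rng.exponential(p.nap_duration_mean) * 2)))
            a0, a1 = int(at), int(min(at + dur, n))
            nap[a0:a1] = True
    nap &= ~nominal_night
    truth |= nap

    # effective sleep depth: nighttime drive, arousals awake, naps asleep
    depth = s.copy()
    depth[arousal] = 0.0
    depth[nap] = 1.0
    wake = 1.0 - depth

    # --- channels -----------------------------------------------------
    sd = p.noise_sd
    bump = p.wt_bump_amp * np.exp(-0.5 * ((hour - p.wt_bump_time) / 1.5) ** 2)
    wt = (p.wt_day_base + (p.wt_night_plateau - p.wt_day_base) * depth
          + bump * wake - p.wt_arousal_dip * arousal
          + _ar1(rng, n, sd.get("wrist_temperature", 0.0)))
    wt = np.clip(wt, 15.0, 45.0)

    acc_level = p.acc_night_mean + (p.acc_day_mean - p.acc_night_mean) * wake
    acc = np.clip(acc_level + rng.normal(0.0, 1.0, n)
                  * sd.get("acceleration", 0.0) * (0.15 + 0.85 * wake), 0.0, None)

    tim_level = p.tim_night_mean + (p.tim_day_mean - p.tim_night_mean) * wake
    tim = np.clip(tim_level + rng.normal(0.0, 1.0, n)
                  * sd.get("time_in_movement", 0.0) * (0.05 + 0.95 * wake),
                  0.0, 30.0)

    # posture: horizontal and quiet in bed, vertical and variable awake;
    # rare nocturnal posture-change impulses
    base_tilt = 10.0 * depth + 55.0 * wake
    tilt_noise = rng.normal(0.0, 1.0, n) * sd.get("tilt_x", 0.0) * wake
    impulses = (rng.random(n) < 0.004) & (depth > 0.5)
    tilt = np.clip(base_tilt + tilt_noise
                   + impulses * rng.uniform(-25, 25, n), 0.0, 90.0)

    light = (wake * p.light_day_level
             * np.exp(rng.normal(0.0, sd.get("light_log", 0.0), n)))
    # light only during plausible waking clock hours (dark evenings indoors)
    light *= np.clip(
        expit((hour - 6.5) * 3) * expit((22.5 - hour) * 3) + 0.15, 0, 1)
    if p.morning_light:
        light[arousal & (hour >= 5.0)] += 100.0
    light = np.clip(light, 0.0, None)

    rec = Recording(
        subject_id=subject_id,
        start=pd.Timestamp(start),
        channels={
            "wrist_temperature": wt,
            "acceleration": acc,
            "time_in_movement": tim,
            "tilt_x": tilt,
            "tilt_y": np.clip(90.0 - tilt + rng.normal(0, 5, n), 0, 90),
            "tilt_z": np.clip(
                30.0 * wake + rng.normal(0, 10, n) * wake, 0, 90),
            "light_visible": light,
            "light_blue": light * 0.3,
            "light_infrared": light * 0.5,
        },
        mask=np.ones(n, dtype=bool),
        label=label,
    )
    if return_truth:
        return rec, truth
    return rec


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate a labeled cohort of PD-like and control-like subjects.

    Per-subject parameters are drawn around the presets with the spec's
    between-subject spread, from independent seed streams derived from
    ``spec.seed``; identical specs yield identical cohorts.
    """
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.n_pd + spec.n_control)
    recs: list[Recording] = []
    groups = [("PD", spec.n_pd, pd_profile, spec.pd_overrides),
              ("control", spec.n_control, control_profile,
               spec.control_overrides)]
    i = 0
    for label, count, preset, overrides in groups:
        for k in range(count):
            seq = child[i]
            i += 1
            rng = np.random.default_rng(seq)
            prof = preset(**overrides)
            draws = {}
            for name, sdv in spec.between_subject_sd.items():
                val = getattr(prof, name) + rng.normal(0.0, sdv)
                if name in ("tim_day_mean", "tim_night_mean"):
                    val = float(np.clip(val, 0.0, 30.0))
                elif name in ("arousal_rate", "acc_night_mean",
                              "phase_jitter_sd", "light_day_level"):
                    val = max(0.0, val)
                elif name == "wt_night_plateau":
                    val = max(val, prof.wt_day_base + 0.2)
                draws[name] = val
            prof = replace(prof, **draws)
            subj_seed = int(rng.integers(0, 2 ** 31 - 1))
            recs.append(generate_subject(
                prof, seed=subj_seed, days=spec.days,
                subject_id=f"{label.lower()}_{k:02d}", label=label))
    return recs


_FLAT_EXTREME = dict(
    wt_bump_amp=0.0,
    acc_night_mean=None,  # -> acc_day_mean (filled at call time)
    tim_night_mean=None,  # -> tim_day_mean (capped at 30)
    phase_jitter_sd=150.0,
    arousal_rate=14.0,
    arousal_duration_mean=10.0,
    nap_rate=3.0,
    nap_duration_mean=60.0,
)


def degrade_to_chronodisrupted(
    profile: SyntheticProfile, severity: float
) -> SyntheticProfile:
    """Interpolate a profile toward a flat, fragmented, jittery extreme.

    ``severity`` 0 returns the profile unchanged; 1 collapses the day-night
    contrast entirely (nocturnal temperature plateau equals the day base,
    nocturnal activity equals diurnal) with heavy jitter, arousals, and
    naps.  Every parameter moves monotonically in ``severity``; this is the
    inverse of a treatment-response scenario in which circadian rhythmicity
    progressively recovers.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    ext = dict(_FLAT_EXTREME)
    ext["acc_night_mean"] = profile.acc_day_mean
    ext["tim_night_mean"] = min(profile.tim_day_mean, 30.0)
    ext["wt_night_plateau"] = profile.wt_day_base
    changes = {}
    for name, target in ext.items():
        v0 = getattr(profile, name)
        changes[name] = (1.0 - severity) * v0 + severity * target
    return replace(profile, **changes)
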