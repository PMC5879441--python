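"""Pipeline orchestration, summary tables, and figures.

``run_pipeline`` composes the full analysis — simulate (or load) a cohort,
compute circadian indices and TAP sleep per subject, build the feature
table, compare groups, and cross-validate the classifier — and writes a
report bundle of CSV/JSON artifacts.  ``render_actogram`` and the waveform
plot reproduce the standard chronobiology visualizations: day-per-row
rasters and 24-h group mean +- SEM curves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acm_io import Recording, read_recording, to_day_matrix
from .cohort import (
    FEATURE_REGISTRY,
    FeatureVector,
    cross_validate,
    extract_features,
    fit_tree,
    group_compare,
)
from .metrics import compute_indices
from .synthetic import CohortSpec, generate_cohort
from .tap_sleep import detect_sleep, tap_score

logger = logging.getLogger("circarhythm")

#: Features used for classification: the complementary motor/sleep set.
DEFAULT_CLASSIFY_FEATURES = (
    "wt_M5V", "acc_M10V", "tim_L5V", "sleep_M5V", "at_ratio",
)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: exactly one input source."""

    cohort_spec: CohortSpec | None = None
    input_paths: list | None = None
    labels: dict = field(default_factory=dict)  # subject_id -> label
    classify_features: tuple = DEFAULT_CLASSIFY_FEATURES
    cv_folds: int = 10
    cv_seed: int = 0
    tap_threshold: float = 0.5
    at_epsilon: float = 0.0
    out_dir: str | Path = "report"
    make_figures: bool = False

    def __post_init__(self):
        if (self.cohort_spec is None) == (self.input_paths is None):
            raise ConfigError(
                "exactly one of cohort_spec / input_paths must be set")


@dataclass
class ReportBundle:
    features: list  # FeatureVector per subject
    feature_table: pd.DataFrame
    group_table: pd.DataFrame
    sleep_table: pd.DataFrame
    cv_report: object
    tree: object
    manifest: dict


def analyze_subject(recording: Recording, tap_threshold: float = 0.5,
                    at_epsilon: float = 0.0):
    """Indices + sleep + feature vector for one recording."""
    tap = tap_score(recording)
    sleep = detect_sleep(tap, threshold=tap_threshold, start=recording.start)
    indices = compute_indices(recording, sleep=sleep, at_epsilon=at_epsilon)
    fv = extract_features(recording, indices, sleep)
    return indices, sleep, fv


def export_group_table(features: list[FeatureVector],
                       n_tests: int | None = None) -> pd.DataFrame:
    """Mean +- SEM per group and feature with significance flags.

    SEM = sd/sqrt(n) across subjects; single-subject groups report SEM as
    missing.  P-values come from :func:`group_compare`; stars mark
    significance at the Bonferroni-adjusted alpha (0.05 / number of
    features unless ``n_tests`` is given).
    """
    labels = sorted({fv.label for fv in features})
    rows = []
    n_tests = n_tests or len(FEATURE_REGISTRY)
    alpha = 0.05 / n_tests
    for name in FEATURE_REGISTRY:
        row = {"feature": name}
        groups = {}
        for lab in labels:
            vals = np.array([fv.features.get(name, np.nan)
                             for fv in features if fv.label == lab])
            vals = vals[np.isfinite(vals)]
            groups[lab] = vals
            row[f"{lab}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{lab}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1
                else np.nan)
        if len(labels) == 2 and all(len(v) >= 3 for v in groups.values()):
            try:
                cmp_res = group_compare(*groups.values())
                row["p_value"] = cmp_res.p_value
                row["test"] = cmp_res.test_name
                row["significant"] = "*" if cmp_res.p_value < alpha else ""
            except ValueError:
                row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute simulate/load -> indices -> sleep -> classify -> export.

    Deterministic given the config's seeds; every stage error is re-raised
    with the stage and subject id attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_spec is not None:
        spec = config.cohort_spec
        if spec.n_pd + spec.n_control == 0:
            raise ConfigError("empty cohort: n_pd + n_control is 0")
        logger.info("simulating cohort: %d PD + %d control, seed %d",
                    spec.n_pd, spec.n_control, spec.seed)
        recordings = generate_cohort(spec)
    else:
        if not config.input_paths:
            raise ConfigError("empty cohort: no input paths")
        recordings = []
        for p in config.input_paths:
            rec = read_recording(p, subject_id=Path(str(p)).stem)
            rec.label = config.labels.get(rec.subject_id)
            recordings.append(rec)

    features, sleep_rows = [], []
    for rec in recordings:
        try:
            indices, sleep, fv = analyze_subject(
                rec, tap_threshold=config.tap_threshold,
                at_epsilon=config.at_epsilon)
        except Exception as err:
            raise RuntimeError(
                f"analysis failed for subject {rec.subject_id!r}") from err
        features.append(fv)
        for night, hours in enumerate(sleep.actual_sleep_hours):
            sleep_rows.append({
                "subject_id": rec.subject_id, "label": rec.label,
                "night": night, "actual_sleep_hours": hours,
            })

    feature_table = pd.DataFrame(
        [{"subject_id": fv.subject_id, "label": fv.label, **fv.features}
         for fv in features])
    group_table = export_group_table(features)
    sleep_table = pd.DataFrame(sleep_rows)

    cv_report, tree = None, None
    labels = {fv.label for fv in features}
    if len(labels) == 2:
        feats = list(config.classify_features)
        tree = fit_tree(features, feats, max_depth=1)
        # stratified folds need at least one member of each class per fold
        counts = [sum(1 for fv in features if fv.label == lab)
                  for lab in labels]
        k = max(2, min(config.cv_folds, min(counts)))
        cv_report = cross_validate(features, feats, k=k, seed=config.cv_seed)

    feature_table.to_csv(out / "features.csv", index=False)
    group_table.to_csv(out / "group_summary.csv", index=False)
    sleep_table.to_csv(out / "sleep_nights.csv", index=False)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            repr(config).encode()).hexdigest()[:16],
        "seeds": {
            "cohort": (config.cohort_spec.seed
                       if config.cohort_spec is not None else None),
            "cv": config.cv_seed,
        },
        "n_subjects": len(recordings),
        "files": ["features.csv", "group_summary.csv", "sleep_nights.csv"],
    }
    if cv_report is not None:
        (out / "cv_report.json").write_text(json.dumps(
            dataclasses.asdict(cv_report), indent=2, default=float))
        manifest["files"].append("cv_report.json")
        tree_desc = [dataclasses.asdict(s) for s in tree.splits()]
        (out / "tree.json").write_text(json.dumps(
            {"max_depth": 1, "splits": tree_desc,
             "features": list(config.classify_features)}, indent=2))
        manifest["files"].append("tree.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if config.make_figures:
        from .tap_sleep import detect_sleep as _ds, tap_score as _ts
        for rec in recordings[:2]:
            sleep = _ds(_ts(rec), threshold=config.tap_threshold,
                        start=rec.start)
            render_actogram(rec, sleep, out / f"actogram_{rec.subject_id}.png")
            manifest["files"].append(f"actogram_{rec.subject_id}.png")

    return ReportBundle(
        features=features, feature_table=feature_table,
        group_table=group_table, sleep_table=sleep_table,
        cv_report=cv_report, tree=tree, manifest=manifest,
    )


def render_actogram(recording: Recording, sleep=None, out_path=None,
                    double_plot: bool = False):
    """Day-per-row raster: activity bars, temperature and light traces,
    sleep bars; masked periods appear as gaps (time off the wrist)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    acc = to_day_matrix(recording, "acceleration")
    wt = to_day_matrix(recording, "wrist_temperature")
    n_days = acc.n_days
    width = 2 if double_plot else 1
    fig, axes = plt.subplots(
        n_days, 1, figsize=(8 * width, 1.1 * n_days),
        sharex=True, squeeze=False)
    sleep_dm = None
    if sleep is not None:
        rec2 = recording.copy()
        rec2.channels["sleep_probability"] = sleep.sleep.astype(float)
        sleep_dm = to_day_matrix(rec2, "sleep_probability")

    hours = np.arange(acc.values.shape[1] * width) / 120.0
    for d in range(n_days):
        ax = axes[d, 0]

        def row(m):
            v = np.where(m.mask[d], m.values[d], np.nan)
            if double_plot:
                nxt = (np.where(m.mask[d + 1], m.values[d + 1], np.nan)
                       if d + 1 < n_days else np.full_like(v, np.nan))
                v = np.concatenate([v, nxt])
            return v

        a = row(acc)
        ax.fill_between(hours, 0, np.nan_to_num(a), color="0.3", step="mid")
        tmp = row(wt)
        if np.isfinite(tmp).any():
            t0, t1 = np.nanmin(tmp), np.nanmax(tmp)
            scale = (np.nanmax(a) if np.isfinite(a).any() else 1.0) or 1.0
            ax.plot(hours, (tmp - t0) / max(t1 - t0, 1e-9) * scale,
                    color="tab:red", lw=0.6)
        if sleep_dm is not None:
            sv = row(sleep_dm)
            ax.fill_between(hours, 0, np.where(sv > 0.5, 1, 0),
                            transform=ax.get_xaxis_transform(),
                            color="tab:orange", alpha=0.25, step="mid")
        ax.set_ylabel(f"d{d}", rotation=0, labelpad=15, fontsize=7)
        ax.set_yticks([])
    axes[-1, 0].set_xlabel("clock time (h)")
    axes[-1, 0].set_xlim(0, 24 * width)
    fig.suptitle(f"Actogram — {recording.subject_id}")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=100)
        plt.close(fig)
    return fig


def plot_waveforms(profiles: dict, out_path=None):
    """24-h mean +- SEM curves, one panel per channel, one line per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    channels = sorted({p.channel for grp in profiles.values() for p in grp})
    fig, axes = plt.subplots(len(channels), 1,
                             figsize=(7, 2.2 * len(channels)), squeeze=False)
    for i, ch in enumerate(channels):
        ax = axes[i, 0]
        for grp, plist in profiles.items():
            for p in plist:
                if p.channel != ch:
                    continue
                x = np.arange(p.n_bins) * p.bin_minutes / 60.0
                ax.plot(x, p.mean, label=grp, lw=1)
                ax.fill_between(x, p.mean - p.sem, p.mean + p.sem, alpha=0.25)
        ax.set_title(ch, fontsize=8)
        ax.set_xlim(0, 24)
    axes[0, 0].legend(fontsize=7)
    axes[-1, 0].set_xlabel("clock time (h)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=100)
        plt.close(fig)
    return fig
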