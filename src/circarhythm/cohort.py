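"""Cohort-level statistics and classification.

Turns per-subject circadian indices into group science: a fixed feature
registry, independent-group comparisons with Shapiro-Wilk-guided test
selection and Bonferroni control, correlations, Shannon-entropy information
gain, Fayyad-Irani minimum-description-length (MDL) discretization, greedy
information-gain decision trees (depth 1 reproduces single-attribute
cut-off "stumps"), and stratified k-fold cross-validation.

``MDLDiscretizer`` and ``InfoGainTreeClassifier`` follow the scikit-learn
estimator protocol (``fit``/``transform``/``predict``, ``get_params``,
trailing-underscore fitted attributes) and compose with sklearn model
selection; the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureVector", "FEATURE_REGISTRY", "MDLDiscretizer",
    "InfoGainTreeClassifier", "extract_features", "entropy",
    "information_gain", "mdl_discretize", "fit_tree", "cross_validate",
    "group_compare", "correlate", "CvReport",
]

#: Canonical per-subject feature names.  Null (NaN) marks a feature whose
#: source channel was absent, never silently zero.
FEATURE_REGISTRY = (
    "wt_M5V", "wt_L10V", "acc_M10V", "acc_L5V", "tim_M10V", "tim_L5V",
    "sleep_M5V", "light_M10V", "at_ratio", "actual_sleep_time",
    "wt_IS", "acc_IS", "tim_IS", "sleep_IS", "light_IS", "overall_IS",
    "wt_IV", "acc_IV", "tim_IV", "sleep_IV", "light_IV", "overall_IV",
    "wt_RA", "acc_RA", "tim_RA", "sleep_RA", "light_RA", "overall_RA",
    "wt_CFI", "acc_CFI", "tim_CFI", "sleep_CFI", "light_CFI", "overall_CFI",
)

_PREFIX = {
    "wrist_temperature": "wt",
    "acceleration": "acc",
    "time_in_movement": "tim",
    "sleep_probability": "sleep",
    "light_visible": "light",
}


@dataclass
class FeatureVector:
    """One subject's named features plus class label."""

    subject_id: str
    label: str
    features: dict[str, float] = field(default_factory=dict)

    def as_array(self, names) -> np.ndarray:
        return np.array([self.features.get(n, np.nan) for n in names])


def extract_features(recording, indices, sleep) -> FeatureVector:
    """Build the registry feature vector from one subject's analyses.

    ``indices`` is a :class:`~circarhythm.metrics.CircadianIndices` and
    ``sleep`` a :class:`~circarhythm.tap_sleep.SleepScore`, both computed
    on ``recording``; subject ids must agree.
    """
    if indices.subject_id != recording.subject_id:
        raise ValueError(
            f"indices belong to {indices.subject_id!r}, "
            f"recording is {recording.subject_id!r}")
    feats = {name: float("nan") for name in FEATURE_REGISTRY}
    for ch, ci in indices.per_channel.items():
        pre = _PREFIX[ch]
        for key in ("IS", "IV", "RA", "CFI"):
            feats[f"{pre}_{key}"] = getattr(ci, key)
        for wk, ws in ci.windows.items():
            name = f"{pre}_{wk}V"
            if name in feats:
                feats[name] = ws.value
    for key in ("IS", "IV", "RA", "CFI"):
        feats[f"overall_{key}"] = getattr(indices, f"overall_{key}")
    feats["at_ratio"] = indices.at_ratio
    if sleep is not None:
        feats["actual_sleep_time"] = sleep.mean_actual_sleep_hours
    return FeatureVector(
        subject_id=recording.subject_id,
        label=recording.label or "none",
        features=feats,
    )


def entropy(labels) -> float:
    """Shannon entropy of a class multiset, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(values, labels, cut_points) -> float:
    """Entropy reduction of labels from binning values at ``cut_points``.

    Equals ``H(labels) - sum_i (n_i/n) H(labels in interval i)`` with
    intervals delimited by the sorted cut points; an empty cut list gives 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels lengths differ")
    cuts = np.sort(np.asarray(list(cut_points), dtype=float))
    bins = np.searchsorted(cuts, values, side="right")
    h = entropy(labels)
    n = len(labels)
    for b in np.unique(bins):
        sel = bins == b
        h -= sel.sum() / n * entropy(labels[sel])
    return float(max(h, 0.0))


def _mdl_accepts(y, y1, y2, gain: float) -> bool:
    """Fayyad-Irani MDL stopping criterion for one binary split."""
    n = len(y)
    k = len(np.unique(y))
    k1, k2 = len(np.unique(y1)), len(np.unique(y2))
    delta = (math.log2(3 ** k - 2)
             - (k * entropy(y) - k1 * entropy(y1) - k2 * entropy(y2)))
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def _boundary_cuts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Candidate cuts: midpoints between adjacent distinct values whose
    class mixtures differ (Fayyad's boundary-point theorem)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cuts = []
    uniq, starts = np.unique(xs, return_index=True)
    groups = [set(ys[starts[i]:(starts[i + 1] if i + 1 < len(starts)
                                else len(ys))])
              for i in range(len(uniq))]
    for i in range(len(uniq) - 1):
        if groups[i] != groups[i + 1] or len(groups[i]) > 1:
            cuts.append((uniq[i] + uniq[i + 1]) / 2.0)
    return np.asarray(cuts)


def _mdl_recurse(x: np.ndarray, y: np.ndarray, out: list) -> None:
    if len(np.unique(y)) < 2 or len(y) < 2:
        return
    cands = _boundary_cuts(x, y)
    if cands.size == 0:
        return
    best_gain, best_cut = -1.0, None
    for c in cands:
        g = information_gain(x, y, [c])
        # ties broken toward the lower cut value (strict > keeps first)
        if g > best_gain + 1e-12:
            best_gain, best_cut = g, c
    left = x <= best_cut
    if not _mdl_accepts(y, y[left], y[~left], best_gain):
        return
    _mdl_recurse(x[left], y[left], out)
    out.append(float(best_cut))
    _mdl_recurse(x[~left], y[~left], out)


class MDLDiscretizer(TransformerMixin, BaseEstimator):
    """Supervised discretization by recursive entropy minimization.

    Implements Fayyad-Irani top-down splitting: at each node the
    information-gain-maximizing boundary cut is accepted only if the gain
    exceeds the minimum-description-length cost of encoding the extra
    partition, then both sides are split recursively.  A feature that
    never clears the criterion gets no cuts (one interval).

    Attributes
    ----------
    cut_points_ : list of ndarray
        Sorted cut points per feature column.
    n_features_in_ : int
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.cut_points_ = []
        for j in range(X.shape[1]):
            col = X[:, j]
            ok = np.isfinite(col)
            cuts: list[float] = []
            if ok.sum() >= 2:
                _mdl_recurse(col[ok], y[ok], cuts)
            self.cut_points_.append(np.sort(np.asarray(cuts)))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "cut_points_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = np.empty_like(X, dtype=int)
        for j, cuts in enumerate(self.cut_points_):
            out[:, j] = np.searchsorted(cuts, X[:, j], side="right")
        return out


def mdl_discretize(values, labels) -> np.ndarray:
    """Sorted MDL cut points of one feature (empty array when the
    criterion rejects every candidate split)."""
    disc = MDLDiscretizer().fit(np.asarray(values, dtype=float), labels)
    return disc.cut_points_[0]


@dataclass
class TreeSplit:
    feature: int
    cut: float
    gain: float


class InfoGainTreeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy decision tree on MDL-discretized cut points.

    At each node the (feature, MDL cut) pair maximizing information gain
    is chosen; growth stops at ``max_depth``, node purity, or when MDL
    rejects every split.  ``max_depth=1`` yields the single-attribute
    threshold stumps used to read off clinical cut-offs.  ``decision_
    function`` returns a leaf-purity score usable for ROC analysis.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; index 1 is the positive class for scores.
    tree_ : dict
        Nested ``{"split": TreeSplit, "left": ..., "right": ...}`` or
        ``{"leaf": class, "score": P(classes_[1])}``.
    is_degenerate_ : bool
        True when no admissible split existed at the root (majority-class
        model).
    """

    def __init__(self, max_depth: int = 1):
        self.max_depth = max_depth

    def _leaf(self, y):
        vals, counts = np.unique(y, return_counts=True)
        best = vals[np.argmax(counts)]
        pos = counts[vals == self.classes_[1]].sum() if len(
            self.classes_) > 1 else 0
        return {"leaf": best, "score": pos / counts.sum()}

    def _grow(self, X, y, depth):
        if depth >= self.max_depth or len(np.unique(y)) < 2:
            return self._leaf(y)
        best = None
        for j in range(X.shape[1]):
            col = X[:, j]
            ok = np.isfinite(col)
            if ok.sum() < 2:
                continue
            cuts: list[float] = []
            _mdl_recurse(col[ok], y[ok], cuts)
            for c in cuts:
                g = information_gain(col[ok], y[ok], [c])
                if best is None or g > best.gain + 1e-12:
                    best = TreeSplit(feature=j, cut=float(c), gain=float(g))
        if best is None:
            return self._leaf(y)
        left = X[:, best.feature] <= best.cut
        return {
            "split": best,
            "left": self._grow(X[left], y[left], depth + 1),
            "right": self._grow(X[~left], y[~left], depth + 1),
        }

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes to fit a tree")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        self.n_features_in_ = X.shape[1]
        self.tree_ = self._grow(X, y, 0)
        self.is_degenerate_ = "leaf" in self.tree_
        return self

    def _walk(self, node, x):
        while "split" in node:
            s = node["split"]
            node = node["left"] if x[s.feature] <= s.cut else node["right"]
        return node

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.asarray([self._walk(self.tree_, row)["leaf"] for row in X])

    def decision_function(self, X):
        """Leaf proportion of the positive class (``classes_[1]``)."""
        check_is_fitted(self, "tree_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.asarray(
            [self._walk(self.tree_, row)["score"] for row in X])

    def splits(self) -> list[TreeSplit]:
        """Splits in preorder (root first)."""
        check_is_fitted(self, "tree_")
        out: list[TreeSplit] = []

        def rec(node):
            if "split" in node:
                out.append(node["split"])
                rec(node["left"])
                rec(node["right"])

        rec(self.tree_)
        return out


def fit_tree(cohort, features, max_depth: int = 1) -> InfoGainTreeClassifier:
    """Fit an information-gain tree on a list of :class:`FeatureVector`."""
    X = np.vstack([fv.as_array(features) for fv in cohort])
    y = np.asarray([fv.label for fv in cohort])
    return InfoGainTreeClassifier(max_depth=max_depth).fit(X, y)


@dataclass
class CvReport:
    """Pooled stratified cross-validation metrics (positive class = PD)."""

    k: int
    seed: int
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auroc: float
    confusion: dict
    per_fold_accuracy: list


def cross_validate(
    cohort,
    features,
    k: int = 10,
    seed: int = 0,
    max_depth: int = 1,
    positive: str = "PD",
    auroc_feature: str | None = None,
) -> CvReport:
    """Stratified k-fold CV of the MDL tree; discretization and splits are
    refit on each training fold only.

    Sensitivity, specificity, accuracy and F1 come from the pooled
    confusion matrix with ``positive`` (disease detection) as the positive
    class.  The ROC curve of a hard stump is degenerate, so AUROC ranks
    subjects by a continuous score: ``auroc_feature`` if given, else the
    tree's leaf-purity decision function.
    """
    X = np.vstack([fv.as_array(features) for fv in cohort])
    y = np.asarray([fv.label for fv in cohort])
    n = len(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if not 2 <= k <= n:
        raise ValueError("k must lie in [2, n]")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_true, y_pred, y_score = [], [], []
    per_fold_acc = []
    for tr, te in skf.split(X, y):
        clf = InfoGainTreeClassifier(max_depth=max_depth).fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        y_true.extend(y[te])
        y_pred.extend(pred)
        if auroc_feature is not None:
            ji = list(features).index(auroc_feature)
            score = X[te, ji]
            # orient so that larger score means positive class
            pos_tr = X[tr][y[tr] == positive, ji]
            neg_tr = X[tr][y[tr] != positive, ji]
            if np.nanmean(pos_tr) < np.nanmean(neg_tr):
                score = -score
            y_score.extend(score)
        else:
            sc = clf.decision_function(X[te])
            if clf.classes_[1] != positive:
                sc = 1.0 - sc
            y_score.extend(sc)
        per_fold_acc.append(float(np.mean(pred == y[te])))
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    auroc = float(roc_auc_score((y_true == positive).astype(int), y_score))
    return CvReport(
        k=k, seed=seed, sensitivity=sens, specificity=spec, accuracy=acc,
        f1=f1, auroc=auroc,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        per_fold_accuracy=per_fold_acc,
    )


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    test_name: str
    normal: tuple


def group_compare(a, b, alpha_normality: float = 0.05) -> GroupComparison:
    """Two-group comparison with normality-guided test selection.

    Each group is Shapiro-Wilk tested; if both look normal a Welch t-test
    is used, otherwise the Mann-Whitney U (the design is unpaired: distinct
    patients and controls).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    pa = stats.shapiro(a).pvalue if len(np.unique(a)) > 1 else 0.0
    pb = stats.shapiro(b).pvalue if len(np.unique(b)) > 1 else 0.0
    normal = (pa > alpha_normality, pb > alpha_normality)
    if all(normal):
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "welch-t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney-u"
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=name,
        normal=normal,
    )


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    adjusted_alpha: float
    significant: bool
    method: str


def correlate(x, y, method: str = "pearson", n_tests: int = 1) -> CorrelationResult:
    """Pearson or Spearman correlation with Bonferroni-adjusted alpha.

    ``adjusted_alpha = 0.05 / n_tests`` (0.008 at 3 d.p. for the usual six
    comparisons); the significance flag tests p against it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input has undefined correlation")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    alpha = 0.05 / n_tests
    return CorrelationResult(
        coefficient=float(res.statistic),
        p_value=float(res.pvalue),
        adjusted_alpha=alpha,
        significant=bool(res.pvalue < alpha),
        method=method,
    )
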