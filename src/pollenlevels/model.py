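"""Imbalance-aware random-forest classifier for high pollen-level days.

High pollen days are rare, so a forest tuned for overall accuracy is
useless at the default 0.5 cutoff.  The remedy implemented here is the
optimizing-probability-threshold technique: collect out-of-fold class
probabilities by repeated stratified cross-validation, then pick the
cutoff on a fixed grid that minimizes the Euclidean distance of
(sensitivity, specificity, positive predictive value, negative predictive
value) from the perfect point (1, 1, 1, 1):

    distance = sqrt((1-Sens)^2 + (1-Spec)^2 + (1-Ppv)^2 + (1-Npv)^2)

The number of trees stays fixed (default 500) while ``mtry`` — the number
of candidate predictors per split — is tuned by the same repeated CV,
scoring each candidate by its distance at its own optimal cutoff.
Variable importance is the permutation mean decrease in accuracy over
held-out resamples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit

from .met_features import PREDICTOR_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Training configuration.

    Defaults follow the full-scale protocol (500 trees, 100 repetitions of
    ten-fold cross-validation, 20 candidate cutoffs); pass smaller
    ``cv_repeats``/``cv_folds`` for desk-scale runs.
    """

    ntree: int = 500
    mtry_grid: tuple[int, ...] = (2, 5, 10, 30)
    cv_folds: int = 10
    cv_repeats: int = 100
    n_thresholds: int = 20
    seed: int = 0
    selection_metric: str = "distance"  # or "accuracy"

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if any(not 1 <= m <= len(PREDICTOR_COLUMNS) for m in self.mtry_grid):
            raise ValueError("mtry candidates must lie in [1, 30]")
        if self.n_thresholds < 2:
            raise ValueError("need at least 2 candidate thresholds")

    def threshold_grid(self) -> np.ndarray:
        """n evenly spaced cutoffs i/(n+1), i = 1..n (never 0 or 1)."""
        n = self.n_thresholds
        return np.arange(1, n + 1) / (n + 1)


def _as_bool_labels(labels) -> np.ndarray:
    """Normalize labels to a boolean array with True = high."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iuf":
        return arr.astype(bool)
    lowered = np.char.lower(arr.astype(str))
    ok = np.isin(lowered, ("high", "low"))
    if not ok.all():
        raise ValueError("labels must be boolean or 'high'/'low'")
    return lowered == "high"


def distance_to_perfect(sens: float, spec: float, ppv: float, npv: float) -> float:
    """Euclidean distance of the four metrics from perfect performance (1,1,1,1).

    Ranges over [0, 2]; exactly 0 iff every metric equals 1.
    """
    vals = np.array([sens, spec, ppv, npv], dtype=float)
    if np.any(np.isnan(vals)) or np.any((vals < 0) | (vals > 1)):
        raise ValueError("metrics must lie in [0, 1]")
    return float(np.sqrt(np.sum((1.0 - vals) ** 2)))


def _metrics_at_cutoff(probs: np.ndarray, y: np.ndarray, cutoff: float):
    """Sens/Spec/Ppv/Npv at one cutoff, undefined ratios resolved to 0.

    The zero resolution penalizes degenerate cutoffs (no predicted
    positives or no predicted negatives) inside the distance; reporting
    contexts use NaN-flagged metrics instead (see ``evaluation``).
    """
    pred = probs >= cutoff
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    return sens, spec, ppv, npv


@dataclass
class ThresholdResult:
    threshold_star: float
    profile: pd.DataFrame  # threshold, sens, spec, ppv, npv, distance
    degenerate: bool = False


def optimize_threshold(probs, labels, spec: ModelSpec | None = None) -> ThresholdResult:
    """Pick the probability cutoff minimizing the distance to perfection.

    Evaluates ``spec.n_thresholds`` evenly spaced cutoffs on the supplied
    (typically out-of-fold) probabilities; a day is called high when its
    probability is >= the cutoff.  Ties go to the smallest cutoff.  When
    all probabilities are equal the threshold is not identifiable; the
    profile is still returned and the result flagged.
    """
    spec = spec or ModelSpec()
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = _as_bool_labels(labels)
    if len(probs) != len(y):
        raise ValueError("probs and labels differ in length")
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    rows = []
    for t in spec.threshold_grid():
        m = _metrics_at_cutoff(probs, y, t)
        rows.append((t, *m, distance_to_perfect(*m)))
    profile = pd.DataFrame(
        rows, columns=["threshold", "sens", "spec", "ppv", "npv", "distance"]
    )
    best = int(np.argmin(profile["distance"].to_numpy()))  # first min = smallest cutoff
    degenerate = bool(np.all(probs == probs[0]))
    if degenerate:
        warnings.warn("all probabilities identical; threshold not identifiable")
    return ThresholdResult(
        threshold_star=float(profile["threshold"].iloc[best]),
        profile=profile,
        degenerate=degenerate,
    )


def _forest(mtry: int, spec: ModelSpec, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=spec.ntree,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
    )


def _oof_probabilities(X, y, mtry, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold P(high) over repeated stratified CV.

    Returns (probs, labels), each of length n_rows * cv_repeats.
    """
    rskf = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=spec.seed
    )
    n = len(y)
    probs = np.empty(n * spec.cv_repeats)
    probs[:] = np.nan
    for i, (tr, te) in enumerate(rskf.split(X, y)):
        repeat = i // spec.cv_folds
        clf = _forest(mtry, spec, seed=spec.seed * 1000 + mtry * 100 + i % 97)
        clf.fit(X[tr], y[tr])
        col = list(clf.classes_).index(True)
        probs[repeat * n + te] = clf.predict_proba(X[te])[:, col]
    labels = np.tile(y, spec.cv_repeats)
    return probs, labels


@dataclass
class TuneResult:
    mtry_star: int
    oof_probs: np.ndarray
    oof_labels: np.ndarray
    scores: pd.DataFrame  # mtry, distance, threshold


def tune_mtry(features: pd.DataFrame, labels, spec: ModelSpec) -> TuneResult:
    """Select mtry by repeated stratified CV.

    Each candidate is scored by the distance to perfection of its pooled
    out-of-fold probabilities, evaluated at the candidate's own optimal
    cutoff (or by CV accuracy at 0.5 when ``selection_metric='accuracy'``).
    Ties break toward the smallest candidate.  Returns the winner's pooled
    probabilities for downstream threshold optimization.
    """
    X = features[list(PREDICTOR_COLUMNS)].to_numpy()
    y = _as_bool_labels(labels)
    if not (y.any() and (~y).any()):
        raise ValueError("training data contain a single class")
    candidates = sorted(set(spec.mtry_grid))
    rows = []
    pooled = {}
    for mtry in candidates:
        probs, lab = _oof_probabilities(X, y, mtry, spec)
        pooled[mtry] = (probs, lab)
        if spec.selection_metric == "accuracy":
            score = float(np.mean((probs >= 0.5) != lab))  # CV error rate
            thr = 0.5
        else:
            res = optimize_threshold(probs, lab, spec)
            score = float(res.profile["distance"].min())
            thr = res.threshold_star
        rows.append((mtry, score, thr))
        logger.info("mtry=%d: score=%.4f threshold=%.3f", mtry, score, thr)
    scores = pd.DataFrame(rows, columns=["mtry", "score", "threshold"])
    best = int(np.argmin(scores["score"].to_numpy()))  # first min = smallest mtry
    mtry_star = int(scores["mtry"].iloc[best])
    probs, lab = pooled[mtry_star]
    return TuneResult(mtry_star=mtry_star, oof_probs=probs, oof_labels=lab, scores=scores)


@dataclass
class TrainedClassifier:
    """A fitted forest plus everything needed to predict levels."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    mtry: int
    threshold: float | None = None
    importance: pd.Series | None = None
    profile: pd.DataFrame | None = None
    spec: ModelSpec = field(default_factory=ModelSpec)

    def predict_proba_high(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(self.feature_names)].to_numpy()
        col = list(self.forest.classes_).index(True)
        return self.forest.predict_proba(X)[:, col]

    def predict_level(self, features: pd.DataFrame) -> np.ndarray:
        """Boolean high/low using the optimized cutoff (>= is high)."""
        if self.threshold is None:
            raise ValueError("classifier has no optimized threshold")
        return self.predict_proba_high(features) >= self.threshold

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedClassifier":
        return joblib.load(path)


def fit_forest(features: pd.DataFrame, labels, mtry: int, spec: ModelSpec) -> TrainedClassifier:
    """Fit the final forest with the selected mtry on all supplied rows."""
    X = features[list(PREDICTOR_COLUMNS)].to_numpy()
    y = _as_bool_labels(labels)
    if not (y.any() and (~y).any()):
        raise ValueError("training data contain a single class")
    clf = _forest(mtry, spec, seed=spec.seed)
    clf.fit(X, y)
    return TrainedClassifier(
        forest=clf, feature_names=tuple(PREDICTOR_COLUMNS), mtry=mtry, spec=spec
    )


def permutation_importance(
    model: TrainedClassifier,
    features: pd.DataFrame,
    labels,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Mean decrease in accuracy per predictor, descending.

    Permutes one column at a time in the supplied evaluation rows and
    averages the accuracy drop of the fitted model over ``n_repeats``
    shuffles.  Permuting nothing drops accuracy by exactly zero, so pure
    noise columns score near zero.
    """
    X = features[list(model.feature_names)]
    y = _as_bool_labels(labels)
    res = _sk_permutation_importance(
        model.forest,
        X.to_numpy(),
        y,
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    imp = pd.Series(res.importances_mean, index=list(model.feature_names))
    return imp.sort_values(ascending=False)


def _resampled_importance(
    features: pd.DataFrame, labels, mtry: int, spec: ModelSpec,
    n_splits: int = 3, test_size: float = 0.25,
) -> pd.Series:
    """Permutation importance averaged over held-out stratified resamples."""
    y = _as_bool_labels(labels)
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_size, random_state=spec.seed
    )
    acc = None
    for i, (tr, te) in enumerate(sss.split(features, y)):
        part = fit_forest(features.iloc[tr], y[tr], mtry, spec)
        imp = permutation_importance(
            part, features.iloc[te], y[te], n_repeats=2, seed=spec.seed + i
        ).sort_index()
        acc = imp if acc is None else acc + imp
    return (acc / n_splits).sort_values(ascending=False)


def probability_profile(
    model: TrainedClassifier,
    features: pd.DataFrame,
    predictor: str,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Mean predicted P(high) binned over one predictor's observed range.

    Returns columns ``bin_center``, ``mean_probability``, ``n``; empty
    bins are omitted.  A constant predictor collapses to a single bin
    (with a warning).
    """
    if predictor not in model.feature_names:
        raise KeyError(f"unknown predictor {predictor!r}")
    x = features[predictor].to_numpy(dtype=float)
    probs = model.predict_proba_high(features)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        warnings.warn(f"predictor {predictor!r} is constant; single-bin profile")
        return pd.DataFrame(
            {"bin_center": [lo], "mean_probability": [float(probs.mean())],
             "n": [len(x)]}
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            rows.append((centers[b], float(probs[mask].mean()), int(mask.sum())))
    return pd.DataFrame(rows, columns=["bin_center", "mean_probability", "n"])


def train_classifier(features: pd.DataFrame, spec: ModelSpec) -> TrainedClassifier:
    """Full training path: tune mtry, optimize the cutoff, fit, score importance.

    ``features`` must carry the 30 predictors plus a ``level`` column.
    Deterministic given ``spec.seed``.
    """
    labels = features["level"]
    tuned = tune_mtry(features, labels, spec)
    thr = optimize_threshold(tuned.oof_probs, tuned.oof_labels, spec)
    model = fit_forest(features, labels, tuned.mtry_star, spec)
    model.threshold = thr.threshold_star
    model.profile = thr.profile
    model.importance = _resampled_importance(features, labels, tuned.mtry_star, spec)
    return model
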