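"""Data splitting and confusion-matrix evaluation.

The three-way split mirrors the study design: training rows are a random
two-thirds of the *dates* of the core monitoring sites, the remaining
dates form the temporal test set (test1), and every row of the held-out
sites forms the spatial test set (test2).  Splitting at the date level
guarantees a calendar day never appears on both sides for any core site.

Performance is summarized by the Kappa statistic and the four
confusion-matrix ratios, with high = positive:

    Kappa = (O - E) / (1 - E)
    Sensitivity = TP / (TP + FN)      Specificity = TN / (TN + FP)
    Ppv = TP / (TP + FP)              Npv = TN / (TN + FN)

where O is the observed accuracy and E the accuracy expected from the
marginal totals of the confusion matrix.  Undefined ratios are reported as
NaN here (reporting context), unlike inside the threshold-optimization
distance where they are resolved to 0 to penalize degenerate cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TrainedClassifier, _as_bool_labels


@dataclass(frozen=True)
class SplitSpec:
    """Site lists and date fraction for the three-way split."""

    core_sites: tuple[str, ...]
    holdout_sites: tuple[str, ...]
    train_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        if set(self.core_sites) & set(self.holdout_sites):
            raise ValueError("core and holdout sites overlap")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Kappa and the four ratios; NaN marks an undefined ratio."""

    kappa: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form matching the study's two-decimal tables."""
        return {
            k: (round(v, ndigits) if np.isfinite(v) else None)
            for k, v in self.__dict__.items()
        }


def make_splits(features: pd.DataFrame, spec: SplitSpec) -> dict[str, pd.DataFrame]:
    """Partition a labeled feature table into train / test1 / test2.

    Core-site *dates* are randomly split by ``train_fraction`` (seeded);
    test2 is every row of the holdout sites.  Raises if the table contains
    sites not named in the spec.
    """
    sites = set(features["site"].unique())
    known = set(spec.core_sites) | set(spec.holdout_sites)
    if sites - known:
        raise ValueError(f"unassigned sites in features: {sorted(sites - known)}")
    core = features[features["site"].isin(spec.core_sites)]
    dates = np.sort(core["date"].unique())
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(dates))
    n_train = int(len(dates) * spec.train_fraction + 0.5)
    train_dates = set(dates[perm[:n_train]])
    is_train = core["date"].isin(train_dates)
    return {
        "train": core[is_train].reset_index(drop=True),
        "test1": core[~is_train].reset_index(drop=True),
        "test2": features[features["site"].isin(spec.holdout_sites)].reset_index(
            drop=True
        ),
    }


def confusion(labels, predictions) -> ConfusionMatrix:
    """Tally TP/FP/TN/FN with high as the positive class."""
    y = _as_bool_labels(labels)
    p = _as_bool_labels(predictions)
    if len(y) != len(p):
        raise ValueError("labels and predictions differ in length")
    return ConfusionMatrix(
        tp=int(np.sum(p & y)),
        fp=int(np.sum(p & ~y)),
        tn=int(np.sum(~p & ~y)),
        fn=int(np.sum(~p & y)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Kappa, sensitivity, specificity, PPV and NPV from raw counts.

    Expected accuracy uses the standard marginal-product form
    ``E = ((TP+FN)(TP+FP) + (TN+FP)(TN+FN)) / n^2``.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    o = (cm.tp + cm.tn) / n
    e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n**2
    kappa = (o - e) / (1 - e) if e != 1 else float("nan")
    return MetricReport(
        kappa=kappa,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def evaluate_model(
    model: TrainedClassifier, test: pd.DataFrame
) -> tuple[MetricReport, ConfusionMatrix]:
    """Apply the optimized cutoff to a labeled test set and score it."""
    if "level" not in test.columns or test["level"].isna().any():
        raise ValueError("test rows must all be labeled")
    preds = model.predict_level(test)
    cm = confusion(test["level"], preds)
    return compute_metrics(cm), cm
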