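"""Repeated-holdout evaluation, comparison grid, and the paired t-test.

Classification quality is the accuracy (TP + TN) / (TP + TN + FP + FN),
estimated by repeated random holdout: many stratified 2/3 train / 1/3
test splits, each scored once, reported as mean +/- SD in percent.  When
several pipeline variants (segmentation source x transform x classifier)
are compared, all cells share the same split sequence so per-repeat
accuracies are paired and a paired two-tailed t-test applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roughset import RoughSetClassifier

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "accuracy",
    "confusion_from_predictions",
    "stratified_splits",
    "repeated_holdout",
    "compare_grid",
    "paired_t",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts.

    Conventions: TP = diseased case called abnormal, TN = healthy case
    called normal, FP = diseased case called normal, FN = healthy case
    called abnormal.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / total


def confusion_from_predictions(
    y_true, y_pred, positive="abnormal", negative="normal"
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == positive) & (y_pred == positive))),
        tn=int(np.sum((y_true == negative) & (y_pred == negative))),
        fp=int(np.sum((y_true == positive) & (y_pred == negative))),
        fn=int(np.sum((y_true == negative) & (y_pred == positive))),
    )


@dataclass(frozen=True)
class EvalResult:
    """Per-repeat accuracies (percent) of one pipeline configuration."""

    accuracies: tuple[float, ...]
    config_tag: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    def __str__(self) -> str:
        return f"{self.config_tag}: {self.mean:.2f}({self.sd:.2f})"


def _largest_remainder_train_count(n_class: int, train_frac: float) -> int:
    exact = n_class * train_frac
    k = int(np.floor(exact))
    if exact - k >= 0.5:
        k += 1
    return min(max(k, 1), n_class - 1)


def stratified_splits(
    y, n_repeats: int, train_frac: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic sequence of stratified train/test index splits.

    Each class contributes its rounded (largest-remainder) share of
    ``train_frac`` to the training fold, and at least one object to each
    side, so no fold ever loses a class.
    """
    y = np.asarray(y)
    labels = np.unique(y)
    if any(np.sum(y == lab) < 2 for lab in labels):
        raise ValueError("need at least 2 objects per class")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    splits = []
    for _ in range(n_repeats):
        train_idx: list[int] = []
        test_idx: list[int] = []
        for lab in labels:
            idx = np.flatnonzero(y == lab)
            perm = rng.permutation(idx)
            k = _largest_remainder_train_count(len(idx), train_frac)
            train_idx.extend(perm[:k])
            test_idx.extend(perm[k:])
        splits.append((np.sort(np.array(train_idx)), np.sort(np.array(test_idx))))
    return splits


def repeated_holdout(
    X,
    y,
    classifier_factory=None,
    n_repeats: int = 100,
    train_frac: float = 2 / 3,
    seed: int = 0,
    config_tag: str = "",
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvalResult:
    """Repeated stratified random-holdout accuracy estimate.

    For each repeat the classifier (discretizer included) is fitted on
    the training fold only and scored on the held-out third; per-repeat
    accuracies are returned in percent.  Passing a precomputed ``splits``
    list lets several configurations share the same split sequence for
    paired comparison.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classifier_factory is None:
        classifier_factory = RoughSetClassifier
    if splits is None:
        splits = stratified_splits(y, n_repeats, train_frac, seed)
    accs = []
    for train, test in splits:
        clf = classifier_factory()
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        accs.append(100.0 * float(np.mean(pred == y[test])))
    return EvalResult(accuracies=tuple(accs), config_tag=config_tag)


def compare_grid(
    feature_sets: dict[str, np.ndarray],
    y,
    classifiers: dict[str, object] | None = None,
    n_repeats: int = 100,
    train_frac: float = 2 / 3,
    seed: int = 0,
) -> dict[str, EvalResult]:
    """Evaluate every (feature set x classifier) cell on SHARED splits.

    ``feature_sets`` maps a tag (e.g. ``"proposed_dwpt"``) to an
    (n, p) feature matrix over the SAME objects in the same order; the
    split sequence is drawn once from ``seed`` so all cells are paired.
    """
    if classifiers is None:
        classifiers = {"rough_set": RoughSetClassifier}
    y = np.asarray(y)
    splits = stratified_splits(y, n_repeats, train_frac, seed)
    out: dict[str, EvalResult] = {}
    for feat_tag, X in feature_sets.items():
        for clf_tag, factory in classifiers.items():
            tag = f"{feat_tag}|{clf_tag}"
            out[tag] = repeated_holdout(
                X, y, factory, config_tag=tag, splits=splits
            )
    return out


def results_table(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Mean(SD) summary table, accuracies in percent with 2 decimals."""
    rows = [
        {
            "configuration": tag,
            "mean_accuracy": round(r.mean, 2),
            "sd_accuracy": round(r.sd, 2),
            "n_repeats": len(r.accuracies),
        }
        for tag, r in results.items()
    ]
    return pd.DataFrame(rows)


def paired_t(acc_a, acc_b) -> tuple[float, float]:
    """Two-tailed paired t-test on per-repeat accuracy differences.

    Degenerate cases: identical lists give (0, 1); a constant nonzero
    difference (zero variance) gives t = +/-inf with p = 0 — an exact
    tie-free ordering at every repeat.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D lists with >= 2 entries")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if float(np.mean(d)) == 0.0:
            return 0.0, 1.0
        return (np.inf if d.mean() > 0 else -np.inf), 0.0
    n = len(d)
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p
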