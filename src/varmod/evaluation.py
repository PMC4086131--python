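"""Protein-grouped fold construction and performance measurement."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from varmod.core_io import LabelledVariant


def grouped_folds_from_ids(
    protein_ids: list[str], k: int = 5, seed: int = 17
) -> dict[str, int]:
    """Assign each protein to one fold (1..k), balancing variant counts.

    Proteins are shuffled (seeded, to break ties among equal counts), then
    greedily assigned in descending order of variant count to the fold
    that currently holds the fewest variants.
    """
    counts = Counter(protein_ids)
    if len(counts) < k:
        raise ValueError(
            f"need at least {k} distinct proteins, got {len(counts)}"
        )
    rng = np.random.default_rng(seed)
    proteins = sorted(counts)
    rng.shuffle(proteins)
    proteins.sort(key=lambda p: -counts[p])  # stable: shuffled order breaks ties
    fold_sizes = [0] * k
    assignment: dict[str, int] = {}
    for p in proteins:
        fold = min(range(k), key=lambda f: (fold_sizes[f], f))
        assignment[p] = fold + 1
        fold_sizes[fold] += counts[p]
    return assignment


def grouped_folds(
    labelled_variants: list[LabelledVariant], k: int = 5, seed: int = 17
) -> dict[str, int]:
    return grouped_folds_from_ids(
        [lv.protein_id for lv in labelled_variants], k=k, seed=seed
    )


def check_no_leakage(train_ids, test_ids) -> None:
    """Raise if any protein appears on both sides of a train/test split."""
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise AssertionError(
            f"protein leakage between train and test: {sorted(overlap)[:5]}"
        )


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    precision: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True
    precision_defined: bool = True


def confusion_metrics(labels, calls) -> ConfusionMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP).

    Undefined ratios (zero denominator) come back as NaN with the
    corresponding ``*_defined`` flag cleared.
    """
    labels = np.asarray(labels).astype(int)
    calls = np.asarray(calls).astype(int)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    tp = int(((labels == 1) & (calls == 1)).sum())
    fp = int(((labels == 0) & (calls == 1)).sum())
    tn = int(((labels == 0) & (calls == 0)).sum())
    fn = int(((labels == 1) & (calls == 0)).sum())

    def ratio(num: int, den: int) -> tuple[float, bool]:
        return (num / den, True) if den else (math.nan, False)

    sens, sens_ok = ratio(tp, tp + fn)
    spec, spec_ok = ratio(tn, tn + fp)
    prec, prec_ok = ratio(tp, tp + fp)
    return ConfusionMetrics(sens, spec, prec, sens_ok, spec_ok, prec_ok)


@dataclass
class MetricReport:
    sensitivity: float
    specificity: float
    precision: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    auc: float

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auc": self.auc,
            "roc_points": self.roc_points,
            "pr_points": self.pr_points,
        }


def roc_and_pr(labels, scores, call_threshold: float = 0.5) -> MetricReport:
    """Threshold-sweep ROC (trapezoidal AUC) and precision-recall analysis.

    Tied scores share a single ROC point.  Point-estimate confusion metrics
    are reported at ``call_threshold``.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both labels must be present for ROC analysis")

    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    prec_arr, rec_arr, _ = precision_recall_curve(labels, scores)
    cm = confusion_metrics(labels, (scores >= call_threshold).astype(int))
    return MetricReport(
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        precision=cm.precision,
        roc_points=[(float(x), float(y)) for x, y in zip(fpr, tpr)],
        pr_points=[(float(r), float(p)) for r, p in zip(rec_arr, prec_arr)],
        auc=roc_auc,
    )
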