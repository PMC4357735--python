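"""ROC and precision-recall evaluation against gold-standard labels."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn import metrics as _skm

from .scan import CandidateSite, split_train_test


@dataclass
class RocResult:
    """ROC curve with trapezoidal AUC; ties grouped into single steps."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class PrResult:
    """Precision-recall curve with step-wise (non-interpolated) average precision."""

    recall: np.ndarray
    precision: np.ndarray
    average_precision: float


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be parallel 1-d arrays")
    return scores, labels


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC over all distinct score thresholds; AUC by the trapezoid rule.

    Requires both classes present.  Equal scores are grouped into a single
    threshold step, so ties contribute a diagonal segment.
    """
    scores, labels = _validate(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both positive and negative labels")
    fpr, tpr, thresholds = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
    )


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> PrResult:
    """Precision-recall curve; average precision by the step-function sum."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("precision-recall requires at least one positive")
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    # sklearn returns the curve with recall decreasing; store it ascending
    return PrResult(
        recall=recall[::-1],
        precision=precision[::-1],
        average_precision=float(_skm.average_precision_score(labels, scores)),
    )


def repeated_split_evaluation(
    sites: Sequence[CandidateSite],
    fit_predict: Callable[[list[CandidateSite], list[CandidateSite], int], tuple[np.ndarray, np.ndarray]],
    n_reps: int = 10,
    seeds: Sequence[int] | None = None,
) -> dict:
    """Repeat random 50/50 split -> train -> predict -> AUC.

    ``fit_predict(train_sites, test_sites, seed)`` must return
    ``(scores, labels)`` for the test sites.  Returns the per-repetition
    AUCs with their mean and standard deviation; reproducible given seeds.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seeds is None:
        seeds = list(range(n_reps))
    if len(seeds) != n_reps:
        raise ValueError("need one seed per repetition")
    aucs = []
    for seed in seeds:
        train, test = split_train_test(sites, seed=seed)
        scores, labels = fit_predict(train, test, seed)
        aucs.append(roc_curve(scores, labels).auc)
    aucs = np.asarray(aucs)
    return {
        "aucs": aucs,
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)) if n_reps > 1 else 0.0,
        "seeds": list(seeds),
    }
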