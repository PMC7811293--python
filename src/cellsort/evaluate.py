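"""Evaluation harnesses: annotation F1 and rank-threshold ROC averaging."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .voting import UNASSIGNED

__all__ = ["evaluate_annotation", "rank_roc", "evaluate_anomaly"]

FPR_GRID = np.linspace(0.0, 1.0, 101)


def evaluate_annotation(predicted: pd.Series, truth: pd.Series):
    """Support-weighted multi-class F1 (excluding unassigned cells) and the
    unassigned fraction over all cells.

    ``predicted`` and ``truth`` are per-cell type labels sharing an index.
    F1 is None when every cell is unassigned.
    """
    predicted, truth = predicted.align(truth, join="inner")
    if len(predicted) == 0:
        raise ValueError("no cells in common between prediction and truth")
    assigned = predicted != UNASSIGNED
    unassigned_fraction = float((~assigned).mean())
    if not assigned.any():
        return None, unassigned_fraction
    f1 = f1_score(
        truth[assigned], predicted[assigned], average="weighted", zero_division=0
    )
    return float(f1), unassigned_fraction


def rank_roc(scores: np.ndarray, flags: np.ndarray):
    """ROC using the anomaly rank as threshold.

    Cells are ordered from most to least anomalous (descending score); at
    each rank cutoff k the top-k cells are called anomalous, giving one
    (FPR, TPR) point.  Returns (fpr, tpr) arrays including (0,0) and (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("flags must contain both classes")
    order = np.argsort(-scores, kind="stable")
    hits = np.cumsum(flags[order])
    misses = np.cumsum(~flags[order])
    # cells with tied scores cross the threshold together: keep only the
    # last point of each tie group so ties trace the chance diagonal
    sorted_scores = scores[order]
    last_of_group = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.concatenate([[0.0], hits[last_of_group] / flags.sum()])
    fpr = np.concatenate([[0.0], misses[last_of_group] / (~flags).sum()])
    return fpr, tpr


def evaluate_anomaly(realizations):
    """Average the rank-threshold ROC over realizations and report its AUC.

    ``realizations`` is an iterable of (scores, flags) pairs.  Each curve
    is interpolated onto a common FPR grid, curves are averaged pointwise,
    and the AUC of the average curve is returned as
    ``(auc, fpr_grid, mean_tpr)``.
    """
    curves = []
    for scores, flags in realizations:
        fpr, tpr = rank_roc(scores, flags)
        curves.append(np.interp(FPR_GRID, fpr, tpr))
    if not curves:
        raise ValueError("no realizations")
    mean_tpr = np.mean(curves, axis=0)
    auc = float(np.trapezoid(mean_tpr, FPR_GRID))
    return auc, FPR_GRID, mean_tpr
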