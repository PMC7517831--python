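"""Ranking metrics: ROC curve and AUC with midrank tie handling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import InsufficientDataError

__all__ = ["ROCResult", "roc_auc"]


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_active: int
    n_decoy: int


def roc_auc(scores, labels) -> ROCResult:
    """AUC of `scores` as a ranking of label 1 over label 0.

    Computed as the Mann-Whitney U statistic normalised by n1*n0, with ties
    midranked; identical to the probability that a random active outranks a
    random decoy (ties count 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InsufficientDataError("both classes must be present to compute AUC")

    ranks = rankdata(scores)  # midranks
    r1 = ranks[labels == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    # ROC curve: sweep thresholds from high to low score
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep one point per distinct score (last index of each tie block)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n1]
    fpr = np.r_[0.0, fp[distinct] / n0]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return ROCResult(auc, fpr, tpr, thresholds, n1, n0)
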