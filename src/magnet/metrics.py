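"""Evaluation metrics: rank-based AUROC and thresholded accuracy."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import ContractError

__all__ = ["accuracy", "auroc"]


def auroc(labels, scores) -> float | None:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Tied scores count 1/2, matching the pairwise-comparison definition.
    Returns ``None`` when only one class is present (AUROC undefined).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ContractError("labels and scores must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy(labels, scores, threshold: float = 0.5) -> float:
    """Fraction of slides whose thresholded score matches the label."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    preds = (scores > threshold).astype(int)
    return float((preds == labels).mean())
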