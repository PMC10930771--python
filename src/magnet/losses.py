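"""Objective terms: paradoxical loss, binary cross-entropy, and their sum.

Functions accept either plain numpy arrays (returning floats) or engine
:class:`~magnet._tensor.Tensor` batches (returning scalar tensors on the
graph), so the same definitions serve both the training loop and direct
numerical checks.

The cross-entropy is the standard negated log-likelihood mean; probability
inputs are clamped to ``[eps, 1 - eps]`` before the logarithms.  The
subgradient of ``max(x, 0)`` at 0 is taken as 0, so the paradoxical loss
has gradient ``1/M`` with respect to the shallow-layer probability on
strictly paradoxical samples and 0 elsewhere.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, astensor, maximum, minimum
from .errors import ContractError

__all__ = ["bce_loss", "paradoxical_loss", "total_loss", "true_class_probability"]

EPS = 1e-7


def _pair(a, b):
    ta, tb = astensor(a), astensor(b)
    if ta.shape != tb.shape:
        raise ContractError(f"length mismatch: {ta.shape} vs {tb.shape}")
    return ta, tb


def paradoxical_loss(p1, p3):
    """Mean over the batch of ``max(P1 - P3, 0)``.

    Zero iff the deeper layer predicts the true class at least as well as
    the shallower one on every sample; bounded in [0, 1].
    """
    t1, t3 = _pair(p1, p3)
    out = maximum(t1 - t3, 0.0).mean()
    return out if isinstance(p1, Tensor) or isinstance(p3, Tensor) else out.item()


def bce_loss(y, y_hat):
    """Binary cross-entropy, averaged over the batch."""
    ty, tp = _pair(y, y_hat)
    tp = minimum(maximum(tp, EPS), 1.0 - EPS)
    out = -(ty * tp.log() + (1.0 - ty) * (1.0 - tp).log()).mean()
    return out if isinstance(y, Tensor) or isinstance(y_hat, Tensor) else out.item()


def total_loss(l1, l2, l3):
    """Unweighted sum of the three terms."""
    return l1 + l2 + l3


def true_class_probability(y, p):
    """P(true class) from a class-1 probability: ``p`` if y=1 else ``1 - p``."""
    ty, tp = _pair(y, p)
    out = ty * tp + (1.0 - ty) * (1.0 - tp)
    return out if isinstance(y, Tensor) or isinstance(p, Tensor) else out.data
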