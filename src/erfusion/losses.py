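"""Relation losses: class-balanced binary cross-entropy and mean squared error.

Both return ``(loss, dloss/dscores)`` so the trainer can backpropagate without
an autodiff framework.  Binary scores are raw logits; the sigmoid lives inside
the loss for numerical stability.
"""

from __future__ import annotations

import numpy as np

__all__ = ["balanced_bce", "mse_loss", "positive_class_weight", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def positive_class_weight(labels: np.ndarray, direction: str = "neg_over_pos") -> float:
    """Class-balance weight for the positive class, from relation-wide counts.

    ``neg_over_pos`` (default) up-weights minority positives by N_neg/N_pos;
    ``pos_over_neg`` is the literal positive:negative ratio.  If either class
    is absent the weight is 1.
    """
    labels = np.asarray(labels)
    n_pos = float((labels == 1).sum())
    n_neg = float((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return 1.0
    return n_neg / n_pos if direction == "neg_over_pos" else n_pos / n_neg


def balanced_bce(scores: np.ndarray, labels: np.ndarray, pos_weight: float = 1.0):
    """Weighted binary cross-entropy on logits.

    Each term is ``softplus(z) - y*z`` with weight ``pos_weight`` on positive
    labels and 1 on negatives; the loss is the weighted mean (division by the
    sum of weights, so a balanced weight of 1 recovers plain mean BCE).
    """
    z = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("balanced_bce requires binary 0/1 labels")
    w = np.where(y == 1.0, pos_weight, 1.0)
    # stable softplus(z) - y z = max(z,0) - y z + log1p(exp(-|z|))
    per = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    wsum = w.sum()
    loss = float((w * per).sum() / wsum)
    grad = w * (sigmoid(z) - y) / wsum
    return loss, grad


def mse_loss(scores: np.ndarray, targets: np.ndarray):
    """Mean squared error and its gradient with respect to the scores."""
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError("mse_loss: shape mismatch")
    r = s - t
    n = s.size
    return float((r * r).sum() / n), 2.0 * r / n
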