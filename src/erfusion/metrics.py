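"""Evaluation metrics for binary DTI prediction and affinity regression.

Binary tasks: ROC AUC (rank-based with midrank tie handling, via
scikit-learn), area under the precision-recall step curve, and thresholded
precision/recall.  Regression tasks: MSE and the concordance index (CI) from
the kinase-affinity benchmark lineage, with half credit for prediction ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["roc_auc", "pr_auc", "precision_recall", "mse", "concordance_index",
           "MetricReport"]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve over all score thresholds.

    Computed as sum over descending distinct thresholds of
    (recall_t - recall_{t-1}) * precision_t, i.e. average precision.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("pr_auc requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # evaluate only at the last index of each tied block of scores
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev) * precision))


def precision_recall(probs, labels, threshold: float = 0.5):
    """Precision and recall of the decision rule prob > threshold.

    Precision is 0 by convention when nothing is predicted positive.
    """
    labels = _check_binary(labels)
    pred = np.asarray(probs, dtype=np.float64) > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def mse(pred, true) -> float:
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(true, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("mse: length mismatch")
    return float(np.mean((p - t) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """CI = (1/Z) sum over pairs with delta_i > delta_j of h(b_i - b_j),
    where h is 1 for a concordant prediction, 0.5 for a tie, 0 otherwise,
    and Z counts pairs with distinct true values."""
    t = np.asarray(y_true, dtype=np.float64)
    b = np.asarray(y_pred, dtype=np.float64)
    if t.shape != b.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("concordance_index needs two equal-length vectors, n >= 2")
    dt = t[:, None] - t[None, :]
    db = b[:, None] - b[None, :]
    mask = dt > 0  # ordered pairs with a strictly larger true value
    z = int(mask.sum())
    if z == 0:
        raise ValueError("concordance_index undefined: all true values equal")
    h = np.where(db[mask] > 0, 1.0, np.where(db[mask] == 0, 0.5, 0.0))
    return float(h.sum() / z)


@dataclass
class MetricReport:
    """Per-fold metric values plus their mean."""

    task: str
    folds: list = field(default_factory=list)  # list of {metric: value} dicts

    @property
    def mean(self) -> dict:
        if not self.folds:
            return {}
        keys = self.folds[0].keys()
        return {k: float(np.mean([f[k] for f in self.folds])) for k in keys}

    def extend(self, other: "MetricReport") -> None:
        if other.task != self.task:
            raise ValueError("cannot merge reports of different tasks")
        self.folds.extend(other.folds)

    def to_json(self, path=None):
        obj = {"task": self.task, "folds": self.folds, "mean": self.mean}
        if path is None:
            return json.dumps(obj, indent=1)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    def to_tsv(self, path) -> None:
        keys = sorted(self.folds[0]) if self.folds else []
        with open(path, "w") as fh:
            fh.write("fold\t" + "\t".join(keys) + "\n")
            for i, f in enumerate(self.folds):
                fh.write("\t".join([str(i)] + [f"{f[k]:.6g}" for k in keys]) + "\n")
            m = self.mean
            fh.write("\t".join(["mean"] + [f"{m[k]:.6g}" for k in keys]) + "\n")
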