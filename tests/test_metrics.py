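"""Metric implementations against brute-force oracles and closed forms."""

import numpy as np
import pytest

from erfusion.metrics import (MetricReport, concordance_index, mse, pr_auc,
                              precision_recall, roc_auc)


# ---------------------------------------------------------------------------
# independent oracles (explicit loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def ci_pair_counting(y_true, y_pred):
    num = 0.0
    z = 0
    n = len(y_true)
    for i in range(n):
        for j in range(n):
            if y_true[i] > y_true[j]:
                z += 1
                d = y_pred[i] - y_pred[j]
                num += 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
    return num / z


def prauc_threshold_enumeration(scores, labels):
    """Step-curve area by exhaustive enumeration of distinct thresholds."""
    n_pos = sum(labels)
    pts = []
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        pts.append((tp / n_pos, tp / (tp + fp)))
    area, prev_r = 0.0, 0.0
    for r, p in pts:
        area += (r - prev_r) * p
        prev_r = r
    return area


# ---------------------------------------------------------------------------

def test_roc_auc_matches_pair_counting_with_ties(rng):
    for _ in range(30):
        n = int(rng.integers(10, 200))
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12)


def test_roc_auc_hand_cases():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.3, 0.3], [1, 0]) == 0.5
    with pytest.raises(ValueError):
        roc_auc([0.5, 0.6], [1, 1])


def test_random_scores_on_balanced_labels_give_half(rng):
    scores = rng.random(2000)
    labels = (rng.random(2000) < 0.5).astype(int)
    assert abs(roc_auc(scores, labels) - 0.5) < 0.05


def test_pr_auc_matches_exhaustive_enumeration(rng):
    for _ in range(50):
        n = int(rng.integers(2, 11))
        scores = rng.integers(0, 5, n).astype(float)
        labels = (rng.random(n) < 0.5).astype(int)
        if labels.sum() == 0:
            continue
        assert pr_auc(scores, labels) == pytest.approx(
            prauc_threshold_enumeration(list(scores), list(labels)), abs=1e-12)


def test_pr_auc_limits(rng):
    assert pr_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
    # random scores at prevalence p: area approaches p
    n = 5000
    scores = rng.random(n)
    labels = (rng.random(n) < 0.2).astype(int)
    assert pr_auc(scores, labels) == pytest.approx(0.2, abs=0.05)
    with pytest.raises(ValueError):
        pr_auc([0.1], [0])


def test_precision_recall_hand_counts():
    # TP=2 FP=1 FN=2
    probs = [0.9, 0.8, 0.7, 0.2, 0.3, 0.1]
    labels = [1, 1, 0, 1, 1, 0]
    p, r = precision_recall(probs, labels)
    assert (p, r) == (pytest.approx(2 / 3), pytest.approx(1 / 2))
    assert precision_recall([0.1, 0.2], [1, 1]) == (0.0, 0.0)  # nothing predicted
    assert precision_recall([0.9, 0.1], [1, 0]) == (1.0, 1.0)


def test_concordance_index_oracle_and_hand_cases(rng):
    assert concordance_index([1, 2, 3], [1, 3, 2]) == pytest.approx(2 / 3)
    assert concordance_index([1, 2, 3], [10, 20, 30]) == 1.0
    assert concordance_index([1, 2, 3], [30, 20, 10]) == 0.0
    for _ in range(30):
        n = int(rng.integers(3, 60))
        t = rng.integers(0, 6, n).astype(float)
        b = rng.integers(0, 6, n).astype(float)
        if np.unique(t).size < 2:
            continue
        assert concordance_index(t, b) == pytest.approx(ci_pair_counting(t, b), abs=1e-12)
    with pytest.raises(ValueError):
        concordance_index([2.0, 2.0], [1.0, 3.0])


def test_auc_and_ci_coincide_on_binary_truths(rng):
    """Both reduce to the Mann-Whitney statistic with midrank ties."""
    for _ in range(100):
        n = int(rng.integers(10, 80))
        labels = (rng.random(n) < 0.5).astype(float)
        scores = rng.integers(0, 6, n).astype(float)
        if labels.min() == labels.max():
            continue
        assert concordance_index(labels, scores) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12)


def test_permutation_invariance_and_score_flip(rng):
    n = 100
    scores = rng.random(n)  # continuous: ties almost surely absent
    labels = (rng.random(n) < 0.5).astype(int)
    perm = rng.permutation(n)
    assert roc_auc(scores[perm], labels[perm]) == pytest.approx(roc_auc(scores, labels))
    assert pr_auc(scores[perm], labels[perm]) == pytest.approx(pr_auc(scores, labels))
    assert roc_auc(1 - scores, labels) == pytest.approx(1 - roc_auc(scores, labels))


def test_mse_and_report():
    assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
    with pytest.raises(ValueError):
        mse([1.0], [1.0, 2.0])
    rep = MetricReport(task="binary", folds=[{"auc": 0.8}, {"auc": 0.6}])
    assert rep.mean == {"auc": pytest.approx(0.7)}
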