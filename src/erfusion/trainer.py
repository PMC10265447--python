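"""Seeded multitask optimization of an ER model.

Training follows the published recipe: Adam at learning rate 1e-3 with weight
decay 1e-3 (applied decoupled from the adaptive step), class-balanced BCE for
binary relations, MSE for regressions.  Each epoch makes one pass over every
relation's training cells (optionally capped for dense self-relations), with
minibatches of all relations shuffled together so tasks interleave.  All
randomness flows from one integer seed; on a single thread two fits with the
same seed produce bit-identical loss histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .graph import BINARY, ERGraph
from .losses import positive_class_weight
from .metrics import MetricReport, concordance_index, mse, pr_auc, precision_recall, roc_auc
from .model import ERModel

__all__ = ["TrainConfig", "TrainHistory", "TrainError", "fit", "evaluate"]


class TrainError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.001
    epochs: int = 200
    batch_size: int = 512
    seed: int = 0
    per_relation_cap: Optional[int] = 20000
    patience: int = 20            # early stop after this many non-improving epochs
    min_delta: float = 1e-5       # improvement threshold on the global train loss
    balance_direction: str = "neg_over_pos"  # or "pos_over_neg", the literal ratio
    decoupled_weight_decay: bool = False     # True -> AdamW-style shrink
    activation: str = "tanh"
    layer_norm: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("bad epochs/batch_size")


@dataclass
class TrainHistory:
    global_loss: list = field(default_factory=list)
    per_relation: dict = field(default_factory=dict)  # name -> list of epoch losses
    stopped_epoch: Optional[int] = None

    def to_tsv(self, path) -> None:
        names = sorted(self.per_relation)
        with open(path, "w") as fh:
            fh.write("epoch\tglobal_loss\t" + "\t".join(names) + "\n")
            for i, g in enumerate(self.global_loss):
                row = [str(i), f"{g:.10g}"] + [f"{self.per_relation[n][i]:.10g}" for n in names]
                fh.write("\t".join(row) + "\n")


class _Adam:
    """Adam stepping every parameter each call.

    Weight decay is L2-coupled by default (added to the gradient before the
    moment updates, the torch ``Adam(weight_decay=...)`` semantics the
    published configuration relies on); pass ``decoupled=True`` for the
    AdamW-style multiplicative shrink instead.
    """

    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8,
                 decoupled=False):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self._buf = [np.empty_like(p.value) for p in params]

    def step(self):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, m, v, buf in zip(self.params, self.m, self.v, self._buf):
            g = p.grad
            if self.wd and not self.decoupled:
                g += self.wd * p.value  # grads are re-zeroed each step
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            if self.wd and self.decoupled:
                p.value *= 1.0 - self.lr * self.wd
            np.sqrt(v, out=buf)
            buf *= 1.0 / np.sqrt(c2)
            buf += self.eps
            np.divide(m, buf, out=buf)
            p.value -= (self.lr / c1) * buf


def fit(graph: ERGraph, train_cells: Optional[dict] = None,
        config: Optional[TrainConfig] = None, model: Optional[ERModel] = None):
    """Optimize the multitask objective; returns (model, TrainHistory).

    ``train_cells`` maps relation name -> index array into that relation's
    observed cells; relations absent from the mapping train on all their
    cells, and an explicit empty array freezes a relation out of the loss.
    """
    config = config or TrainConfig()
    train_cells = dict(train_cells or {})
    graph.validate()

    active: dict[str, np.ndarray] = {}
    for rname, rel in graph.relations.items():
        idx = train_cells.get(rname)
        idx = np.arange(len(rel.cells)) if idx is None else np.asarray(idx, dtype=np.intp)
        if rel.main and len(idx) == 0:
            raise TrainError("main relation has no training cells")
        if len(idx):
            active[rname] = idx

    if model is None:
        model = ERModel(graph, seed=config.seed, activation=config.activation,
                        layer_norm=config.layer_norm)
    model.train_cells = {r: np.sort(i) for r, i in active.items()}

    # class-balance weights from each binary relation's *training* labels
    for rname, idx in active.items():
        rel = graph.relations[rname]
        if rel.task == BINARY and rel.loss_id == "bce_balanced":
            model.pos_weight[rname] = positive_class_weight(
                rel.values[idx], config.balance_direction)

    # instances touched by any training cell keep the 'trained' mark
    for rname, idx in active.items():
        rel = graph.relations[rname]
        model.trained_instances[rel.src.name][rel.cells[idx, 0]] = True
        model.trained_instances[rel.dst.name][rel.cells[idx, 1]] = True

    params = model.params()
    opt = _Adam(params, config.learning_rate, config.weight_decay,
                decoupled=config.decoupled_weight_decay)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory(per_relation={r: [] for r in active})

    best = np.inf
    bad_epochs = 0
    for epoch in range(config.epochs):
        tasks = []
        for rname in sorted(active):
            idx = active[rname]
            perm = rng.permutation(len(idx))
            if config.per_relation_cap is not None:
                perm = perm[: config.per_relation_cap]
            for start in range(0, len(perm), config.batch_size):
                tasks.append((rname, idx[perm[start:start + config.batch_size]]))
        order = rng.permutation(len(tasks))

        sums = {r: 0.0 for r in active}
        counts = {r: 0 for r in active}
        for ti in order:
            rname, batch = tasks[ti]
            rel = graph.relations[rname]
            model.zero_grad()
            loss = model.relation_loss(
                rname, rel.cells[batch, 0], rel.cells[batch, 1], rel.values[batch],
                backward=True)
            if not np.isfinite(loss):
                raise TrainError(f"non-finite loss in relation {rname!r} at epoch {epoch}")
            opt.step()
            sums[rname] += loss
            counts[rname] += 1

        for r in active:
            history.per_relation[r].append(sums[r] / max(counts[r], 1))
        g = sum(graph.relations[r].weight * history.per_relation[r][-1] for r in active)
        history.global_loss.append(g)

        if best - g > config.min_delta:
            best = g
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                history.stopped_epoch = epoch
                break

    return model, history


def evaluate(model: ERModel, relation: str, test_cells) -> MetricReport:
    """Metrics on held-out cells of a relation, with a train/test leakage guard.

    ``test_cells`` indexes into the relation's observed cells.  Any overlap
    with the cells the model was trained on is a hard error.
    """
    rel = model.graph.relations[relation]
    test_idx = np.asarray(test_cells, dtype=np.intp)
    trained = model.train_cells.get(relation)
    if trained is not None and len(trained):
        overlap = np.intersect1d(test_idx, trained)
        if len(overlap):
            raise TrainError(
                f"leakage: {len(overlap)} test cells of relation {relation!r} "
                f"were used for training")
    rows, cols = rel.cells[test_idx, 0], rel.cells[test_idx, 1]
    y = rel.values[test_idx]
    scores, probs, _ = model.predict(relation, rows, cols)
    if rel.task == BINARY:
        prec, rec = precision_recall(probs, y)
        vals = {"auc": roc_auc(probs, y), "auprc": pr_auc(probs, y),
                "precision": prec, "recall": rec}
    else:
        vals = {"mse": mse(scores, y), "ci": concordance_index(y, scores)}
    return MetricReport(task=rel.task, folds=[vals])
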