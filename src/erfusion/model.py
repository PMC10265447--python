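"""The neural factorization model over an ER graph.

Every entity owns one embedding table e_i and one entity module f_i (a small
tanh/layer-norm MLP); entities participating in several relations share that
single table and module, which is the mechanism by which auxiliary relations
inform the main task.  A relation between entities i and j is scored by a
relation module M_ij(f_i(e_i), f_j(e_j)): a bilinear stage followed by a
feed-forward head producing one raw score per observed cell.  Side-information
features are mixed into an entity's latent additively through a bilinear
mixer, so zero features leave the latent untouched.

The multitask training objective is sum over relations of omega_ij * L_ij.
"""

from __future__ import annotations

import io
import json
import zipfile

import numpy as np

from . import nn
from .graph import BINARY, ERGraph, Relation
from .losses import balanced_bce, mse_loss, sigmoid

__all__ = ["ERModel"]


class ERModel:
    """Trainable parameters plus forward/backward machinery for one ERGraph."""

    def __init__(self, graph: ERGraph, seed: int = 0, activation: str = "tanh",
                 layer_norm: bool = True):
        graph.validate()
        self.graph = graph
        self.seed = int(seed)
        self.activation = activation
        self.layer_norm = layer_norm
        rng = np.random.default_rng(self.seed)

        self.embeddings: dict[str, nn.Embedding] = {}
        self.entity_modules: dict[str, nn.MLP] = {}
        self.mixers: dict[str, nn.FeatureMixer] = {}
        for name, ent in graph.entities.items():
            self.embeddings[name] = nn.Embedding(name, ent.n_instances, ent.embedding_dim, rng)
            self.entity_modules[name] = nn.MLP(
                f"{name}.f", ent.embedding_dim, ent.module_width, ent.module_depth, rng,
                activation=activation, norm=layer_norm)
        for name, si in graph.side_infos.items():
            ent = si.entity
            self.mixers[name] = nn.FeatureMixer(
                f"{name}.mixer", ent.embedding_dim, si.dim, ent.latent_dim, rng)

        self.relation_modules: dict[str, nn.RelationHead] = {}
        for rname, rel in graph.relations.items():
            self.relation_modules[rname] = nn.RelationHead(
                rname, rel.src.latent_dim, rel.dst.latent_dim, rng,
                bilinear_dim=rel.bilinear_dim, head_depth=rel.head_depth,
                head_width=rel.head_width, activation=activation, norm=layer_norm,
                pure_bilinear=rel.pure_bilinear)

        # filled in by the trainer
        self.pos_weight: dict[str, float] = {}
        self.train_cells: dict[str, np.ndarray] = {}
        self.trained_instances: dict[str, np.ndarray] = {
            name: np.zeros(ent.n_instances, dtype=bool) for name, ent in graph.entities.items()}
        self._observed_keys: dict[str, set] = {}

    # -- parameters -------------------------------------------------------
    def params(self) -> list[nn.Param]:
        if not hasattr(self, "_params_cache"):
            out = []
            for coll in (self.embeddings, self.entity_modules, self.mixers,
                         self.relation_modules):
                for mod in coll.values():
                    out.extend(mod.params())
            self._params_cache = out
        return self._params_cache

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward ----------------------------------------------------------
    def _latent_forward(self, entity: str, idx: np.ndarray):
        emb = self.embeddings[entity]
        e, c_emb = emb.forward(idx)
        z, c_mod = self.entity_modules[entity].forward(e)
        c_mix = None
        if entity in self.mixers:
            X = self.graph.side_infos[entity].features[np.asarray(idx, dtype=np.intp)]
            m, c_mix = self.mixers[entity].forward(e, X)
            z = z + m
        return z, (entity, c_emb, c_mod, c_mix)

    def _latent_backward(self, cache, grad):
        entity, c_emb, c_mod, c_mix = cache
        de = self.entity_modules[entity].backward(c_mod, grad)
        if c_mix is not None:
            de = de + self.mixers[entity].backward(c_mix, grad)
        self.embeddings[entity].backward(c_emb, de)

    def entity_latent(self, entity: str, indices) -> np.ndarray:
        """Latent representation f_i(e_i[indices]) with side info mixed in."""
        if entity not in self.graph.entities:
            raise KeyError(f"unknown entity {entity!r}")
        idx = np.asarray(indices, dtype=np.intp)
        n = self.graph.entities[entity].n_instances
        if len(idx) and (idx.min() < 0 or idx.max() >= n):
            raise IndexError(f"entity {entity!r}: index out of range")
        z, _ = self._latent_forward(entity, idx)
        return z

    def _score_forward(self, rel: Relation, rows: np.ndarray, cols: np.ndarray):
        zu, cu = self._latent_forward(rel.src.name, rows)
        zv, cv = self._latent_forward(rel.dst.name, cols)
        s, ch = self.relation_modules[rel.name].forward(zu, zv)
        return s, (cu, cv, ch)

    def _score_backward(self, rel: Relation, cache, dscore):
        cu, cv, ch = cache
        du, dv = self.relation_modules[rel.name].backward(ch, dscore)
        self._latent_backward(cu, du)
        self._latent_backward(cv, dv)

    def relation_score(self, relation: str, row_indices, col_indices) -> np.ndarray:
        """Raw score per (row, col) pair; sigmoid gives the probability for
        binary tasks, for regression the score is the prediction."""
        rel = self._rel(relation)
        rows = np.asarray(row_indices, dtype=np.intp)
        cols = np.asarray(col_indices, dtype=np.intp)
        if rows.shape != cols.shape:
            raise ValueError("row/col index vectors must have equal length")
        if len(rows):
            if rows.min() < 0 or rows.max() >= rel.src.n_instances:
                raise IndexError("row index out of range")
            if cols.min() < 0 or cols.max() >= rel.dst.n_instances:
                raise IndexError("col index out of range")
        s, _ = self._score_forward(rel, rows, cols)
        return s

    # -- losses -----------------------------------------------------------
    def _rel(self, relation: str) -> Relation:
        if relation not in self.graph.relations:
            raise KeyError(f"unknown relation {relation!r}")
        return self.graph.relations[relation]

    def _observed(self, rel: Relation) -> set:
        if rel.name not in self._observed_keys:
            keys = rel.cells[:, 0] * rel.dst.n_instances + rel.cells[:, 1]
            self._observed_keys[rel.name] = set(keys.tolist())
        return self._observed_keys[rel.name]

    def relation_loss(self, relation: str, rows, cols, values, backward: bool = False) -> float:
        """Loss of one relation on a batch of its observed cells.

        With ``backward=True`` parameter gradients (scaled by the relation's
        weight omega) are accumulated in place.
        """
        rel = self._rel(relation)
        rows = np.asarray(rows, dtype=np.intp)
        cols = np.asarray(cols, dtype=np.intp)
        values = np.asarray(values, dtype=np.float64)
        obs = self._observed(rel)
        keys = rows * rel.dst.n_instances + cols
        for k in keys.tolist():
            if k not in obs:
                raise ValueError(f"relation {relation!r}: batch references unobserved cell")
        s, cache = self._score_forward(rel, rows, cols)
        if rel.loss_id == "bce_balanced":
            loss, grad = balanced_bce(s, values, self.pos_weight.get(relation, 1.0))
        else:
            loss, grad = mse_loss(s, values)
        if backward:
            self._score_backward(rel, cache, rel.weight * grad)
        return loss

    def global_loss(self, batches: dict) -> float:
        """Weighted multitask objective sum_ij omega_ij L_ij on the given
        per-relation batches (each drawn from observed cells only)."""
        total = 0.0
        for rname, (rows, cols, values) in batches.items():
            rel = self._rel(rname)
            total += rel.weight * self.relation_loss(rname, rows, cols, values)
        return total

    # -- prediction -------------------------------------------------------
    def predict(self, relation: str, row_indices, col_indices):
        """Scores for arbitrary pairs, plus probabilities for binary tasks and
        an 'untrained' flag per pair (an endpoint instance never observed in
        any training cell keeps its random embedding)."""
        rel = self._rel(relation)
        rows = np.asarray(row_indices, dtype=np.intp)
        cols = np.asarray(col_indices, dtype=np.intp)
        scores = self.relation_score(relation, rows, cols)
        untrained = (~self.trained_instances[rel.src.name][rows]) | \
                    (~self.trained_instances[rel.dst.name][cols])
        probs = sigmoid(scores) if rel.task == BINARY else None
        return scores, probs, untrained

    # -- serialization ----------------------------------------------------
    def save(self, path: str) -> None:
        """Single-archive serialization: parameter arrays + config + seed."""
        cfg = {
            "seed": self.seed,
            "activation": self.activation,
            "layer_norm": self.layer_norm,
            "pos_weight": self.pos_weight,
            "entities": {n: {"n_instances": e.n_instances, "embedding_dim": e.embedding_dim,
                             "module_depth": e.module_depth, "module_width": e.module_width}
                         for n, e in self.graph.entities.items()},
            "relations": sorted(self.graph.relations),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(cfg, indent=1))
            buf = io.BytesIO()
            np.savez(buf, **{p.name: p.value for p in self.params()},
                     **{f"__trained__{n}": m for n, m in self.trained_instances.items()})
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str, graph: ERGraph) -> "ERModel":
        """Restore a saved model onto a structurally identical graph."""
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            arrays = np.load(io.BytesIO(zf.read("params.npz")))
            model = cls(graph, seed=cfg["seed"], activation=cfg["activation"],
                        layer_norm=cfg["layer_norm"])
            model.pos_weight = {k: float(v) for k, v in cfg["pos_weight"].items()}
            for p in model.params():
                if p.name not in arrays:
                    raise ValueError(f"archive missing parameter {p.name!r}")
                if arrays[p.name].shape != p.value.shape:
                    raise ValueError(f"archive shape mismatch for {p.name!r}")
                p.value[...] = arrays[p.name]
            for n in model.trained_instances:
                key = f"__trained__{n}"
                if key in arrays:
                    model.trained_instances[n] = arrays[key].astype(bool)
        return model
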