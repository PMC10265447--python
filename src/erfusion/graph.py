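"""The entity-relation (ER) graph data model.

An ER graph is the abstract object the model factorizes: a set of entities
(drugs, proteins, domains, ...), each backed by one shared embedding table,
connected by sparsely observed relation matrices, each carrying its own task
type (binary or regression), loss, and relevance weight omega.  Auxiliary
per-instance feature matrices can be attached to an entity as side
information instead of as a relation.

G1 denotes the minimal graph with only the main drug-protein interaction
relation; G* graphs add auxiliary relations (similarity self-relations,
domain incidence, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse as sp

BINARY = "binary"
REGRESSION = "regression"
LOSSES = {"bce_balanced", "mse"}

# architecture defaults from the published configuration
DEFAULT_EMBEDDING_DIM = {"protein": 30, "drug": 20, "domain": 10}
DEFAULT_MODULE_WIDTH = {"protein": 20, "drug": 10, "domain": 10}


class GraphError(ValueError):
    pass


@dataclass
class Entity:
    """A class of objects represented by one trainable embedding table."""

    name: str
    n_instances: int
    embedding_dim: int
    module_depth: int = 3
    module_width: int = 10
    ids: list = field(default_factory=list)          # instance id per row
    id_index: dict = field(default_factory=dict)     # instance id -> row

    def bind_ids(self, ids) -> None:
        ids = list(ids)
        if len(ids) != self.n_instances:
            raise GraphError(f"entity {self.name!r}: {len(ids)} ids for {self.n_instances} instances")
        if len(set(ids)) != len(ids):
            raise GraphError(f"entity {self.name!r}: duplicate instance ids")
        self.ids = ids
        self.id_index = {x: i for i, x in enumerate(ids)}

    @property
    def latent_dim(self) -> int:
        return self.module_width if self.module_depth > 0 else self.embedding_dim


@dataclass
class Relation:
    """One sparsely observed matrix between two entities, as a prediction task.

    ``cells`` is an (n, 2) integer array of (row, col) indices and ``values``
    the observed entries.  A self-relation has src is dst and shares the
    single embedding table of that entity.
    """

    name: str
    src: Entity
    dst: Entity
    cells: np.ndarray
    values: np.ndarray
    task: str = BINARY
    loss_id: str = "bce_balanced"
    weight: float = 1.0
    main: bool = False
    # relation-module architecture knobs (paper-silent values configurable)
    bilinear_dim: int = 10
    head_depth: int = 2
    head_width: int = 10
    pure_bilinear: bool = False

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.intp).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if len(self.cells) != len(self.values):
            raise GraphError(f"relation {self.name!r}: {len(self.cells)} cells vs {len(self.values)} values")
        if self.task not in (BINARY, REGRESSION):
            raise GraphError(f"relation {self.name!r}: unknown task {self.task!r}")
        if self.loss_id not in LOSSES:
            raise GraphError(f"relation {self.name!r}: unknown loss {self.loss_id!r}")
        if self.weight < 0:
            raise GraphError(f"relation {self.name!r}: negative weight")
        if len(self.cells):
            r, c = self.cells[:, 0], self.cells[:, 1]
            if r.min() < 0 or r.max() >= self.src.n_instances:
                raise GraphError(f"relation {self.name!r}: row index out of range for {self.src.name!r}")
            if c.min() < 0 or c.max() >= self.dst.n_instances:
                raise GraphError(f"relation {self.name!r}: col index out of range for {self.dst.name!r}")
            key = r * self.dst.n_instances + c
            if len(np.unique(key)) != len(key):
                raise GraphError(f"relation {self.name!r}: duplicate (row, col) cells")
        if self.task == BINARY and len(self.values):
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise GraphError(f"relation {self.name!r}: binary task with non-0/1 values")

    @property
    def is_self(self) -> bool:
        return self.src is self.dst


@dataclass
class SideInfo:
    """Per-instance features mixed into an entity's latent representation."""

    entity: Entity
    features: object  # dense ndarray or scipy.sparse matrix, n_instances x d

    def __post_init__(self):
        n = self.features.shape[0]
        if n != self.entity.n_instances:
            raise GraphError(
                f"side info for {self.entity.name!r}: {n} feature rows for "
                f"{self.entity.n_instances} instances")
        if sp.issparse(self.features):
            self.features = self.features.tocsr().astype(np.float64)
        else:
            self.features = np.asarray(self.features, dtype=np.float64)

    @property
    def dim(self) -> int:
        return self.features.shape[1]


class ERGraph:
    """Registry of entities, relations, and side information."""

    def __init__(self):
        self.entities: dict[str, Entity] = {}
        self.relations: dict[str, Relation] = {}
        self.side_infos: dict[str, SideInfo] = {}

    # -- construction -----------------------------------------------------
    def add_entity(self, name: str, n_instances: int, embedding_dim: Optional[int] = None,
                   module_depth: int = 3, module_width: Optional[int] = None,
                   ids=None) -> Entity:
        if name in self.entities:
            raise GraphError(f"duplicate entity {name!r}")
        if n_instances < 1:
            raise GraphError(f"entity {name!r}: n_instances must be >= 1")
        if embedding_dim is None:
            embedding_dim = DEFAULT_EMBEDDING_DIM.get(name, 20)
        if embedding_dim < 1:
            raise GraphError(f"entity {name!r}: embedding_dim must be >= 1")
        if module_width is None:
            module_width = DEFAULT_MODULE_WIDTH.get(name, 10)
        ent = Entity(name, n_instances, embedding_dim,
                     module_depth=module_depth, module_width=module_width)
        if ids is not None:
            ent.bind_ids(ids)
        self.entities[name] = ent
        return ent

    def add_relation(self, name: str, src: str, dst: str, cells, values,
                     task: str = BINARY, loss_id: Optional[str] = None,
                     weight: float = 1.0, main: bool = False, **module_kwargs) -> Relation:
        if name in self.relations:
            raise GraphError(f"duplicate relation {name!r}")
        for e in (src, dst):
            if e not in self.entities:
                raise GraphError(f"relation {name!r}: unregistered entity {e!r}")
        if loss_id is None:
            loss_id = "bce_balanced" if task == BINARY else "mse"
        rel = Relation(name, self.entities[src], self.entities[dst],
                       cells, values, task=task, loss_id=loss_id, weight=weight,
                       main=main, **module_kwargs)
        self.relations[name] = rel
        return rel

    def add_side_info(self, entity: str, features) -> SideInfo:
        if entity not in self.entities:
            raise GraphError(f"side info: unregistered entity {entity!r}")
        if entity in self.side_infos:
            raise GraphError(f"duplicate side info for entity {entity!r}")
        si = SideInfo(self.entities[entity], features)
        self.side_infos[entity] = si
        return si

    # -- queries ----------------------------------------------------------
    @property
    def main_relation(self) -> Relation:
        mains = [r for r in self.relations.values() if r.main]
        if not mains:
            raise GraphError("no relation designated as main task")
        return mains[0]

    def validate(self) -> None:
        self.main_relation  # raises if absent
        for rel in self.relations.values():
            if rel.src.name not in self.entities or rel.dst.name not in self.entities:
                raise GraphError(f"relation {rel.name!r} references unregistered entity")
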