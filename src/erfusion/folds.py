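"""Cross-validation stratification schemes and leakage diagnostics.

Five fold schemes of increasing stringency over a bipartite interaction
matrix:

- ``random``: cells partitioned uniformly at random.
- ``no_strat``: random partition repaired so that every drug and protein in a
  test fold also occurs in that fold's training cells.
- ``protein_strat`` / ``drug_strat``: the named entity's instances are
  partitioned into k groups; a fold's test cells are the cells of one group,
  so no test protein (resp. drug) is seen in training.
- ``pair_strat``: drugs and proteins are independently partitioned into k
  groups; fold f tests cells whose drug AND protein are both in group f,
  trains on cells with neither endpoint in group f, and discards cells with
  exactly one held-out endpoint.  This is the cold-start-for-both setting; the
  expected discarded fraction per fold is 2(k-1)/k^2 for uniform groupings.

``polarization_report`` measures the fraction of entities whose observed
interactions carry a single label - the property that lets entity-wise CV
leak "generally active/inactive" information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["FoldPlan", "make_folds", "polarization_report", "verify_folds",
           "PolarizationReport", "SCHEMES"]

SCHEMES = ("random", "no_strat", "protein_strat", "drug_strat", "pair_strat")

TRAIN, TEST, DISCARDED = "train", "test", "discarded"


@dataclass
class FoldPlan:
    scheme: str
    k: int
    seed: int
    cells: np.ndarray                      # (n, 2) drug, protein indices
    fold_of_cell: Optional[np.ndarray] = None   # partition schemes
    drug_group: Optional[np.ndarray] = None     # pair_strat
    protein_group: Optional[np.ndarray] = None  # pair_strat

    def split(self, f: int):
        """(train_idx, test_idx, discarded_idx) for fold f."""
        if not 0 <= f < self.k:
            raise IndexError(f"fold {f} out of range")
        n = len(self.cells)
        if self.scheme == "pair_strat":
            dg = self.drug_group[self.cells[:, 0]]
            pg = self.protein_group[self.cells[:, 1]]
            test = (dg == f) & (pg == f)
            train = (dg != f) & (pg != f)
            disc = ~(test | train)
            idx = np.arange(n)
            return idx[train], idx[test], idx[disc]
        test = self.fold_of_cell == f
        idx = np.arange(n)
        return idx[~test], idx[test], idx[:0]

    # -- serialization: one row per (cell, fold) --------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scheme={self.scheme}\tk={self.k}\tseed={self.seed}\n")
            if self.scheme == "pair_strat":
                fh.write("# drug_group=" + ",".join(map(str, self.drug_group)) + "\n")
                fh.write("# protein_group=" + ",".join(map(str, self.protein_group)) + "\n")
            fh.write("cell\tfold\tstatus\n")
            for f in range(self.k):
                train, test, disc = self.split(f)
                for name, idxs in ((TRAIN, train), (TEST, test), (DISCARDED, disc)):
                    for i in idxs:
                        fh.write(f"{i}\t{f}\t{name}\n")

    @classmethod
    def from_tsv(cls, path, cells) -> "FoldPlan":
        cells = np.asarray(cells, dtype=np.intp)
        groups = {}
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            line = fh.readline()
            while line.startswith("#"):
                key, val = line.lstrip("# ").rstrip("\n").split("=", 1)
                groups[key] = np.array([int(x) for x in val.split(",")], dtype=np.intp)
                line = fh.readline()
            status = {}
            for line in fh:
                c, f, s = line.split()
                status[(int(c), int(f))] = s
        plan = cls(scheme=meta["scheme"], k=int(meta["k"]), seed=int(meta["seed"]),
                   cells=cells)
        if plan.scheme == "pair_strat":
            plan.drug_group = groups["drug_group"]
            plan.protein_group = groups["protein_group"]
        else:
            plan.fold_of_cell = np.zeros(len(cells), dtype=np.intp)
            for (c, f), s in status.items():
                if s == TEST:
                    plan.fold_of_cell[c] = f
        return plan


def _balanced_partition(n: int, k: int, rng) -> np.ndarray:
    group = np.arange(n) % k
    return group[rng.permutation(n)]


def make_folds(cells, scheme: str, k: int = 5, seed: int = 0,
               n_drugs: Optional[int] = None, n_proteins: Optional[int] = None,
               max_repair_passes: int = 100) -> FoldPlan:
    """Build a FoldPlan for one of the five schemes (seeded)."""
    cells = np.asarray(cells, dtype=np.intp).reshape(-1, 2)
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(cells)
    n_drugs = int(cells[:, 0].max()) + 1 if n_drugs is None else n_drugs
    n_proteins = int(cells[:, 1].max()) + 1 if n_proteins is None else n_proteins
    rng = np.random.default_rng(seed)
    plan = FoldPlan(scheme=scheme, k=k, seed=seed, cells=cells)

    if scheme in ("random", "no_strat"):
        plan.fold_of_cell = _balanced_partition(n, k, rng)
        if scheme == "no_strat":
            _repair_no_strat(plan, rng, max_repair_passes)
        return plan

    if scheme in ("protein_strat", "drug_strat"):
        col = 1 if scheme == "protein_strat" else 0
        ents = np.unique(cells[:, col])
        if len(ents) < k:
            raise ValueError(f"{scheme}: only {len(ents)} distinct entities for k={k}")
        size = n_proteins if col == 1 else n_drugs
        group = np.full(size, -1, dtype=np.intp)
        group[ents] = _balanced_partition(len(ents), k, rng)
        # instances with no observed cell get an arbitrary group
        group[group == -1] = rng.integers(0, k, size=(group == -1).sum())
        plan.fold_of_cell = group[cells[:, col]]
        return plan

    # pair_strat
    du = np.unique(cells[:, 0])
    pu = np.unique(cells[:, 1])
    if len(du) < k or len(pu) < k:
        raise ValueError(f"pair_strat: need at least k entities of each class")
    plan.drug_group = _balanced_partition(n_drugs, k, rng)
    plan.protein_group = _balanced_partition(n_proteins, k, rng)
    return plan


def _entity_cells(cells):
    """id -> cell indices, for drugs (col 0) and proteins (col 1)."""
    out = []
    for col in (0, 1):
        d: dict[int, list[int]] = {}
        for i, e in enumerate(cells[:, col].tolist()):
            d.setdefault(e, []).append(i)
        out.append(d)
    return out


def _repair_no_strat(plan: FoldPlan, rng, max_passes: int) -> None:
    """Move cells between folds until every entity with >= 2 cells spans at
    least two folds (so it is in training whenever it is in test).  Entities
    with a single observed cell cannot satisfy the contract and are left in
    place (verify_folds reports them separately)."""
    cells = plan.cells
    fold = plan.fold_of_cell
    by_entity = _entity_cells(cells)
    for _ in range(max_passes):
        moved = False
        for d in by_entity:
            for e, idxs in d.items():
                if len(idxs) < 2:
                    continue
                folds_here = {int(fold[i]) for i in idxs}
                if len(folds_here) == 1:
                    f = folds_here.pop()
                    target = int(rng.integers(plan.k - 1))
                    if target >= f:
                        target += 1
                    fold[idxs[int(rng.integers(len(idxs)))]] = target
                    moved = True
        if not moved:
            return


@dataclass
class PolarizationReport:
    """Fraction of entities whose observed labels are homogeneous."""

    drug_fraction: float
    protein_fraction: float
    combined: float
    n_drugs: int
    n_proteins: int


def polarization_report(cells, labels, task: str = "binary") -> PolarizationReport:
    if task != "binary":
        raise ValueError("polarization is defined for binary relations only")
    cells = np.asarray(cells, dtype=np.intp).reshape(-1, 2)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("polarization_report requires binary labels")
    fracs, ns, homs = [], [], []
    for col in (0, 1):
        hom = tot = 0
        for e, idxs in _entity_cells(cells)[col].items():
            lab = labels[idxs]
            tot += 1
            hom += int(lab.min() == lab.max())
        fracs.append(hom / tot if tot else 0.0)
        ns.append(tot)
        homs.append(hom)
    combined = (homs[0] + homs[1]) / (ns[0] + ns[1]) if (ns[0] + ns[1]) else 0.0
    return PolarizationReport(drug_fraction=fracs[0], protein_fraction=fracs[1],
                              combined=combined, n_drugs=ns[0], n_proteins=ns[1])


def verify_folds(plan: FoldPlan, cells=None) -> list[str]:
    """Scheme-specific disjointness / coverage / discard checks.

    Returns a list of violation messages; empty means the plan is valid.
    Entities with a single observed cell are exempt from the no_strat
    contract (it is unsatisfiable for them).
    """
    cells = plan.cells if cells is None else np.asarray(cells, dtype=np.intp)
    v: list[str] = []
    n = len(cells)
    tested = np.zeros(n, dtype=int)
    by_entity = _entity_cells(cells)
    counts = [{e: len(i) for e, i in d.items()} for d in by_entity]

    for f in range(plan.k):
        train, test, disc = plan.split(f)
        tested[test] += 1
        if np.intersect1d(train, test).size:
            v.append(f"fold {f}: train/test cell overlap")
        train_d = set(cells[train, 0].tolist())
        train_p = set(cells[train, 1].tolist())
        test_d = set(cells[test, 0].tolist())
        test_p = set(cells[test, 1].tolist())
        if plan.scheme == "no_strat":
            for d in sorted(test_d - train_d):
                if counts[0].get(d, 0) > 1:
                    v.append(f"fold {f}: drug {d} in test but not train")
            for p in sorted(test_p - train_p):
                if counts[1].get(p, 0) > 1:
                    v.append(f"fold {f}: protein {p} in test but not train")
        elif plan.scheme == "protein_strat":
            for p in sorted(test_p & train_p):
                v.append(f"fold {f}: protein {p} leaks between train and test")
        elif plan.scheme == "drug_strat":
            for d in sorted(test_d & train_d):
                v.append(f"fold {f}: drug {d} leaks between train and test")
        elif plan.scheme == "pair_strat":
            for d in sorted(test_d & train_d):
                v.append(f"fold {f}: drug {d} leaks between train and test")
            for p in sorted(test_p & train_p):
                v.append(f"fold {f}: protein {p} leaks between train and test")
            dg = plan.drug_group[cells[disc, 0]]
            pg = plan.protein_group[cells[disc, 1]]
            bad = (dg == f) == (pg == f)
            for i in np.asarray(disc)[bad]:
                v.append(f"fold {f}: cell {i} discarded without exactly one held-out endpoint")

    if plan.scheme in ("random", "no_strat"):
        if (tested != 1).any():
            v.append("cells not covered exactly once across test folds")
    elif plan.scheme in ("protein_strat", "drug_strat"):
        if (tested != 1).any():
            v.append("cells not covered exactly once across test folds")
    return v
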