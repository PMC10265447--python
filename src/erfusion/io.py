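"""File formats, experiment configuration, and the end-to-end pipeline driver.

Interchange formats are plain TSV: interaction tables (drug, protein, value),
dense similarity matrices with id headers, two-column annotation tables, and
fold plans.  Ids are opaque strings mapped to dense 0-based indices in
first-appearance order; the registry is persisted with every run so splits
stay valid across re-executions.  ``run_experiment`` drives the full loop -
build graph, make folds, fit per fold, evaluate - and in ablation mode
re-runs with each auxiliary relation cumulatively enabled, one metrics row
per graph variant.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .folds import FoldPlan, make_folds, verify_folds
from .graph import BINARY, REGRESSION, ERGraph
from .metrics import MetricReport
from .model import ERModel
from .relations import incidence_matrix
from .trainer import TrainConfig, evaluate, fit

log = logging.getLogger(__name__)

__all__ = ["read_interactions", "read_similarity", "read_annotations",
           "write_predictions", "read_predictions", "ExperimentConfig",
           "RunRecord", "run_experiment", "build_graph"]

PACKAGE_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_interactions(path):
    """Parse a 3-column TSV (drug_id, protein_id, value).

    Returns (cells, values, drug_ids, protein_ids) with ids mapped to dense
    indices in first-appearance order.  Malformed lines and duplicate pairs
    are hard errors naming the offending line/pair.
    """
    drug_index: dict[str, int] = {}
    prot_index: dict[str, int] = {}
    cells, values = [], []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            d, p, v = parts
            try:
                val = float(v)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {v!r}") from None
            if (d, p) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair ({d}, {p})")
            seen.add((d, p))
            di = drug_index.setdefault(d, len(drug_index))
            pi = prot_index.setdefault(p, len(prot_index))
            cells.append((di, pi))
            values.append(val)
    return (np.asarray(cells, dtype=np.intp), np.asarray(values, dtype=np.float64),
            list(drug_index), list(prot_index))


def read_similarity(path, ids):
    """Dense similarity TSV with id header row and id-labelled rows, aligned
    (reordered if needed) to the given registry order."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_ids = header[1:]  # leading header cell is a corner label (often empty)
        rows = {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows[parts[0]] = parts[1:]
    n = len(col_ids)
    if any(len(r) != n for r in rows.values()) or len(rows) != n:
        raise ValueError(f"{path}: similarity matrix is not square")
    missing = [i for i in ids if i not in rows]
    if missing:
        raise ValueError(f"{path}: missing entities {missing[:5]}")
    extra = [i for i in rows if i not in set(ids)]
    if extra:
        raise ValueError(f"{path}: ids not in the entity registry: {extra[:5]}")
    col_pos = {c: j for j, c in enumerate(col_ids)}
    M = np.empty((len(ids), len(ids)))
    for i, rid in enumerate(ids):
        row = rows[rid]
        for j, cid in enumerate(ids):
            M[i, j] = float(row[col_pos[cid]])
    if M.min() < 0 or M.max() > 1:
        log.warning("%s: similarity values outside [0, 1] kept as-is", path)
    return M


def read_annotations(path):
    """Two-column TSV ``entity_id<TAB>term`` -> id -> term-set mapping."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>term'")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_predictions(path, drug_ids, protein_ids, scores, probs=None, untrained=None) -> None:
    with open(path, "w") as fh:
        cols = ["drug_id", "protein_id", "score"]
        if probs is not None:
            cols.append("probability")
        if untrained is not None:
            cols.append("untrained")
        fh.write("\t".join(cols) + "\n")
        for i in range(len(drug_ids)):
            row = [drug_ids[i], protein_ids[i], f"{scores[i]:.10g}"]
            if probs is not None:
                row.append(f"{probs[i]:.10g}")
            if untrained is not None:
                row.append(str(int(untrained[i])))
            fh.write("\t".join(row) + "\n")


def read_predictions(path):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return header, rows


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

_RELATION_KINDS = ("similarity", "incidence")
_TOP_KEYS = {"interactions", "task", "relations", "side_info", "folds", "train",
             "output_dir", "embedding_dims", "ablation"}
_REL_KEYS = {"name", "kind", "entity", "file", "weight"}
_FOLD_KEYS = {"scheme", "k", "seed"}


@dataclass
class ExperimentConfig:
    interactions: str
    task: str = BINARY
    relations: list = field(default_factory=list)
    side_info: list = field(default_factory=list)   # [{entity, file}]
    folds: dict = field(default_factory=lambda: {"scheme": "random", "k": 5, "seed": 0})
    train: dict = field(default_factory=dict)
    output_dir: str = "run_out"
    embedding_dims: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for rel in raw.get("relations", []):
            bad = set(rel) - _REL_KEYS
            if bad:
                raise ValueError(f"unknown relation keys: {sorted(bad)}")
            if rel.get("kind") not in _RELATION_KINDS:
                raise ValueError(f"unknown relation kind {rel.get('kind')!r}")
        bad = set(raw.get("folds", {})) - _FOLD_KEYS
        if bad:
            raise ValueError(f"unknown fold keys: {sorted(bad)}")
        cfg = cls(**{k: v for k, v in raw.items() if k != "ablation"})
        base = Path(path).parent
        cfg.interactions = str((base / cfg.interactions))
        for rel in cfg.relations:
            rel["file"] = str(base / rel["file"])
        for si in cfg.side_info:
            si["file"] = str(base / si["file"])
        if not Path(cfg.interactions).exists():
            raise FileNotFoundError(cfg.interactions)
        for rel in cfg.relations:
            if not Path(rel["file"]).exists():
                raise FileNotFoundError(rel["file"])
        return cfg


@dataclass
class RunRecord:
    """Everything needed to re-execute a run bit-compatibly."""

    config: dict
    seeds: dict
    version: str
    graph_name: str
    metrics: dict          # MetricReport mean + folds
    fold_plan_file: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_graph(cfg: ExperimentConfig, cells, values, drug_ids, protein_ids,
                aux_names: Optional[list] = None) -> ERGraph:
    """Assemble the ER graph declared by a config, restricted to the
    auxiliary relations named in ``aux_names`` (None = all)."""
    g = ERGraph()
    dims = cfg.embedding_dims
    g.add_entity("drug", len(drug_ids), embedding_dim=dims.get("drug"), ids=drug_ids)
    g.add_entity("protein", len(protein_ids), embedding_dim=dims.get("protein"),
                 module_width=20, ids=protein_ids)
    task = cfg.task
    g.add_relation("dti", "drug", "protein", cells, values, task=task, main=True)

    registry = {"drug": drug_ids, "protein": protein_ids}
    for rel in cfg.relations:
        if aux_names is not None and rel["name"] not in aux_names:
            continue
        ent = rel["entity"]
        if rel["kind"] == "similarity":
            M = read_similarity(rel["file"], registry[ent])
            n = len(registry[ent])
            rows, cols = np.divmod(np.arange(n * n), n)
            g.add_relation(rel["name"], ent, ent, np.column_stack([rows, cols]),
                           M.ravel(), task=REGRESSION, weight=rel.get("weight", 1.0))
        elif rel["kind"] == "incidence":
            ann = read_annotations(rel["file"])
            id_index = {x: i for i, x in enumerate(registry[ent])}
            M, vocab = incidence_matrix(ann, id_index)
            if "domain" not in g.entities:
                g.add_entity("domain", len(vocab), ids=vocab)
            rows, cols = np.divmod(np.arange(M.size), M.shape[1])
            g.add_relation(rel["name"], ent, "domain", np.column_stack([rows, cols]),
                           M.ravel().astype(float), task=BINARY,
                           weight=rel.get("weight", 1.0))
    for si in cfg.side_info:
        ent = si["entity"]
        ann = read_annotations(si["file"])
        id_index = {x: i for i, x in enumerate(registry[ent])}
        M, _ = incidence_matrix(ann, id_index)
        g.add_side_info(ent, M.astype(float))
    return g


def run_experiment(cfg: ExperimentConfig, ablation: bool = False):
    """Execute the configured experiment; returns a list of RunRecords (one
    per graph variant; a single-element list unless ``ablation``)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells, values, drug_ids, protein_ids = read_interactions(cfg.interactions)

    fold_cfg = {"scheme": "random", "k": 5, "seed": 0} | cfg.folds
    plan = make_folds(cells, fold_cfg["scheme"], k=fold_cfg["k"], seed=fold_cfg["seed"],
                      n_drugs=len(drug_ids), n_proteins=len(protein_ids))
    violations = verify_folds(plan)
    if violations:
        raise RuntimeError(f"stage make-folds: invalid plan: {violations[:3]}")
    plan_path = outdir / "fold_plan.tsv"
    plan.to_tsv(plan_path)

    with open(outdir / "registry.tsv", "w") as fh:
        for kind, ids in (("drug", drug_ids), ("protein", protein_ids)):
            for i, x in enumerate(ids):
                fh.write(f"{kind}\t{x}\t{i}\n")

    aux_all = [r["name"] for r in cfg.relations]
    variants = [aux_all[:i] for i in range(len(aux_all) + 1)] if ablation else [aux_all]

    tcfg = TrainConfig(**cfg.train)
    records = []
    for aux in variants:
        gname = "G1" if not aux else "G1+" + "+".join(aux)
        report = MetricReport(task=cfg.task)
        for f in range(plan.k):
            train_idx, test_idx, _ = plan.split(f)
            graph = build_graph(cfg, cells, values, drug_ids, protein_ids, aux_names=aux)
            try:
                model, history = fit(graph, {"dti": train_idx}, tcfg)
            except Exception as exc:
                raise RuntimeError(f"stage fit (graph {gname}, fold {f}): {exc}") from exc
            report.extend(evaluate(model, "dti", test_idx))
            if f == 0:
                history.to_tsv(outdir / f"history_{gname}_fold0.tsv")
                rows, cols = cells[test_idx, 0], cells[test_idx, 1]
                scores, probs, unt = model.predict("dti", rows, cols)
                write_predictions(outdir / f"predictions_{gname}_fold0.tsv",
                                  [drug_ids[i] for i in rows],
                                  [protein_ids[i] for i in cols], scores, probs, unt)
        record = RunRecord(
            config=dataclasses.asdict(cfg), graph_name=gname,
            seeds={"folds": fold_cfg["seed"], "train": tcfg.seed},
            version=PACKAGE_VERSION,
            metrics={"folds": report.folds, "mean": report.mean},
            fold_plan_file=str(plan_path))
        record.to_json(outdir / f"run_record_{gname}.json")
        report.to_tsv(outdir / f"metrics_{gname}.tsv")
        records.append(record)

    with open(outdir / "metrics.json", "w") as fh:
        json.dump({r.graph_name: r.metrics for r in records}, fh, indent=1)
    return records
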