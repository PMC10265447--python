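"""Builders for auxiliary relations and side information.

Covers the standard preprocessing around the factorization model: Tanimoto
similarity between circular-fingerprint bit sets, row normalization of
alignment bit-score matrices, domain-annotation incidence matrices, sparse
fingerprint side information, the log-space transform of dissociation
constants, and seeded negative sampling by random pairing.

Alignment and domain scanning themselves are not performed here; their
precomputed outputs are the input contracts (TSV files).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "FingerprintSet", "AffinityRecord", "tanimoto_matrix", "row_normalize",
    "incidence_matrix", "load_fingerprints", "write_fingerprints",
    "smiles_fingerprints", "transform_affinity", "sample_negatives",
]


@dataclass
class FingerprintSet:
    """Sparse binary fingerprints, rows ordered like the drug registry.

    Defaults follow the similarity recipe (circular fingerprints of radius 2
    folded to 1028 bits); 30000 bits is the high-dimensional side-information
    variant, typically 0.1-0.2% dense.
    """

    ids: list
    bits: sp.csr_matrix
    n_bits: int = 1028
    radius: int = 2

    def __post_init__(self):
        self.bits = sp.csr_matrix(self.bits, dtype=np.int8)
        if self.bits.shape != (len(self.ids), self.n_bits):
            raise ValueError("fingerprint matrix shape does not match ids/n_bits")

    def onbits(self, i: int) -> set:
        return set(self.bits.indices[self.bits.indptr[i]:self.bits.indptr[i + 1]].tolist())

    @property
    def density(self) -> float:
        return self.bits.nnz / (self.bits.shape[0] * self.bits.shape[1])


@dataclass
class AffinityRecord:
    drug_id: str
    protein_id: str
    kd_nM: float  # dissociation constant in nanomolar


def tanimoto_matrix(fps: FingerprintSet) -> np.ndarray:
    """Dense pairwise Tanimoto (Jaccard) similarity in [0, 1].

    S[i, j] = |bits_i & bits_j| / |bits_i | bits_j|; a pair of two empty
    fingerprints is defined as 0 (no shared chemistry evidence), so the
    diagonal is 1 only for non-empty fingerprints.
    """
    B = fps.bits.astype(np.float64)
    inter = np.asarray((B @ B.T).todense())
    sizes = np.asarray(B.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return S


def row_normalize(M: np.ndarray) -> np.ndarray:
    """Divide each row with positive sum by that sum; zero rows pass through.

    The row-normalized form of an all-vs-all alignment bit-score matrix is
    the protein-protein similarity relation.  Note normalization breaks
    symmetry; the matrix is kept as produced.
    """
    M = np.asarray(M, dtype=np.float64)
    if (M < 0).any():
        raise ValueError("row_normalize requires non-negative entries")
    sums = M.sum(axis=1, keepdims=True)
    return np.divide(M, sums, out=M.copy(), where=sums > 0)


def incidence_matrix(annotations: dict, id_index: dict):
    """Binary entity x term matrix from an id -> term-set mapping.

    Rows follow ``id_index`` order, columns the sorted term vocabulary.
    Entities absent from the mapping get an all-zero row; ids absent from the
    registry are an error.
    """
    for eid in annotations:
        if eid not in id_index:
            raise KeyError(f"annotation for unknown entity id {eid!r}")
    vocab = sorted({t for terms in annotations.values() for t in terms})
    col = {t: j for j, t in enumerate(vocab)}
    M = np.zeros((len(id_index), len(vocab)), dtype=np.int8)
    for eid, terms in annotations.items():
        i = id_index[eid]
        for t in terms:
            M[i, col[t]] = 1
    return M, vocab


def load_fingerprints(path, ids=None, n_bits: int = 1028, radius: int = 2) -> FingerprintSet:
    """Read a sparse on-bit index file: ``id<TAB>comma-separated bit indices``.

    An empty index field denotes an empty fingerprint.  ``ids`` fixes the row
    order (entity registry order); by default rows follow file order.
    """
    rows: dict[str, list[int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>bits'")
            fid, bitfield = parts
            if fid in rows:
                raise ValueError(f"{path}:{lineno}: duplicate id {fid!r}")
            onbits = [int(b) for b in bitfield.split(",") if b.strip() != ""]
            for b in onbits:
                if not 0 <= b < n_bits:
                    raise ValueError(f"{path}:{lineno}: bit index {b} >= n_bits {n_bits}")
            rows[fid] = sorted(set(onbits))
            order.append(fid)
    if ids is None:
        ids = order
    else:
        missing = [i for i in ids if i not in rows]
        if missing:
            raise ValueError(f"fingerprint file missing ids: {missing[:5]}")
    indptr = [0]
    indices: list[int] = []
    for fid in ids:
        indices.extend(rows[fid])
        indptr.append(len(indices))
    bits = sp.csr_matrix((np.ones(len(indices), dtype=np.int8), indices, indptr),
                         shape=(len(ids), n_bits))
    return FingerprintSet(ids=list(ids), bits=bits, n_bits=n_bits, radius=radius)


def write_fingerprints(fps: FingerprintSet, path) -> None:
    with open(path, "w") as fh:
        for i, fid in enumerate(fps.ids):
            onbits = sorted(fps.onbits(i))
            fh.write(f"{fid}\t{','.join(map(str, onbits))}\n")


def smiles_fingerprints(smiles: dict, n_bits: int = 1028, radius: int = 2) -> FingerprintSet:
    """Morgan (extended-connectivity) fingerprints from SMILES via RDKit.

    Unparsable SMILES are skipped with a warning, matching how malformed
    structures are handled upstream.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ids, rows = [], []
    for fid, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            log.warning("skipping unparsable SMILES for %r", fid)
            continue
        fp = gen.GetFingerprint(mol)
        ids.append(fid)
        rows.append(sorted(fp.GetOnBits()))
    indptr = [0]
    indices: list[int] = []
    for onbits in rows:
        indices.extend(onbits)
        indptr.append(len(indices))
    bits = sp.csr_matrix((np.ones(len(indices), dtype=np.int8), indices, indptr),
                         shape=(len(ids), n_bits))
    return FingerprintSet(ids=ids, bits=bits, n_bits=n_bits, radius=radius)


def transform_affinity(records) -> np.ndarray:
    """pKd transform: Kd in nM -> -log10(Kd / 1e9).

    Kd = 1e9 nM (1 M) maps to 0; Kd = 1 nM maps to 9.  Smaller dissociation
    constants (stronger binding) give larger transformed values.  Scores that
    are already on a combined-bioactivity scale should be passed through
    unchanged rather than run through this transform.
    """
    kd = np.asarray([r.kd_nM if isinstance(r, AffinityRecord) else r for r in records],
                    dtype=np.float64)
    if (kd <= 0).any():
        raise ValueError("Kd values must be positive")
    return -np.log10(kd / 1e9)


def sample_negatives(positives, n_drugs: int, n_proteins: int, ratio: float = 1.0,
                     seed: int = 0) -> np.ndarray:
    """Uniform negative pairs by random pairing, excluding known positives.

    Returns ``round(ratio * len(positives))`` distinct (drug, protein) index
    pairs sampled without replacement from the complement of the positive set.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos = np.asarray(positives, dtype=np.intp).reshape(-1, 2)
    pos_keys = set((pos[:, 0] * n_proteins + pos[:, 1]).tolist())
    want = int(round(ratio * len(pos)))
    total = n_drugs * n_proteins
    if want > total - len(pos_keys):
        raise ValueError(
            f"requested {want} negatives but only {total - len(pos_keys)} "
            f"non-positive pairs exist")
    rng = np.random.default_rng(seed)
    if total <= 4_000_000:
        candidates = np.setdiff1d(np.arange(total), np.fromiter(pos_keys, dtype=np.intp),
                                  assume_unique=False)
        keys = rng.choice(candidates, size=want, replace=False)
    else:  # rejection sampling for very large drug x protein grids
        chosen: set[int] = set()
        while len(chosen) < want:
            k = int(rng.integers(total))
            if k not in pos_keys and k not in chosen:
                chosen.add(k)
        keys = np.fromiter(chosen, dtype=np.intp)
    return np.column_stack([keys // n_proteins, keys % n_proteins])
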