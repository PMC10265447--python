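"""Classical masked matrix factorization, used as a linear-limit oracle.

The nonlinear ER model with identity activations, depth-0 entity modules and a
pure bilinear relation module collapses to Y ~ U V; this module solves that
problem directly by alternating ridge regression, providing an independent
reference objective the trainer must match in the linear configuration.

Objective: ||mask o (Y - U V)||_F^2 + lam (||U||_F^2 + ||V||_F^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MFProblem", "MFFactors", "mf_oracle", "mf_objective"]


@dataclass
class MFProblem:
    Y: np.ndarray            # dense n x m matrix
    mask: np.ndarray         # boolean n x m, True = observed
    rank: int
    lam: float = 0.0

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.Y.shape != self.mask.shape:
            raise ValueError("Y and mask shapes differ")
        if self.rank < 1 or self.rank > min(self.Y.shape):
            raise ValueError("rank must be in [1, min(Y.shape)]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not self.mask.any():
            raise ValueError("empty observation mask")


@dataclass
class MFFactors:
    U: np.ndarray            # n x rank
    V: np.ndarray            # rank x m
    objective: float
    objective_path: np.ndarray  # objective after each alternating sweep


def mf_objective(problem: MFProblem, U: np.ndarray, V: np.ndarray) -> float:
    R = (problem.Y - U @ V) * problem.mask
    return float((R * R).sum() + problem.lam * ((U * U).sum() + (V * V).sum()))


def mf_oracle(problem: MFProblem, iters: int = 100, seed: int = 0) -> MFFactors:
    """Alternating least squares on the masked objective.

    Each half-sweep solves an exact ridge problem per row/column, so the
    objective is non-increasing across sweeps.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    n, m = problem.Y.shape
    r = problem.rank
    rng = np.random.default_rng(seed)
    U = rng.normal(0.0, 0.1, size=(n, r))
    V = rng.normal(0.0, 0.1, size=(r, m))
    eye = np.eye(r)
    path = []
    for _ in range(iters):
        for i in range(n):
            obs = problem.mask[i]
            if not obs.any():
                continue
            Vo = V[:, obs]
            A = Vo @ Vo.T + problem.lam * eye
            U[i] = np.linalg.solve(A, Vo @ problem.Y[i, obs])
        for j in range(m):
            obs = problem.mask[:, j]
            if not obs.any():
                continue
            Uo = U[obs]
            A = Uo.T @ Uo + problem.lam * eye
            V[:, j] = np.linalg.solve(A, Uo.T @ problem.Y[obs, j])
        path.append(mf_objective(problem, U, V))
    return MFFactors(U=U, V=V, objective=path[-1], objective_path=np.asarray(path))
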