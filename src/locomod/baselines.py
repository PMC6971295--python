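"""Matrix-decomposition baselines on the task-stacked matrix.

Stacking the K task slices side by side gives Z in R^{S x (T*K)}; PCA
(joint angles) or NNMF (EMG) then factors Z ~= sum_r w_r p_r^T.  Spatial
modules are shared across tasks but the temporal modules absorb all
task-dependent structure, which is what the CP model separates out.  The
stacked model spends (S + T*K) * R parameters against CP's (S + T + K) * R.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cp import CPOptions, _MU_EPS
from .datatypes import DataTensor

__all__ = [
    "StackedMatrix",
    "MatrixModel",
    "stack_tasks",
    "unstack_tensor",
    "unstack_temporal",
    "pca_modules",
    "nnmf_modules",
]


@dataclass
class StackedMatrix:
    """S x (T*K) matrix with task-major column order (task k occupies
    columns [k*T, (k+1)*T))."""

    Z: np.ndarray
    T: int
    K: int
    layout: str = "task_major"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != self.T * self.K:
            raise ValueError(
                f"stacked matrix must have T*K = {self.T * self.K} columns, "
                f"got shape {self.Z.shape}")


@dataclass
class MatrixModel:
    """Rank-R matrix factorization Z ~= spatial @ temporal_stacked.T."""

    spatial: np.ndarray            # S x R
    temporal_stacked: np.ndarray   # (T*K) x R
    method: str                    # 'pca' | 'nnmf'
    vaf: float
    vaf_curve: Optional[np.ndarray] = None
    objective_history: Optional[np.ndarray] = None


def stack_tasks(tensor: DataTensor) -> StackedMatrix:
    """Arrange the K task slices side by side, task-major."""
    S, T, K = tensor.shape
    Z = np.moveaxis(tensor.X, 2, 1).reshape(S, K * T)
    return StackedMatrix(Z=Z, T=T, K=K)


def unstack_tensor(stacked: StackedMatrix) -> np.ndarray:
    """Inverse of :func:`stack_tasks` (lossless round trip)."""
    S = stacked.Z.shape[0]
    return np.moveaxis(stacked.Z.reshape(S, stacked.K, stacked.T), 1, 2)


def unstack_temporal(p_r: np.ndarray, T: int, K: int) -> np.ndarray:
    """Split one stacked temporal module into its K per-task curves (K x T)."""
    p_r = np.asarray(p_r, dtype=float).ravel()
    if p_r.size != T * K:
        raise ValueError(f"temporal module length {p_r.size} != T*K = {T * K}")
    return p_r.reshape(K, T)


def _vaf(Z: np.ndarray, Zhat: np.ndarray) -> float:
    denom = float(np.sum(Z * Z))
    if denom == 0.0:
        return 1.0 if not np.any(Zhat) else 0.0
    return 1.0 - float(np.sum((Z - Zhat) ** 2)) / denom


def pca_modules(stacked: StackedMatrix, R: int) -> MatrixModel:
    """Leading R left singular directions of the (uncentered) stacked matrix.

    Uncentered SVD keeps the variance-accounted-for definition identical to
    the tensor fits (uncentered R^2).  Spatial modules are orthonormal and
    the rank-R reconstruction is the Frobenius-optimal one, so the residual
    equals the sum of discarded squared singular values.
    """
    Z = stacked.Z
    if R < 1 or R > min(Z.shape):
        raise ValueError(f"rank must lie in [1, {min(Z.shape)}]")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    spatial = U[:, :R]
    temporal = (Vt[:R].T * s[:R])
    total = float(np.sum(s ** 2))
    curve = (np.cumsum(s ** 2) / total)[:R] if total > 0 else np.ones(R)
    return MatrixModel(spatial=spatial, temporal_stacked=temporal,
                       method="pca", vaf=float(curve[-1]), vaf_curve=curve)


def nnmf_modules(stacked: StackedMatrix, R: int,
                 opts: Optional[CPOptions] = None) -> MatrixModel:
    """Non-negative matrix factorization by multiplicative updates.

    Same defaults as the non-negative tensor solver: best of ``n_restarts``
    uniform-random initializations, squared-error objective non-increasing
    per sweep, denominators floored.
    """
    Z = stacked.Z
    if Z.min() < 0:
        raise ValueError("NNMF requires a non-negative matrix")
    if R < 1:
        raise ValueError("rank must be >= 1")
    opts = opts or CPOptions()
    S, N = Z.shape
    master = np.random.SeedSequence(opts.seed)
    best = None
    for ss in master.spawn(opts.n_restarts):
        rng = np.random.default_rng(int(ss.generate_state(1)[0] % (2**31)))
        W = rng.random((S, R)) + 0.1
        H = rng.random((R, N)) + 0.1
        prev = np.inf
        history = []
        for _ in range(opts.max_iter):
            W *= (Z @ H.T) / np.maximum(W @ (H @ H.T), _MU_EPS)
            H *= (W.T @ Z) / np.maximum((W.T @ W) @ H, _MU_EPS)
            obj = float(np.sum((Z - W @ H) ** 2))
            history.append(obj)
            if np.isfinite(prev) and prev - obj <= opts.tol * max(prev, 1e-300):
                break
            prev = obj
        if best is None or obj < best[0]:
            best = (obj, W, H, history)
    _, W, H, history = best
    return MatrixModel(spatial=W, temporal_stacked=H.T, method="nnmf",
                       vaf=_vaf(Z, W @ H),
                       objective_history=np.asarray(history))
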