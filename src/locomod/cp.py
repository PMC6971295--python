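"""CP (CANDECOMP/PARAFAC) decomposition of locomotor data tensors.

Two solvers minimise the squared-error objective

    E = 1/2 * sum_{i,j,k} ( X[i,j,k] - sum_r lambda_r w[i,r] p[j,r] t[k,r] )^2

* :func:`cp_als` — alternating least squares, unconstrained factors
  (joint-angle data);
* :func:`cp_nonneg` — multiplicative updates keeping all factors >= 0
  (EMG envelopes).

Both return a :class:`~locomod.datatypes.CPModel` with unit-norm factor
columns (scale absorbed into ``lambda``) and a
:class:`~locomod.datatypes.FitDiagnostics` record.  Model quality is
measured by the uncentered variance accounted for,
``vaf = 1 - ||X - Xhat||^2 / ||X||^2``; :func:`select_rank` applies the
"smallest R whose vaf strictly exceeds the threshold" rule.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import khatri_rao

from .datatypes import CPModel, DataTensor, FitDiagnostics

__all__ = [
    "cp_als",
    "cp_nonneg",
    "normalize_components",
    "reconstruct",
    "fitting_error",
    "variance_explained",
    "select_rank",
    "parameter_counts",
    "CPOptions",
]

_MU_EPS = 1e-12  # multiplicative-update denominator floor


class CPOptions:
    """Solver options with the package defaults.

    max_iter : maximum number of alternating sweeps (default 500)
    tol : relative objective-change stopping tolerance (default 1e-8)
    n_restarts : random restarts; the best final objective is kept (default 10)
    seed : master seed; restart ``i`` uses child seed derived from it
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-8,
                 n_restarts: int = 10, seed: Optional[int] = None) -> None:
        if max_iter < 1 or n_restarts < 1 or tol < 0:
            raise ValueError("invalid solver options")
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.seed = seed


def _as_array(tensor) -> np.ndarray:
    X = tensor.X if isinstance(tensor, DataTensor) else np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a 3-way tensor")
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains NaN or infinite entries")
    return X


def reconstruct(model: CPModel) -> np.ndarray:
    """Evaluate Xhat[i,j,k] = sum_r lambda_r w[i,r] p[j,r] t[k,r]."""
    W = model.spatial * model.weights
    return np.einsum("ir,jr,kr->ijk", W, model.temporal, model.task, optimize=True)


def fitting_error(tensor, model: CPModel) -> float:
    """Relative squared fitting error ||X - Xhat||^2_F / ||X||^2_F."""
    X = _as_array(tensor)
    Xhat = reconstruct(model)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    denom = float(np.sum(X * X))
    resid = float(np.sum((X - Xhat) ** 2))
    if denom == 0.0:
        if resid == 0.0:
            return 0.0
        raise ValueError("fitting error undefined: zero tensor, nonzero model")
    return resid / denom


def variance_explained(tensor, model: CPModel) -> float:
    """Uncentered coefficient of determination, 1 - fitting_error."""
    return 1.0 - fitting_error(tensor, model)


def parameter_counts(S: int, T: int, K: int, R: int) -> dict:
    """Fitting-parameter counts of the three model families.

    CP shares spatial and temporal modules across all K tasks, the stacked
    matrix model shares only the spatial modules, and fully separate per-task
    matrix fits share nothing.
    """
    for v in (S, T, K, R):
        if not (isinstance(v, (int, np.integer)) and v > 0):
            raise ValueError("dimensions must be positive integers")
    return {
        "cp": (S + T + K) * R,
        "stacked_matrix": (S + T * K) * R,
        "separate_matrix": S * T * K * R,
    }


def normalize_components(spatial: np.ndarray, temporal: np.ndarray,
                         task: np.ndarray, weights: Optional[np.ndarray] = None,
                         nonneg: bool = False) -> CPModel:
    """Scale factor columns to unit norm and resolve the sign gauge.

    Column norms (times any incoming ``weights``) are absorbed into lambda;
    components are sorted by lambda descending (zero-lambda components last,
    their columns kept as zeros).  For unconstrained fits the reconstruction
    is invariant under flipping the signs of any two factors of a component;
    the gauge is fixed by flipping (w, p) so each temporal column's
    largest-magnitude entry is positive, then (w, t) so each spatial column's
    largest-magnitude entry is positive.
    """
    spatial = np.array(spatial, dtype=float)
    temporal = np.array(temporal, dtype=float)
    task = np.array(task, dtype=float)
    R = spatial.shape[1]
    lam = np.ones(R) if weights is None else np.asarray(weights, dtype=float).copy()
    flips = np.ones((R, 3))
    for r in range(R):
        for M in (spatial, temporal, task):
            nrm = np.linalg.norm(M[:, r])
            if not np.isfinite(nrm):
                raise ValueError("non-finite factor column norm")
            if nrm == 0.0:
                lam[r] = 0.0
            else:
                M[:, r] /= nrm
                lam[r] *= nrm
        if not nonneg and lam[r] > 0:
            jp = np.argmax(np.abs(temporal[:, r]))
            if temporal[jp, r] < 0:  # flip (w, p): reconstruction unchanged
                spatial[:, r] *= -1
                temporal[:, r] *= -1
                flips[r, 0] *= -1
                flips[r, 1] *= -1
            iw = np.argmax(np.abs(spatial[:, r]))
            if spatial[iw, r] < 0:  # flip (w, t): reconstruction unchanged
                spatial[:, r] *= -1
                task[:, r] *= -1
                flips[r, 0] *= -1
                flips[r, 2] *= -1
    order = np.argsort(-lam, kind="stable")
    return CPModel(weights=lam[order], spatial=spatial[:, order],
                   temporal=temporal[:, order], task=task[:, order],
                   nonneg=nonneg, sign_flips=flips[order])


def _unfoldings(X: np.ndarray):
    S, T, K = X.shape
    return (
        X.reshape(S, T * K),                       # mode-0: columns (j,k)
        np.moveaxis(X, 1, 0).reshape(T, S * K),    # mode-1: columns (i,k)
        np.moveaxis(X, 2, 0).reshape(K, S * T),    # mode-2: columns (i,j)
    )


def _model_norm_sq(factors) -> float:
    # ||Xhat||^2 from the factor Gram matrices: sum_{r,s} prod_n (A_n^T A_n)[r,s]
    G = np.ones((factors[0].shape[1],) * 2)
    for A in factors:
        G *= A.T @ A
    return float(np.sum(G))


def _objective(norm_x_sq: float, factors, mttkrp_last: np.ndarray) -> float:
    # E = 1/2(||X||^2 - 2<X, Xhat> + ||Xhat||^2); <X, Xhat> reuses the last
    # MTTKRP so no full reconstruction is formed inside the sweep loop.
    inner = float(np.sum(factors[2] * mttkrp_last))
    return 0.5 * max(norm_x_sq - 2.0 * inner + _model_norm_sq(factors), 0.0)


def _init_factors(rng: np.random.Generator, shape, R: int, nonneg: bool):
    if nonneg:
        return [rng.random((n, R)) + 0.1 for n in shape]
    return [rng.standard_normal((n, R)) for n in shape]


def _als_sweeps(X, unf, factors, opts: CPOptions, norm_x_sq: float):
    history = []
    prev = np.inf
    converged = False
    n_iter = 0
    for it in range(opts.max_iter):
        before = [A.copy() for A in factors]
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            mttkrp = unf[mode] @ kr
            try:
                sol = np.linalg.solve(gram, mttkrp.T).T
            except np.linalg.LinAlgError:
                warnings.warn("rank-deficient ALS system; using ridge-regularized solve")
                R = gram.shape[0]
                sol = np.linalg.solve(gram + 1e-10 * np.trace(gram) * np.eye(R),
                                      mttkrp.T).T
            if mode < 2:
                # keep blocks well conditioned; the next exact solve
                # re-absorbs the scale, so per-sweep monotonicity holds
                sol = sol / np.maximum(np.linalg.norm(sol, axis=0), 1e-300)
            factors[mode] = sol
        obj = _objective(norm_x_sq, factors, mttkrp)
        if it >= 3:
            # line-search extrapolation along the sweep direction, doubling
            # the step while the objective keeps dropping; accepted only when
            # it lowers the objective, so per-sweep monotonicity holds.
            # Plain ALS crawls through rank-deficient "swamps" (and through
            # degenerate instances whose best approximation is an infimum
            # with diverging components); this is the standard cure.
            step = 2.0
            for _ in range(30):
                cand = [b + step * (a - b) for a, b in zip(factors, before)]
                kr_c = khatri_rao(cand[0], cand[1])
                obj_c = _objective(norm_x_sq, cand, unf[2] @ kr_c)
                if obj_c >= obj:
                    break
                factors, obj = cand, obj_c
                step *= 2.0
        history.append(obj)
        n_iter = it + 1
        if np.isfinite(prev) and prev - obj <= opts.tol * max(prev, 1e-300):
            converged = True
            break
        prev = obj
    return factors, history, n_iter, converged


def _mu_sweeps(X, unf, factors, opts: CPOptions, norm_x_sq: float):
    history = []
    prev = np.inf
    converged = False
    n_iter = 0
    for it in range(opts.max_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            mttkrp = unf[mode] @ kr
            denom = factors[mode] @ gram
            factors[mode] = factors[mode] * mttkrp / np.maximum(denom, _MU_EPS)
        obj = _objective(norm_x_sq, factors, mttkrp)
        history.append(obj)
        n_iter = it + 1
        if np.isfinite(prev) and prev - obj <= opts.tol * max(prev, 1e-300):
            converged = True
            break
        prev = obj
    return factors, history, n_iter, converged


def _fit(tensor, R: int, opts: CPOptions, nonneg: bool):
    X = _as_array(tensor)
    if R < 1:
        raise ValueError("rank must be >= 1")
    if nonneg and X.min() < 0:
        raise ValueError("non-negative CP requires a non-negative tensor")
    norm_x_sq = float(np.sum(X * X))
    S, T, K = X.shape

    if norm_x_sq == 0.0:
        model = CPModel(weights=np.zeros(R), spatial=np.zeros((S, R)),
                        temporal=np.zeros((T, R)), task=np.zeros((K, R)),
                        nonneg=nonneg)
        diag = FitDiagnostics(objective=0.0, rel_fitting_error=0.0, vaf=1.0,
                              n_iter=0, converged=True,
                              n_restarts=opts.n_restarts, best_restart_seed=-1)
        return model, diag

    unf = _unfoldings(X)
    sweeps = _mu_sweeps if nonneg else _als_sweeps
    master = np.random.SeedSequence(opts.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   master.spawn(opts.n_restarts)]

    best = None
    for seed in child_seeds:
        rng = np.random.default_rng(seed)
        factors = _init_factors(rng, (S, T, K), R, nonneg)
        factors, history, n_iter, converged = sweeps(X, unf, factors, opts, norm_x_sq)
        if best is None or history[-1] < best[1][-1]:
            best = (factors, history, n_iter, converged, seed)

    factors, history, n_iter, converged, seed = best
    model = normalize_components(*factors, nonneg=nonneg)
    err = fitting_error(X, model)
    diag = FitDiagnostics(objective=history[-1], rel_fitting_error=err,
                          vaf=1.0 - err, n_iter=n_iter, converged=converged,
                          n_restarts=opts.n_restarts, best_restart_seed=seed,
                          objective_history=np.asarray(history))
    return model, diag


def cp_als(tensor, R: int, opts: Optional[CPOptions] = None):
    """Unconstrained CP fit by alternating least squares.

    Each sweep solves the three exact block least-squares problems via the
    matricized-tensor-times-Khatri-Rao system, so the objective is
    non-increasing per sweep.  Best of ``opts.n_restarts`` random restarts.
    """
    return _fit(tensor, R, opts or CPOptions(), nonneg=False)


def cp_nonneg(tensor, R: int, opts: Optional[CPOptions] = None):
    """Non-negative CP fit by multiplicative updates.

    The Lee-Seung style update ``A <- A * (X_(n) KR) / (A G)`` keeps all
    factors non-negative and does not increase the squared-error objective.
    Denominators are floored at 1e-12.
    """
    return _fit(tensor, R, opts or CPOptions(), nonneg=True)


def select_rank(tensor, threshold: float = 0.7, R_max: int = 10,
                solver: str = "als", opts: Optional[CPOptions] = None,
                early_stop: bool = False):
    """Smallest R whose variance accounted for strictly exceeds ``threshold``.

    Fits R = 1..R_max (or stops at the first success when ``early_stop``)
    and returns ``(R_star, curve)`` where ``curve`` maps ``"vaf"`` and
    ``"fitting_error"`` to the per-rank arrays.  A vaf exactly equal to the
    threshold does not qualify.

    Raises ``ValueError`` reporting the best vaf reached if no rank up to
    ``R_max`` exceeds the threshold.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    if R_max < 1:
        raise ValueError("R_max must be >= 1")
    fit = {"als": cp_als, "nonneg": cp_nonneg}[solver]
    base = opts or CPOptions()
    master = np.random.SeedSequence(base.seed)
    rank_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(R_max)]
    vafs, errs, models = [], [], []
    R_star = None
    for R in range(1, R_max + 1):
        o = CPOptions(max_iter=base.max_iter, tol=base.tol,
                      n_restarts=base.n_restarts, seed=rank_seeds[R - 1])
        model, diag = fit(tensor, R, o)
        vafs.append(diag.vaf)
        errs.append(diag.rel_fitting_error)
        models.append(model)
        if R_star is None and diag.vaf > threshold:
            R_star = R
            if early_stop:
                break
    if R_star is None:
        raise ValueError(
            f"no rank up to {R_max} exceeds vaf threshold {threshold}; "
            f"best vaf = {max(vafs):.4f}")
    curve = {"vaf": np.asarray(vafs), "fitting_error": np.asarray(errs),
             "models": models}
    return R_star, curve
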