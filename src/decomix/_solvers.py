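"""Constrained least-squares primitives shared by the deconvolution engines.

Two shapes of problem recur:

* many right-hand sides sharing one small design matrix, each solution
  constrained to the probability simplex (proportion columns) — solved
  exactly by an active-set method on the K-variable QP;
* many rows sharing one small Gram matrix, each solution box-constrained
  (profile rows, bounds ``[0, inf)`` or ``[0, 1]``) — solved by vectorized
  cyclic coordinate descent, which minimizes each coordinate exactly and
  therefore never increases the residual sum of squares.
"""
from __future__ import annotations

import numpy as np

__all__ = ["simplex_lstsq_cols", "bounded_lstsq_rows"]


def _simplex_qp(G: np.ndarray, b: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Minimize ``1/2 a'Ga - b'a`` subject to ``a >= 0`` and ``sum(a) = 1``.

    Active-set on the non-negativity constraints; the sum-to-one equality is
    kept in the KKT system. Exact for positive semi-definite G (a tiny ridge
    guards rank-deficient free sets). The dual feasibility threshold is
    looser than the primal drop threshold so the iteration cannot cycle on a
    variable whose optimum sits at zero.
    """
    K = b.shape[0]
    if K == 1:
        return np.ones(1)
    scale = 1.0 + float(np.abs(b).max()) + float(np.abs(G).max())
    ridge = 1e-12 * scale
    dual_tol = 1e-8 * scale
    free = np.ones(K, dtype=bool)
    a = np.full(K, 1.0 / K)
    for _ in range(4 * K + 12):
        idx = np.flatnonzero(free)
        k = idx.size
        M = np.zeros((k + 1, k + 1))
        M[:k, :k] = G[np.ix_(idx, idx)]
        M[:k, :k].flat[:: k + 1] += ridge
        M[:k, k] = 1.0
        M[k, :k] = 1.0
        rhs = np.concatenate([b[idx], [1.0]])
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        a_f, lam = sol[:k], sol[k]
        if k > 1 and a_f.min() < -tol:
            free[idx[int(np.argmin(a_f))]] = False
            continue
        a = np.zeros(K)
        a[idx] = np.maximum(a_f, 0.0)
        bound = np.flatnonzero(~free)
        if bound.size:
            mu = G[bound] @ a - b[bound] - lam
            j = int(np.argmin(mu))
            if mu[j] < -dual_tol:
                free[bound[j]] = True
                continue
        return a
    return a  # iteration cap (numerically degenerate input): best iterate


def simplex_lstsq_cols(design: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Columnwise simplex-constrained least squares.

    Solves ``min ||design @ C - targets||_F`` with every column of ``C``
    non-negative and summing to one. ``design`` is (m, K), ``targets`` is
    (m, P); returns (K, P).
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    G = design.T @ design
    B = design.T @ targets
    K, P = G.shape[0], targets.shape[1]
    if K == 1:
        return np.ones((1, P))
    # batched all-free KKT solve first; fall back per column on violations
    M = np.zeros((K + 1, K + 1))
    M[:K, :K] = G + 1e-12 * np.eye(K)
    M[:K, K] = 1.0
    M[K, :K] = 1.0
    rhs = np.vstack([B, np.ones((1, P))])
    try:
        sol = np.linalg.solve(M, rhs)
        cand = sol[:K]
        ok = cand.min(axis=0) >= -1e-12
    except np.linalg.LinAlgError:
        cand = np.zeros((K, P))
        ok = np.zeros(P, dtype=bool)
    out = np.empty((K, P))
    out[:, ok] = np.clip(cand[:, ok], 0.0, None)
    out[:, ok] /= out[:, ok].sum(axis=0, keepdims=True)
    for j in np.flatnonzero(~ok):
        out[:, j] = _simplex_qp(G, B[:, j])
    return out


def bounded_lstsq_rows(
    X: np.ndarray,
    A: np.ndarray,
    lower: float = 0.0,
    upper: float = np.inf,
    T0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 500,
) -> np.ndarray:
    """Rowwise box-constrained least squares ``min ||X - T A||_F``.

    ``X`` is (F, S), ``A`` is (K, S); every entry of the returned ``T``
    (F, K) lies in ``[lower, upper]``. All rows share the Gram matrix
    ``A A'`` and are updated together by cyclic coordinate descent; warm
    starts via ``T0`` make repeated calls inside alternating solvers cheap.
    Each coordinate update is an exact 1-D minimization, so the objective is
    non-increasing sweep over sweep.
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    F, K = X.shape[0], A.shape[0]
    G = A @ A.T
    B = X @ A.T
    if T0 is not None:
        T = np.clip(np.asarray(T0, dtype=float).copy(), lower, upper)
    else:
        T = np.zeros((F, K))
    diag = np.diag(G).copy()
    scale = max(1.0, np.abs(B).max() / max(diag.max(), 1e-300))
    for _ in range(max_sweeps):
        delta = 0.0
        for k in range(K):
            if diag[k] <= 1e-300:
                continue
            r = B[:, k] - T @ G[:, k] + T[:, k] * diag[k]
            new = np.clip(r / diag[k], lower, upper)
            d = np.abs(new - T[:, k]).max() if F else 0.0
            if d > delta:
                delta = d
            T[:, k] = new
        if delta <= tol * scale:
            break
    return T
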