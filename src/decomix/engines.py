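"""Reference-free deconvolution engines.

Every engine factorizes a bulk matrix ``X`` (features × samples) into
cell-type profiles ``T`` (features × K) and proportions ``A`` (K × samples)
with simplex columns, given only the number of components K:

* :func:`nmf_deconvolve` — alternating constrained least squares with
  non-negative profiles and simplex proportions, followed by the
  pseudoinverse re-estimation of T with negative entries clamped to zero;
* :func:`edec_deconvolve` — alternating constrained least squares for
  beta-value matrices, profiles box-constrained to ``[0, 1]``, multiple
  seeded restarts, minimizing the Euclidean reconstruction distance;
* :func:`ica_deconvolve` — FastICA source separation over features, with
  sign reorientation, marker selection and weighted-mean abundance scores
  renormalized to proportions;
* :func:`cam_lite_deconvolve` — a simplified convex-geometry vertex search:
  k-means in the row-normalized (simplex) space followed by an exhaustive
  corner-subset search.

:func:`match_components` aligns an estimate with a ground-truth proportion
matrix via the Hungarian algorithm, for evaluation.
"""
from __future__ import annotations

import itertools
import warnings
from typing import NamedTuple

import numpy as np

from ._solvers import bounded_lstsq_rows, simplex_lstsq_cols
from .data import OmicsMatrix
from .results import DeconvolutionResults

__all__ = [
    "nmf_deconvolve",
    "edec_deconvolve",
    "ica_deconvolve",
    "cam_lite_deconvolve",
    "reorient_components",
    "match_components",
    "ComponentMatch",
]


def _rss(X: np.ndarray, T: np.ndarray, A: np.ndarray) -> float:
    R = X - T @ A
    return float(np.einsum("ij,ij->", R, R))


def _t_upper(m: OmicsMatrix) -> float:
    # profiles of a beta-value matrix are themselves beta-values
    return 1.0 if m.modality == "methylation" else np.inf


def _result(m, A, T, k, engine, seed, rss_trace, n_iter, converged, diagnostics):
    return DeconvolutionResults(
        A=A,
        T=T,
        k=k,
        engine=engine,
        seed=seed,
        modality=m.modality,
        feature_ids=list(m.feature_ids),
        sample_ids=list(m.sample_ids),
        rss_trace=rss_trace,
        n_iterations=n_iter,
        converged=converged,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------
def nmf_deconvolve(
    m: OmicsMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DeconvolutionResults:
    """Non-negative matrix factorization with simplex proportions.

    Stage 1 alternates exact constrained least-squares updates — profiles
    ``T >= 0`` given ``A``, then each proportion column of ``A`` on the
    simplex given ``T`` (the sum-to-one constraint is enforced inside the
    update, so the final renormalization by column sums is an exact no-op
    and the recorded RSS trace is non-increasing). Iteration stops when the
    relative RSS change drops below ``tol`` or after ``max_iter`` rounds.

    Stage 2 re-estimates ``T = X A^+`` through the Moore–Penrose
    pseudoinverse of the proportion matrix and clamps negative entries of
    ``T`` to zero (and to one from above for beta-value input).
    """
    X = m.values
    F, S = X.shape
    if not (0 < k < min(F, S)):
        raise ValueError(
            f"K={k} must satisfy 0 < K < min(features, samples)={min(F, S)}"
        )
    if X.min() < 0:
        raise ValueError("nmf_deconvolve requires non-negative values")
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(k), size=S).T
    T = None
    rss_trace: list[float] = []
    converged = False
    upper = _t_upper(m)
    for it in range(max_iter):
        T = bounded_lstsq_rows(X, A, 0.0, upper, T0=T)
        A = simplex_lstsq_cols(T, X)
        A = A / A.sum(axis=0, keepdims=True)  # exact renormalization (sums ≈ 1)
        rss = _rss(X, T, A)
        rss_trace.append(rss)
        if it > 0 and abs(rss_trace[-2] - rss) <= tol * max(rss_trace[-2], 1e-300):
            converged = True
            break
    diagnostics: dict = {}
    rank = int(np.linalg.matrix_rank(A))
    if rank < k:
        diagnostics["degenerate_A"] = (
            f"A has rank {rank} < K={k} at convergence; "
            "pseudoinverse still defined"
        )
        warnings.warn(diagnostics["degenerate_A"], RuntimeWarning, stacklevel=2)
    T = X @ np.linalg.pinv(A)
    np.clip(T, 0.0, upper, out=T)
    diagnostics["post_rss"] = _rss(X, T, A)
    return _result(
        m, A, T, k, "nmf", seed, rss_trace, len(rss_trace), converged, diagnostics
    )


# ---------------------------------------------------------------------------
# EDec-style constrained factorization for beta-values
# ---------------------------------------------------------------------------
def edec_deconvolve(
    m: OmicsMatrix,
    k: int,
    seed: int = 0,
    max_its: int = 2000,
    rss_diff_stop: float = 1e-10,
    n_restarts: int = 5,
) -> DeconvolutionResults:
    """Constrained factorization of a beta-value matrix.

    Alternates exact block updates minimizing the squared Euclidean
    reconstruction distance: each feature row of ``T`` by least squares
    box-constrained to ``[0, 1]``, then each sample column of ``A`` by
    simplex-constrained least squares. A restart stops when the absolute
    RSS change falls below ``rss_diff_stop`` (default ``1e-10``) or after
    ``max_its`` iterations (default 2000); the best of ``n_restarts``
    seeded random initializations is returned.
    """
    if m.modality != "methylation":
        raise ValueError("edec_deconvolve requires modality='methylation'")
    X = m.values
    F, S = X.shape
    if not (0 < k < S):
        raise ValueError(f"K={k} must satisfy 0 < K < samples={S}")
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        A = rng.dirichlet(np.ones(k), size=S).T
        T = None
        trace: list[float] = []
        converged = False
        for it in range(max_its):
            T = bounded_lstsq_rows(X, A, 0.0, 1.0, T0=T)
            A = simplex_lstsq_cols(T, X)
            A = A / A.sum(axis=0, keepdims=True)
            rss = _rss(X, T, A)
            trace.append(rss)
            if it > 0 and abs(trace[-2] - rss) < rss_diff_stop:
                converged = True
                break
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], A, T, trace, converged, restart)
    final_rss, A, T, trace, converged, which = best
    diagnostics = {"best_restart": which, "n_restarts": n_restarts}
    return _result(
        m, A, T, k, "edec", seed, trace, len(trace), converged, diagnostics
    )


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------
def reorient_components(weights: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Fix the sign indeterminacy of component weight vectors.

    For each column the entry with the largest absolute value (ties broken
    by the smallest row index) is made positive: if it is negative the whole
    column is multiplied by −1. Returns the reoriented matrix and the
    per-component sign applied. Idempotent.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2:
        raise ValueError("weights must be a 2-D matrix")
    flips: list[int] = []
    out = W.copy()
    for j in range(W.shape[1]):
        col = W[:, j]
        top = int(np.argmax(np.abs(col)))  # argmax takes the first on ties
        if col[top] == 0:
            raise ValueError(f"component {j + 1} has an all-zero weight column")
        sign = -1 if col[top] < 0 else 1
        flips.append(sign)
        out[:, j] = sign * col
    return out, flips


def _weighted_mean_scores(
    W: np.ndarray, X: np.ndarray, n_markers: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-sample component scores from marker-weighted means.

    For each component the ``n_markers`` features with the largest positive
    weight are markers; the score of sample ``j`` is
    ``sum_g w_g X_gj / sum_g w_g`` over the markers. With equal weights this
    reduces to the arithmetic mean of the marker rows.
    """
    F, k = W.shape
    scores = np.empty((k, X.shape[1]))
    marker_idx: list[np.ndarray] = []
    for j in range(k):
        w = W[:, j]
        order = np.argsort(-w, kind="stable")
        top = order[: min(n_markers, F)]
        top = top[w[top] > 0]
        if top.size == 0:
            raise ValueError(
                f"component {j + 1} has no positively weighted feature"
            )
        ww = w[top]
        scores[j] = ww @ X[top, :] / ww.sum()
        marker_idx.append(top)
    return scores, marker_idx


def ica_deconvolve(
    m: OmicsMatrix,
    k: int,
    seed: int = 0,
    n_markers: int = 30,
    renormalize: bool = True,
) -> DeconvolutionResults:
    """Independent-component deconvolution with marker-based scoring.

    Rows (features) are centered and FastICA extracts ``k`` statistically
    independent source components over features. Each component is
    reoriented so its largest-magnitude weight is positive, its
    ``n_markers`` largest positively weighted features become markers, and a
    per-sample abundance score is the weighted mean of the marker rows of
    the original matrix (weights = marker weights). With
    ``renormalize=True`` (default) the score columns are divided by their
    sums to yield simplex proportions; negative scores (possible on general
    input) are clamped to zero first and counted in the diagnostics.

    ``T`` holds each component's weight vector with negative weights set to
    zero (clipped to ``[0, 1]`` for beta-value input).
    """
    from sklearn.decomposition import FastICA

    X = m.values
    F, S = X.shape
    if S < k:
        raise ValueError(f"need at least K={k} samples, got {S}")
    Xc = X - X.mean(axis=1, keepdims=True)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ica = FastICA(
            n_components=k,
            random_state=seed,
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-5,
        )
        sources = ica.fit_transform(Xc)  # (F, k) gene weights
    W, flips = reorient_components(sources)
    scores, marker_idx = _weighted_mean_scores(W, X, n_markers)
    markers = {
        f"C{j + 1}": [m.feature_ids[i] for i in idx]
        for j, idx in enumerate(marker_idx)
    }
    diagnostics: dict = {
        "sign_flips": flips,
        "markers": markers,
        "ica_warnings": [str(c.message) for c in caught],
    }
    if renormalize:
        n_neg = int((scores < 0).sum())
        if n_neg:
            diagnostics["negative_scores_clamped"] = n_neg
            scores = np.clip(scores, 0.0, None)
        colsums = scores.sum(axis=0)
        bad = np.flatnonzero(colsums <= 0)
        if bad.size:
            raise ValueError(
                f"sample {m.sample_ids[bad[0]]!r} has non-positive total "
                "component score; cannot form proportions"
            )
        A = scores / colsums
    else:
        A = scores
    T = np.clip(W, 0.0, _t_upper(m))
    rss_trace = [_rss(X, T, A)]
    return _result(m, A, T, k, "ica", seed, rss_trace, 1, True, diagnostics)


# ---------------------------------------------------------------------------
# Simplified convex-geometry vertex search
# ---------------------------------------------------------------------------
def cam_lite_deconvolve(
    m: OmicsMatrix,
    k: int,
    seed: int = 0,
    cluster_factor: int = 5,
) -> DeconvolutionResults:
    """Simplified convex-analysis-of-mixtures vertex search.

    Feature rows are scaled to sum one, placing each feature in the simplex
    of sample composition; rows proportional to a single component's
    proportions sit at the corners of the mixture's convex hull. The scaled
    rows are summarized by k-means into ``cluster_factor * k`` centers
    (default factor 5) and every K-subset of centers is scored by the total
    squared residual of the remaining centers under their best convex
    combination of the subset; the minimizing subset gives the corners. ``A``
    is the corner rows renormalized per sample column, and ``T`` follows by
    non-negative least squares per feature.

    Exhaustive subset scoring bounds K at 6 and ``K * cluster_factor`` at 60.
    """
    from sklearn.cluster import KMeans

    X = m.values
    F, S = X.shape
    if X.min() < 0:
        raise ValueError("cam_lite_deconvolve requires non-negative values")
    if k > 6:
        raise ValueError("cam_lite supports K <= 6 (exhaustive subset search)")
    n_clusters = cluster_factor * k
    if n_clusters > 60:
        raise ValueError("K * cluster_factor must be <= 60")
    rowsums = X.sum(axis=1)
    keep = np.flatnonzero(rowsums > 0)
    if n_clusters > keep.size:
        raise ValueError(
            f"{n_clusters} clusters requested but only {keep.size} usable features"
        )
    R = X[keep] / rowsums[keep, None]
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    km.fit(R)
    centers = km.cluster_centers_  # (C, S), rows ~ on the simplex
    indices = range(n_clusters)
    best_subset, best_score = None, np.inf
    for subset in itertools.combinations(indices, k):
        rest = [i for i in indices if i not in subset]
        B = centers[list(subset)]  # (k, S)
        if rest:
            C = simplex_lstsq_cols(B.T, centers[rest].T)  # (k, n_rest)
            resid = centers[rest].T - B.T @ C
            score = float(np.einsum("ij,ij->", resid, resid))
        else:
            score = 0.0
        if score < best_score:
            best_score, best_subset = score, subset
    corners = centers[list(best_subset)]  # (k, S)
    # corner rows estimate the proportion rows only up to a positive row
    # scale (each was normalized to sum one over samples); the column
    # sum-to-one constraint pins the scales: solve min ||C'd - 1|| with
    # d >= 0, then project columns onto the simplex.
    from scipy.optimize import nnls as _nnls

    d, _ = _nnls(corners.T, np.ones(S))
    scaled = np.clip(d, 1e-12, None)[:, None] * corners
    colsums = scaled.sum(axis=0)
    bad = np.flatnonzero(colsums <= 0)
    if bad.size:
        raise ValueError(
            f"sample {m.sample_ids[bad[0]]!r} has zero total corner weight"
        )
    A = np.clip(scaled, 0.0, None) / colsums
    T = bounded_lstsq_rows(X, A, 0.0, _t_upper(m))
    diagnostics = {
        "n_clusters": n_clusters,
        "subset_score": best_score,
        "chosen_clusters": list(best_subset),
    }
    rss_trace = [_rss(X, T, A)]
    return _result(m, A, T, k, "cam_lite", seed, rss_trace, 1, True, diagnostics)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------
class ComponentMatch(NamedTuple):
    """Hungarian matching of estimated components to ground truth."""

    permutation: np.ndarray  # permutation[i] = estimated row matched to truth row i
    correlations: np.ndarray  # Pearson r per truth component, after matching
    mae: float  # mean absolute proportion error after matching


def _row_correlations(E: np.ndarray, G: np.ndarray) -> np.ndarray:
    """corr[i, j] = Pearson r(E[i], G[j]); zero-variance rows give 0."""
    Ec = E - E.mean(axis=1, keepdims=True)
    Gc = G - G.mean(axis=1, keepdims=True)
    En = np.linalg.norm(Ec, axis=1)
    Gn = np.linalg.norm(Gc, axis=1)
    denom = np.outer(En, Gn)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, Ec @ Gc.T / denom, 0.0)
    return corr


def match_components(estimated, truth_A: np.ndarray) -> ComponentMatch:
    """Optimally pair estimated with true components.

    ``estimated`` may be a :class:`DeconvolutionResults` or a bare
    K × samples array. The one-to-one assignment maximizes the summed
    Pearson correlation between proportion rows (Hungarian algorithm);
    reported are the permutation, the per-component correlation and the
    mean absolute error of the permuted proportions.
    """
    from scipy.optimize import linear_sum_assignment

    E = np.asarray(getattr(estimated, "A", estimated), dtype=float)
    G = np.asarray(truth_A, dtype=float)
    if E.shape != G.shape:
        raise ValueError(
            f"shape mismatch: estimated {E.shape} vs truth {G.shape}"
        )
    corr = _row_correlations(E, G)
    rows, cols = linear_sum_assignment(-corr)  # rows = estimated, cols = truth
    perm = np.empty(G.shape[0], dtype=int)
    perm[cols] = rows
    matched = E[perm]
    return ComponentMatch(
        permutation=perm,
        correlations=corr[perm, np.arange(G.shape[0])],
        mae=float(np.mean(np.abs(matched - G))),
    )
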