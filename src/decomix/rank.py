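"""Guidance for choosing the number of components K from PCA eigenvalues.

Reference-free deconvolution needs the number of latent components K as an
input. :func:`scree` computes the eigenvalues of the sample covariance
(features as variables) and applies an automatic elbow rule in the spirit of
Cattell's scree criterion; the eigenvalue table is the primary output and the
suggested K is advisory.

A geometric fact matters here: when the data are a mixture ``X = T A`` with
proportion columns of ``A`` on the simplex, the samples live on an affine
subspace of dimension ``K - 1`` — the feature-centered matrix has rank
``K - 1`` because the centered proportion rows sum to zero. The number of
mixture components is therefore the centered-spectrum elbow **plus one**
(the endmember-counting rule of convex mixture analysis); the uncentered
spectrum has rank ``K`` but its first eigenvalue is dominated by the grand
mean, which masks the component gap. ``scree(..., simplex_mixture=True)``
applies the plus-one rule and is what the deconvolution pipeline uses; the
default reports the plain spectrum elbow.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import OmicsMatrix

__all__ = ["ScreeResult", "scree"]


@dataclass
class ScreeResult:
    """Eigenvalue scree with an automatic elbow suggestion.

    Attributes
    ----------
    eigenvalues : ndarray
        Non-increasing, non-negative eigenvalues of the (optionally
        centered/scaled) feature covariance.
    explained_variance_fraction : ndarray
        ``eigenvalues / eigenvalues.sum()``; sums to 1 over the returned
        components.
    suggested_k : int
        Elbow position (see :func:`scree`); advisory.
    """

    eigenvalues: np.ndarray
    explained_variance_fraction: np.ndarray
    suggested_k: int
    centered: bool
    scaled: bool

    def plot(self, ax=None):
        """Draw the scree plot; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(1, len(self.eigenvalues) + 1)
        ax.plot(k, self.eigenvalues, "o-")
        ax.axvline(self.suggested_k, color="grey", ls="--", lw=1)
        ax.set_xlabel("component")
        ax.set_ylabel("eigenvalue")
        ax.set_title(f"scree (suggested K = {self.suggested_k})")
        return ax


def _elbow(lam: np.ndarray, max_k: int) -> int:
    kmax = max(min(max_k, len(lam) - 1), 1)
    drops = lam[:kmax] - lam[1 : kmax + 1]
    denom = lam[1 : kmax + 1] - lam[-1] + 1e-12
    return int(np.argmax(drops / denom)) + 1


def scree(
    m: OmicsMatrix,
    center: bool = True,
    scale: bool = False,
    max_k: int = 10,
    simplex_mixture: bool = False,
) -> ScreeResult:
    """PCA eigenvalue scree with an automatic elbow suggestion.

    Features are the variables and samples the observations; with
    ``center=True`` the eigenvalues are those of the feature covariance
    matrix (computed via SVD, denominator ``n_samples - 1``), with
    ``scale=True`` each feature is additionally divided by its standard
    deviation. The elbow is the ``k`` maximizing the eigenvalue drop
    relative to the remaining scree,

    ``(lam_k - lam_{k+1}) / (lam_{k+1} - lam_min + 1e-12)``,

    searched over ``k in [1, min(max_k, n_eigenvalues - 1)]``.

    With ``simplex_mixture=True`` the suggestion targets the number of
    mixture components of proportion-constrained data: the elbow is located
    on the *centered* spectrum (the mixture's affine dimension) and one is
    added, since K components span a (K-1)-dimensional affine subspace.
    The reported eigenvalues still follow ``center``/``scale``.
    """
    if m.n_samples < 2 or m.n_features < 2:
        raise ValueError("scree requires at least 2 features and 2 samples")
    X = m.values.astype(float)
    if np.ptp(X) == 0:
        raise ValueError("constant matrix: no variance to decompose")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    if scale:
        sd = X.std(axis=1, ddof=1)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"feature {m.feature_ids[bad]!r} has zero variance; "
                "cannot scale"
            )
        X = X / sd[:, None]
    sv = np.linalg.svd(X, compute_uv=False)
    lam = sv**2 / (m.n_samples - 1)
    total = lam.sum()
    if total <= 0:
        raise ValueError("constant matrix: no variance to decompose")
    frac = lam / total

    if simplex_mixture:
        Xc = m.values - m.values.mean(axis=1, keepdims=True)
        svc = np.linalg.svd(Xc, compute_uv=False)
        lam_c = svc**2 / (m.n_samples - 1)
        suggested = min(_elbow(lam_c, max_k) + 1, len(lam))
    else:
        suggested = _elbow(lam, max_k)
    return ScreeResult(
        eigenvalues=lam,
        explained_variance_fraction=frac,
        suggested_k=suggested,
        centered=center,
        scaled=scale,
    )
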