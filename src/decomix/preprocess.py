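"""Normalization, transformation and feature selection for expression data.

Three preprocessing stages are offered, mirroring common bulk RNA-seq
practice before reference-free deconvolution:

* library-size normalization — reads-per-million (:func:`normalize_rpm`) or
  median-of-ratios size factors (:func:`normalize_median_of_ratios`);
* variance-stabilizing transformation — ``log2(x + 1)`` or a signed
  pseudo-log (:func:`transform`);
* unsupervised feature selection by coefficient of variation
  (:func:`select_features_by_cv`).
"""
from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data import OmicsMatrix

logger = logging.getLogger("decomix")

__all__ = [
    "normalize_rpm",
    "normalize_median_of_ratios",
    "MedianOfRatiosResult",
    "transform",
    "select_features_by_cv",
]


def _require_expression(m: OmicsMatrix, op: str) -> None:
    if m.modality != "expression":
        raise ValueError(f"{op} requires modality='expression', got {m.modality!r}")


def normalize_rpm(m: OmicsMatrix) -> OmicsMatrix:
    """Scale every sample column so its total equals one million.

    Raises if any sample column sums to zero (its scaling is undefined).
    """
    _require_expression(m, "normalize_rpm")
    if m.values.min() < 0:
        raise ValueError("normalize_rpm requires non-negative values")
    colsums = m.values.sum(axis=0)
    zero = np.flatnonzero(colsums <= 0)
    if zero.size:
        raise ValueError(
            f"sample {m.sample_ids[zero[0]]!r} has zero total signal; "
            "cannot normalize"
        )
    return m.with_values(m.values * (1e6 / colsums))


class MedianOfRatiosResult(NamedTuple):
    matrix: OmicsMatrix
    size_factors: pd.Series


def normalize_median_of_ratios(m: OmicsMatrix) -> MedianOfRatiosResult:
    """Median-of-ratios library-size normalization.

    The reference profile is the per-feature geometric mean across samples,
    computed over features with strictly positive counts in every sample;
    each sample's size factor is the median of its ratios to the reference,
    and its column is divided by that factor.

    Returns
    -------
    MedianOfRatiosResult
        ``matrix`` — the normalized matrix; ``size_factors`` — per-sample
        factors (a Series indexed by sample id).
    """
    _require_expression(m, "normalize_median_of_ratios")
    X = m.values
    if X.min() < 0:
        raise ValueError("counts must be non-negative")
    all_positive = np.all(X > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has strictly positive counts in every sample; "
            "median-of-ratios size factors are undefined"
        )
    ref = np.exp(np.mean(np.log(X[all_positive]), axis=1))  # geometric mean
    ratios = X[all_positive] / ref[:, None]
    factors = np.median(ratios, axis=0)
    out = m.with_values(X / factors)
    return MedianOfRatiosResult(
        matrix=out,
        size_factors=pd.Series(factors, index=list(m.sample_ids), name="size_factor"),
    )


def transform(m: OmicsMatrix, kind: str = "log2", sigma: float = 1.0) -> OmicsMatrix:
    """Apply a monotone variance-stabilizing transform entrywise.

    ``log2`` maps ``x -> log2(x + 1)`` (the pseudocount keeps zero counts
    defined). ``pseudoLog`` maps ``x -> asinh(x / (2 * sigma)) / ln(2)``,
    which is 0 at 0 and asymptotically equal to ``log2(x)`` for large ``x``.
    """
    _require_expression(m, "transform")
    if m.values.min() < 0:
        raise ValueError("transform requires non-negative values")
    key = kind.lower()
    if key == "log2":
        out = np.log2(m.values + 1.0)
    elif key == "pseudolog":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        out = np.arcsinh(m.values / (2.0 * sigma)) / np.log(2.0)
    else:
        raise ValueError(f"unknown transform kind {kind!r} (log2 or pseudoLog)")
    return m.with_values(out)


def select_features_by_cv(m: OmicsMatrix, n_top: int) -> OmicsMatrix:
    """Keep the ``n_top`` features with the largest coefficient of variation.

    CV is the per-feature sample standard deviation divided by the mean,
    computed across samples. Features with zero mean have no defined CV; they
    are never selected and their count is logged. Among the selected
    features the original row order is preserved, and ties in CV are broken
    by original row order (stable sort).
    """
    if n_top > m.n_features:
        raise ValueError(
            f"n_top={n_top} exceeds the number of features ({m.n_features})"
        )
    if n_top < 1:
        raise ValueError("n_top must be a positive integer")
    means = m.values.mean(axis=1)
    sds = m.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / means, -np.inf)
    n_undefined = int(np.sum(means == 0))
    if n_undefined:
        logger.info(
            "select_features_by_cv: %d feature(s) with zero mean excluded "
            "from CV ranking",
            n_undefined,
        )
    order = np.argsort(-cv, kind="stable")[:n_top]
    return m.subset_features(np.sort(order))
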