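"""Seeded synthetic bulk-mixture generators.

Every stage of the package is testable offline against mixtures with known
ground truth. Two generators emulate the two data modalities:

* :func:`simulate_expression` — bulk RNA mixtures of K cell types. Each
  cell-type profile shares a log-normal baseline; a disjoint block of marker
  genes per component is up-weighted by a fold change (default 8) in that
  component only. Proportions are Dirichlet; noise is multiplicative
  log-normal.
* :func:`simulate_methylation` — beta-value mixtures. Profiles are bimodal
  Beta(0.3, 0.3) draws; each component receives a block of anchor CpGs
  (beta 0.95 in it, 0.05 elsewhere). Noise is additive Gaussian with the
  result clipped back into [0, 1]. A CpG → gene map (3 CpGs per synthetic
  gene) accompanies the matrix for the interpretation pipeline.

Both return the :class:`MixtureTruth` (true T, true A, the planted marker
sets) so recovery can be scored with
:func:`decomix.engines.match_components`. Output is fully determined by the
seed. The defaults mirror a six-cell-type mixture experiment (K=6, 2000
features, 36 samples, 5% noise).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import OmicsMatrix

__all__ = ["MixtureTruth", "simulate_expression", "simulate_methylation"]


@dataclass
class MixtureTruth:
    """Ground truth behind a simulated mixture."""

    T_true: np.ndarray  # features × K
    A_true: np.ndarray  # K × samples, simplex columns
    marker_sets: dict[str, set[str]] = field(repr=False)  # component -> gene ids
    noise_sd: float = 0.0
    seed: int = 0


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _dirichlet_proportions(
    rng, k: int, n_samples: int, alpha: float, n_pure_per_component: int = 0
) -> np.ndarray:
    """Dirichlet proportion columns, optionally with purified endmembers.

    Designed benchmark mixtures profile purified cell populations alongside
    the mixtures; ``n_pure_per_component`` leading samples per component are
    set to that component's vertex of the simplex. Without boundary samples
    an exact mixture is not identifiable from the factorization constraints
    alone (any slightly wider simplex reproduces X), so exact-recovery
    experiments need pure samples.
    """
    n_pure = k * n_pure_per_component
    if n_pure > n_samples:
        raise ValueError("more pure samples requested than samples")
    A = rng.dirichlet(np.full(k, alpha), size=n_samples).T
    for j in range(k):
        for r in range(n_pure_per_component):
            col = j * n_pure_per_component + r
            A[:, col] = 0.0
            A[j, col] = 1.0
    return A


def simulate_expression(
    k: int = 6,
    n_features: int = 2000,
    n_samples: int = 36,
    n_markers_per_component: int = 30,
    noise_sd: float = 0.05,
    seed: int = 0,
    fold_change: float = 8.0,
    dirichlet_alpha: float = 1.0,
    baseline_meanlog: float = 5.0,
    baseline_sdlog: float = 1.0,
    marker_background: float = 1.0,
    n_pure_samples_per_component: int = 0,
) -> tuple[OmicsMatrix, MixtureTruth]:
    """Simulate a bulk expression mixture with planted marker genes.

    ``X = T_true · A_true`` with multiplicative log-normal noise of
    log-scale standard deviation ``noise_sd`` (``noise_sd=0`` gives the
    exact product). Marker genes (disjoint blocks of
    ``n_markers_per_component`` per component, placed at seeded random
    rows) have their baseline multiplied by ``fold_change`` in their
    component only, giving them high coefficients of variation across
    samples.
    """
    if k * n_markers_per_component > n_features:
        raise ValueError(
            f"{k} components x {n_markers_per_component} markers exceed "
            f"{n_features} features"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=baseline_meanlog, sigma=baseline_sdlog, size=n_features)
    T = np.tile(baseline[:, None], (1, k))
    marker_rows = rng.permutation(n_features)[: k * n_markers_per_component]
    feature_ids = _ids("gene", n_features)
    marker_sets: dict[str, set[str]] = {}
    for j in range(k):
        rows = marker_rows[
            j * n_markers_per_component : (j + 1) * n_markers_per_component
        ]
        T[rows, :] *= marker_background
        T[rows, j] = baseline[rows] * fold_change
        marker_sets[f"C{j + 1}"] = {feature_ids[i] for i in rows}
    A = _dirichlet_proportions(
        rng, k, n_samples, dirichlet_alpha, n_pure_samples_per_component
    )
    X = T @ A
    if noise_sd > 0:
        X = X * rng.lognormal(mean=0.0, sigma=noise_sd, size=X.shape)
    m = OmicsMatrix(
        values=X,
        feature_ids=feature_ids,
        sample_ids=_ids("sample", n_samples),
        modality="expression",
    )
    truth = MixtureTruth(
        T_true=T, A_true=A, marker_sets=marker_sets, noise_sd=noise_sd, seed=seed
    )
    return m, truth


def simulate_methylation(
    k: int = 6,
    n_features: int = 2000,
    n_samples: int = 36,
    n_anchor_cpgs: int = 30,
    noise_sd: float = 0.05,
    seed: int = 0,
    dirichlet_alpha: float = 1.0,
    cpgs_per_gene: int = 3,
    n_pure_samples_per_component: int = 0,
) -> tuple[OmicsMatrix, MixtureTruth, dict[str, str]]:
    """Simulate a beta-value mixture with planted anchor CpGs.

    Profile entries are Beta(0.3, 0.3) (bimodal, as beta-values are);
    anchor CpGs of component ``j`` have beta 0.95 in it and 0.05 elsewhere.
    Anchors are allocated in whole synthetic genes (``cpgs_per_gene`` CpGs
    each) so the planted marker sets are disjoint at the gene level too.
    ``X = T_true · A_true`` plus additive Gaussian noise clipped to
    ``[0, 1]``. Returns the matrix, the truth and the CpG → gene map.
    """
    if k * n_anchor_cpgs > n_features:
        raise ValueError(
            f"{k} components x {n_anchor_cpgs} anchors exceed {n_features} CpGs"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    T = rng.beta(0.3, 0.3, size=(n_features, k))
    cpg_ids = _ids("cpg", n_features)
    n_genes = int(np.ceil(n_features / cpgs_per_gene))
    gene_ids = _ids("gene", n_genes)
    cpg_map = {
        cpg_ids[i]: gene_ids[i // cpgs_per_gene] for i in range(n_features)
    }
    # anchors assigned by whole genes so marker sets stay disjoint
    anchors_per_comp_genes = int(np.ceil(n_anchor_cpgs / cpgs_per_gene))
    gene_order = rng.permutation(n_genes)
    marker_sets: dict[str, set[str]] = {}
    g_cursor = 0
    for j in range(k):
        genes_j = gene_order[g_cursor : g_cursor + anchors_per_comp_genes]
        g_cursor += anchors_per_comp_genes
        rows: list[int] = []
        for g in genes_j:
            rows.extend(
                i
                for i in range(
                    g * cpgs_per_gene, min((g + 1) * cpgs_per_gene, n_features)
                )
            )
        rows = rows[:n_anchor_cpgs]
        T[rows, :] = 0.05
        T[rows, j] = 0.95
        marker_sets[f"C{j + 1}"] = {gene_ids[g] for g in genes_j}
    A = _dirichlet_proportions(
        rng, k, n_samples, dirichlet_alpha, n_pure_samples_per_component
    )
    X = T @ A
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = np.clip(X, 0.0, 1.0)
    m = OmicsMatrix(
        values=X,
        feature_ids=cpg_ids,
        sample_ids=_ids("sample", n_samples),
        modality="methylation",
    )
    truth = MixtureTruth(
        T_true=T, A_true=A, marker_sets=marker_sets, noise_sd=noise_sd, seed=seed
    )
    return m, truth, cpg_map
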