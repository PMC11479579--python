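"""Results container for fitted deconvolutions.

A :class:`DeconvolutionResults` holds the estimated proportion matrix ``A``
(components × samples, simplex columns), the profile matrix ``T``
(features × components), the fit trace and diagnostics, plus enough metadata
(ids, modality, engine, seed) to interpret or serialize the fit. Instances
are produced by the engine functions in :mod:`decomix.engines` or by
:meth:`decomix.model.DeconvolutionModel.fit`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DeconvolutionResults"]


@dataclass
class DeconvolutionResults:
    A: np.ndarray
    T: np.ndarray
    k: int
    engine: str
    seed: int
    modality: str
    feature_ids: list[str] = field(repr=False)
    sample_ids: list[str] = field(repr=False)
    rss_trace: list[float] = field(default_factory=list, repr=False)
    n_iterations: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.A.shape != (self.k, len(self.sample_ids)):
            raise ValueError("A must be K x n_samples")
        if self.T.shape != (len(self.feature_ids), self.k):
            raise ValueError("T must be n_features x K")

    # -- tabular views ------------------------------------------------------
    @property
    def component_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.k)]

    @property
    def proportions(self) -> pd.DataFrame:
        """Estimated proportions A as a DataFrame (components × samples)."""
        return pd.DataFrame(
            self.A, index=self.component_names, columns=list(self.sample_ids)
        )

    @property
    def profiles(self) -> pd.DataFrame:
        """Estimated profiles T as a DataFrame (features × components)."""
        return pd.DataFrame(
            self.T, index=list(self.feature_ids), columns=self.component_names
        )

    @property
    def final_rss(self) -> float:
        return float(self.rss_trace[-1]) if self.rss_trace else float("nan")

    # -- analysis -----------------------------------------------------------
    def rank_genes(self, component: int):
        """Ranked contribution scores for one component (1-based index)."""
        from .interpretation import rank_component_genes

        return rank_component_genes(self.profiles, component)

    def interpret(self, sets, cpg_map=None, **kwargs):
        """Enrichment-based interpretation of every component."""
        from .interpretation import interpret_components

        return interpret_components(self, sets, cpg_map=cpg_map, **kwargs)

    def match(self, truth_A: np.ndarray):
        """Match components against a ground-truth proportion matrix."""
        from .engines import match_components

        return match_components(self, truth_A)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Deconvolution Results",
            "=" * 58,
            f"engine: {self.engine:<12} modality: {self.modality}",
            f"components (K): {self.k:<6} seed: {self.seed}",
            f"features: {len(self.feature_ids):<8} samples: {len(self.sample_ids)}",
            f"iterations: {self.n_iterations:<6} converged: {self.converged}",
            f"final RSS: {self.final_rss:.6g}",
            "-" * 58,
            "mean proportion per component:",
        ]
        means = self.A.mean(axis=1)
        for name, mu in zip(self.component_names, means):
            lines.append(f"  {name:<6} {mu:8.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_proportions(self, ax=None):
        """Stacked-bar plot of estimated proportions per sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        bottom = np.zeros(self.A.shape[1])
        x = np.arange(self.A.shape[1])
        for i, name in enumerate(self.component_names):
            ax.bar(x, self.A[i], bottom=bottom, label=name)
            bottom += self.A[i]
        ax.set_xticks(x)
        ax.set_xticklabels(self.sample_ids, rotation=90, fontsize=6)
        ax.set_ylabel("proportion")
        ax.legend(fontsize=6)
        return ax

    # -- serialization ------------------------------------------------------
    def save(self, prefix: str | Path) -> list[Path]:
        """Write ``<prefix>.A.csv``, ``<prefix>.T.csv``, ``<prefix>.diagnostics.json``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        a_path = Path(str(prefix) + ".A.csv")
        t_path = Path(str(prefix) + ".T.csv")
        d_path = Path(str(prefix) + ".diagnostics.json")
        self.proportions.to_csv(a_path)
        self.profiles.to_csv(t_path)
        meta = {
            "engine": self.engine,
            "k": self.k,
            "seed": self.seed,
            "modality": self.modality,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "rss_trace": [float(r) for r in self.rss_trace],
            "diagnostics": _jsonable(self.diagnostics),
        }
        d_path.write_text(json.dumps(meta, indent=2))
        return [a_path, t_path, d_path]

    @classmethod
    def load(cls, prefix: str | Path) -> "DeconvolutionResults":
        prefix = Path(prefix)
        A = pd.read_csv(str(prefix) + ".A.csv", index_col=0)
        T = pd.read_csv(str(prefix) + ".T.csv", index_col=0)
        meta = json.loads(Path(str(prefix) + ".diagnostics.json").read_text())
        return cls(
            A=A.to_numpy(),
            T=T.to_numpy(),
            k=int(meta["k"]),
            engine=meta["engine"],
            seed=int(meta["seed"]),
            modality=meta["modality"],
            feature_ids=[str(i) for i in T.index],
            sample_ids=[str(c) for c in A.columns],
            rss_trace=list(meta.get("rss_trace", [])),
            n_iterations=int(meta.get("n_iterations", 0)),
            converged=bool(meta.get("converged", True)),
            diagnostics=meta.get("diagnostics", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
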