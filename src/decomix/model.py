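"""Model-style front end to the deconvolution engines.

Usage follows the familiar model/results pattern::

    model = DeconvolutionModel(matrix, k=4, engine="nmf")
    res = model.fit(seed=0)
    print(res.summary())
    res.proportions          # K × samples DataFrame, simplex columns
    res.interpret(gene_sets) # enrichment-based annotation
"""
from __future__ import annotations

import pandas as pd

from . import engines
from .data import OmicsMatrix
from .results import DeconvolutionResults

__all__ = ["DeconvolutionModel", "ENGINES"]

ENGINES = {
    "nmf": engines.nmf_deconvolve,
    "edec": engines.edec_deconvolve,
    "ica": engines.ica_deconvolve,
    "cam_lite": engines.cam_lite_deconvolve,
}


class DeconvolutionModel:
    """Reference-free deconvolution model ``X ≈ T · A``.

    Parameters
    ----------
    data : OmicsMatrix
        Bulk features × samples matrix.
    k : int
        Number of latent components (putative cell types).
    engine : {"nmf", "edec", "ica", "cam_lite"}
        Factorization algorithm; ``edec`` requires methylation input.
    **options
        Engine-specific keyword options, passed through to the engine
        function at fit time (e.g. ``max_iter``, ``n_restarts``,
        ``n_markers``, ``cluster_factor``).
    """

    def __init__(self, data: OmicsMatrix, k: int, engine: str = "nmf", **options):
        if not isinstance(data, OmicsMatrix):
            raise TypeError("data must be an OmicsMatrix")
        engine_key = engine.replace("-", "_").lower()
        if engine_key not in ENGINES:
            raise ValueError(
                f"unknown engine {engine!r}; choose from {sorted(ENGINES)}"
            )
        if k < 1:
            raise ValueError("k must be a positive integer")
        self.data = data
        self.k = int(k)
        self.engine = engine_key
        self.options = options

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        modality: str,
        k: int,
        engine: str = "nmf",
        **options,
    ) -> "DeconvolutionModel":
        """Build a model from a features × samples DataFrame."""
        return cls(OmicsMatrix.from_frame(frame, modality), k, engine, **options)

    def fit(self, seed: int = 0) -> DeconvolutionResults:
        """Run the configured engine; deterministic given ``seed``."""
        fn = ENGINES[self.engine]
        return fn(self.data, self.k, seed=seed, **self.options)

    def __repr__(self) -> str:
        return (
            f"DeconvolutionModel(engine={self.engine!r}, k={self.k}, "
            f"features={self.data.n_features}, samples={self.data.n_samples}, "
            f"modality={self.data.modality!r})"
        )
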