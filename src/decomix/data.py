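"""Omics matrix container and CSV input/output.

The central data structure is :class:`OmicsMatrix`, a features-by-samples
numeric matrix carrying its feature and sample identifiers and a modality tag.
Expression matrices hold non-negative counts or intensities; methylation
matrices hold CpG beta-values, i.e. proportions in ``[0, 1]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("expression", "methylation")

__all__ = ["OmicsMatrix", "MODALITIES", "read_matrix_csv", "write_matrix_csv"]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """A features × samples numeric matrix with identifiers and a modality.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
        The numeric data; samples in columns, features in rows.
    feature_ids, sample_ids : list of str
        Unique row and column identifiers, in matrix order.
    modality : {"expression", "methylation"}
        Methylation matrices must contain finite beta-values in ``[0, 1]``.
    """

    values: np.ndarray
    feature_ids: list[str] = field(repr=False)
    sample_ids: list[str] = field(repr=False)
    modality: str = "expression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        nf, ns = self.values.shape
        if nf != len(self.feature_ids):
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if ns != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {ns} matrix columns"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.modality == "methylation":
            if self.values.size and (
                self.values.min() < 0.0 or self.values.max() > 1.0
            ):
                i, j = np.argwhere(
                    (self.values < 0) | (self.values > 1)
                )[0]
                raise ValueError(
                    f"methylation beta-value {self.values[i, j]!r} outside [0, 1] "
                    f"at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )

    # -- basic introspection ------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        """Return the matrix as a DataFrame (features in index)."""
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, modality: str) -> "OmicsMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            modality=modality,
        )

    def with_values(self, values: np.ndarray) -> "OmicsMatrix":
        """Copy with new values, same ids and modality."""
        return OmicsMatrix(
            values=values,
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            modality=self.modality,
        )

    def subset_features(self, row_indices) -> "OmicsMatrix":
        idx = np.asarray(row_indices, dtype=int)
        return OmicsMatrix(
            values=self.values[idx, :],
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            modality=self.modality,
        )


def read_matrix_csv(path: str | Path, modality: str) -> OmicsMatrix:
    """Read a features × samples CSV matrix.

    The first column holds feature ids and the header row holds sample ids
    (the first header cell is ignored). Every data cell must parse as a
    number; for methylation the values must lie in ``[0, 1]``.
    """
    path = Path(path)
    # pandas mangles duplicate header names; check the raw header ourselves
    import csv as _csv

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(_csv.reader(fh))
    _check_unique([str(c) for c in header[1:]], "sample")
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    # locate a non-numeric or missing cell precisely before handing off
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = frame.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"non-numeric cell in {path.name} at feature {row!r}, "
                f"sample {col!r}: {frame.at[row, col]!r}"
            )
        frame[col] = numeric
    return OmicsMatrix.from_frame(frame, modality=modality)


def write_matrix_csv(m: OmicsMatrix, path: str | Path) -> None:
    """Write an :class:`OmicsMatrix` to CSV (lossless round trip)."""
    m.to_frame().to_csv(path)
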