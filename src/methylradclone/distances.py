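"""Symmetric pairwise distance matrices between shoots.

All downstream inference (Mantel tests, relative-distance summaries)
consumes this container, whether the distances are epigenetic (PCA plane),
genetic (SNP dosage space), phenotypic (|ΔPiABS|), or physical (transect
position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal.

    Parameters
    ----------
    sample_ids
        Ordered sample labels, one per row/column.
    values
        Square array of pairwise distances.
    label
        Free-text context tag (e.g. ``"gene-CG"``, ``"genetic"``, ``"all"``).
    """

    sample_ids: list[str]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distance matrix has negative entries")
        # clean tiny numerical asymmetries so condensed() is exact
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (scipy convention)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def relative(self) -> "DistanceMatrix":
        """Distances divided by the maximum distance (entries in [0, 1]).

        Raises if all distances are zero, since the normalization is then
        undefined.
        """
        m = self.values.max()
        if m <= 0:
            raise ValueError("cannot normalize an all-zero distance matrix")
        return DistanceMatrix(list(self.sample_ids), self.values / m, self.label)

    def subset(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            list(sample_ids), self.values[np.ix_(idx, idx)], self.label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), label)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_frame(df, label)


def euclidean_distance_matrix(
    matrix: np.ndarray, sample_ids: list[str], label: str = ""
) -> DistanceMatrix:
    """Euclidean distances between the rows of ``matrix`` (samples x features)."""
    from scipy.spatial.distance import pdist, squareform

    values = squareform(pdist(np.asarray(matrix, dtype=float), metric="euclidean"))
    return DistanceMatrix(list(sample_ids), values, label)


def from_positions(positions: dict[str, float], label: str = "physical") -> DistanceMatrix:
    """|Δposition| matrix from along-transect coordinates in meters."""
    ids = list(positions)
    pos = np.array([positions[s] for s in ids], dtype=float)
    return DistanceMatrix(ids, np.abs(pos[:, None] - pos[None, :]), label)
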