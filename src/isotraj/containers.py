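"""Core in-memory containers shared by every pipeline stage.

The pipeline moves a genes-by-cells expression matrix through a sequence of
coordinate systems (PCA, t-SNE, isometric embedding).  Each container keeps
its cell identifiers so that per-cell results can always be joined back to
the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "Embedding", "CellMetadata"]


def _check_unique(ids: np.ndarray, what: str) -> None:
    values, counts = np.unique(ids, return_counts=True)
    dup = values[counts > 1]
    if dup.size:
        raise ValueError(
            f"duplicate {what}: {', '.join(map(str, dup[:10]))}"
            + (" ..." if dup.size > 10 else "")
        )


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray, shape (K, N)
        Expression values, genes as rows and cells as columns.  May be raw
        counts, RPKM/TPM, or already log-scale.
    gene_ids : array-like of str, length K
    cell_ids : array-like of str, length N
    is_log : bool
        Whether a log transform has already been applied.  Guards against
        double transformation.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_log: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        k, n = self.values.shape
        if k < 1 or n < 2:
            raise ValueError(f"need at least 1 gene and 2 cells, got {k} x {n}")
        if self.gene_ids.shape != (k,):
            raise ValueError("gene_ids length does not match number of rows")
        if self.cell_ids.shape != (n,):
            raise ValueError("cell_ids length does not match number of columns")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class Embedding:
    """Per-cell coordinates in a named space (``pca``, ``tsne`` or ``isomap``)."""

    coords: np.ndarray
    space: str
    cell_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    _SPACES = ("pca", "tsne", "isomap")

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        if self.space not in self._SPACES:
            raise ValueError(f"space must be one of {self._SPACES}, got {self.space!r}")
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be N x d with d >= 1")
        if self.space == "tsne" and self.coords.shape[1] != 2:
            raise ValueError("t-SNE embedding must be 2-D")
        if self.cell_ids.shape[0] != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match coords")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.space}_{i + 1}" for i in range(self.n_dims)]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "cell_id", self.cell_ids)
        return df


@dataclass
class CellMetadata:
    """Optional per-cell annotations, e.g. true collection-time labels.

    ``time_label`` is used to pick the trajectory root automatically (the
    cluster holding most cells from the earliest time point) and to score
    the inferred pseudo-time against known time by rank correlation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "cell_id" not in self.table.columns:
            raise ValueError("metadata table requires a 'cell_id' column")
        self.table = self.table.copy()
        self.table["cell_id"] = self.table["cell_id"].astype(str)
        _check_unique(self.table["cell_id"].to_numpy(), "metadata cell ids")

    @property
    def cell_ids(self) -> np.ndarray:
        return self.table["cell_id"].to_numpy()

    def time_labels_for(self, cell_ids: np.ndarray) -> Optional[np.ndarray]:
        """Time labels aligned to ``cell_ids``; None if absent.

        Cells without a label get NaN.
        """
        if "time_label" not in self.table.columns:
            return None
        s = self.table.set_index("cell_id")["time_label"]
        return s.reindex(np.asarray(cell_ids, dtype=str)).to_numpy(dtype=float)

    @classmethod
    def from_file(cls, path) -> "CellMetadata":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df)
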