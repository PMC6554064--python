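"""Matrix input, gene filtering, and the PCA / t-SNE reductions.

All downstream stages consume either the PCA embedding (geodesic graph for
the isometric map) or the 2-D t-SNE embedding (density estimation and
clustering), so this module fixes the conventions once: matrices are
oriented genes x cells in memory, the log transform is ``log2(x + 1)``, and
every embedding carries the cell identifiers of its source matrix.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .containers import Embedding, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "log2_transform",
    "filter_genes",
    "pca_reduce",
    "tsne_embed",
]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def _read_sidecar_ids(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    # 10x genes.tsv carries (id, symbol); the first column is the identifier
    return df.iloc[:, 0].astype(str).to_numpy()


def read_matrix(
    path,
    format: Optional[str] = None,
    *,
    cells_as_rows: bool = False,
    genes_file=None,
    barcodes_file=None,
    is_log: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or MatrixMarket triplet.

    Delimited text is expected to carry gene identifiers in the first column
    and cell identifiers in the header row (flip with ``cells_as_rows``).
    MatrixMarket input follows the 10x layout: ``genes.tsv`` and
    ``barcodes.tsv`` next to the ``.mtx`` file unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "mtx":
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.tsv"
        barcodes_file = (
            Path(barcodes_file) if barcodes_file else path.parent / "barcodes.tsv"
        )
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise ValueError(f"unparseable MatrixMarket file {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = _read_sidecar_ids(genes_file)
        cell_ids = _read_sidecar_ids(barcodes_file)
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"unparseable {fmt} file {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ValueError(f"unparseable {fmt} file {path}: no data columns")
        values = df.to_numpy(dtype=float)
        gene_ids = df.index.astype(str).to_numpy()
        cell_ids = df.columns.astype(str).to_numpy()
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if cells_as_rows:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, cell_ids, is_log=is_log)


def write_matrix(m: ExpressionMatrix, path) -> None:
    """Write genes x cells as TSV with gene ids as index and cell ids as header."""
    m.to_frame().to_csv(path, sep="\t")


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``x -> log2(x + 1)`` entrywise.

    The unit pseudocount keeps zeros at zero and so preserves sparsity;
    refuses matrices already flagged as log-scale.
    """
    if m.is_log:
        raise ValueError("matrix is already log-transformed; refusing to re-apply")
    if np.any(m.values < 0):
        raise ValueError("negative entries: input does not look like counts/abundance")
    return ExpressionMatrix(
        np.log2(m.values + 1.0), m.gene_ids, m.cell_ids, is_log=True
    )


def filter_genes(
    m: ExpressionMatrix,
    min_cells_frac: float = 0.01,
    min_variance_quantile: float = 0.0,
) -> Tuple[ExpressionMatrix, np.ndarray]:
    """Drop lowly expressed and (optionally) low-variance genes.

    A gene survives if it is detected (value > 0) in at least
    ``min_cells_frac`` of cells.  If ``min_variance_quantile`` > 0, genes
    whose variance does not exceed that quantile of the surviving genes'
    variances are dropped as well.  Gene order is preserved.

    Returns the filtered matrix and the kept gene ids.
    """
    if not 0.0 <= min_cells_frac <= 1.0:
        raise ValueError("min_cells_frac must be in [0, 1]")
    if not 0.0 <= min_variance_quantile < 1.0:
        raise ValueError("min_variance_quantile must be in [0, 1)")

    n = m.n_cells
    expressed_frac = (m.values > 0).sum(axis=1) / n
    keep = expressed_frac >= min_cells_frac
    if min_variance_quantile > 0.0 and keep.any():
        variances = m.values[keep].var(axis=1)
        threshold = np.quantile(variances, min_variance_quantile)
        var_keep = np.zeros_like(keep)
        var_keep[keep] = variances > threshold
        keep = var_keep
    if not keep.any():
        raise ValueError(
            "gene filtering removed every gene; relax min_cells_frac or "
            "min_variance_quantile"
        )
    filtered = ExpressionMatrix(
        m.values[keep], m.gene_ids[keep], m.cell_ids, is_log=m.is_log
    )
    log.info("filter_genes kept %d / %d genes", filtered.n_genes, m.n_genes)
    return filtered, filtered.gene_ids


def pca_reduce(
    m: ExpressionMatrix,
    n_pcs: Optional[int] = None,
    var_explained: Optional[float] = None,
) -> Embedding:
    """Project cells onto the top principal components of the centered matrix.

    Exactly one of ``n_pcs`` / ``var_explained`` may be given; with neither,
    the smallest number of components explaining 90% of the variance is
    used.  Cells are observations, genes are features.
    """
    if n_pcs is not None and var_explained is not None:
        raise ValueError("give n_pcs or var_explained, not both")
    if n_pcs is None and var_explained is None:
        var_explained = 0.90

    x = m.values.T  # cells x genes
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_pcs is not None:
        if n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if n_pcs > max_rank:
            warnings.warn(
                f"n_pcs={n_pcs} exceeds the matrix rank bound {max_rank}; clamped",
                stacklevel=2,
            )
            n_pcs = max_rank
        n_fit = n_pcs
    else:
        if not 0.0 < var_explained <= 1.0:
            raise ValueError("var_explained must be in (0, 1]")
        n_fit = max_rank

    # full SVD is cheap whenever one dimension is small; fall back to the
    # seeded randomized solver for big dense problems
    solver = "full" if min(x.shape) <= 1000 else "auto"
    pca = PCA(n_components=n_fit, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_

    if var_explained is not None:
        cumulative = np.cumsum(ratios)
        d = int(np.searchsorted(cumulative, var_explained - 1e-12) + 1)
        d = min(d, scores.shape[1])
        scores = scores[:, :d]
        ratios = ratios[:d]

    return Embedding(
        scores,
        "pca",
        m.cell_ids,
        meta={
            "n_pcs": scores.shape[1],
            "explained_variance_ratio": ratios.tolist(),
        },
    )


def tsne_embed(
    pca: Embedding,
    perplexity: float = 30.0,
    seed: int = 0,
    max_iter: int = 500,
) -> Embedding:
    """2-D t-SNE of the PCA scores; deterministic for a fixed seed."""
    if pca.space != "pca":
        raise ValueError("tsne_embed expects a PCA embedding")
    n = pca.n_cells
    if not 0 < perplexity < n:
        raise ValueError(f"perplexity must be in (0, N={n})")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=max_iter,
    )
    coords = tsne.fit_transform(pca.coords)
    return Embedding(
        np.asarray(coords, dtype=float),
        "tsne",
        pca.cell_ids,
        meta={"perplexity": perplexity, "seed": seed, "max_iter": max_iter},
    )
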