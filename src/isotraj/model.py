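"""High-level model interface: configure once, ``fit()``, inspect results.

``TrajectoryModel`` wires the pipeline stages together — log transform and
gene filtering, PCA, t-SNE, kNN-graph density peaks, iterative clustering,
Landmark Isomap with peaks and valleys as landmarks, the MST trajectory and
edge-projection pseudo-time — and ``TrajectoryResults`` carries every
intermediate product plus a text ``summary()`` and table writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import density, isomap, preprocessing, trajectory
from .containers import CellMetadata, Embedding, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["TrajectoryModel", "TrajectoryResults"]


@dataclass
class TrajectoryResults:
    """Everything the fitted pipeline produced, one attribute per stage."""

    matrix: ExpressionMatrix
    pca: Embedding
    tsne: Embedding
    iso: Embedding
    graph: density.DensityGraph
    clusters: density.ClusterAssignment
    tree: trajectory.TrajectoryTree
    pseudotime: trajectory.PseudotimeResult
    spearman: Optional[float] = None
    config: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def cell_table(self) -> pd.DataFrame:
        """One row per cell: cluster, density, flags, coordinates, pseudotime."""
        df = pd.DataFrame(
            {
                "cell_id": self.matrix.cell_ids,
                "cluster": self.clusters.labels,
                "density": self.graph.density,
                "is_peak": self.graph.is_peak,
                "is_valley": self.graph.is_valley,
            }
        )
        for emb in (self.tsne, self.iso):
            for d in range(emb.n_dims):
                df[f"{emb.space}_{d + 1}"] = emb.coords[:, d]
        pt = self.pseudotime.to_frame().drop(columns="cell_id")
        return pd.concat([df, pt], axis=1)

    def summary(self) -> str:
        deg = self.tree.degrees()
        n_lineages = int(np.sum(deg == 1)) - (
            1 if deg[self.tree.root] == 1 else 0
        ) if self.tree.n_clusters > 1 else 1
        lines = [
            "Trajectory reconstruction summary",
            "=" * 48,
            f"cells:                  {self.n_cells}",
            f"genes (after filter):   {self.matrix.n_genes}",
            f"principal components:   {self.pca.n_dims}",
            f"density peaks:          {len(self.graph.peak_idx)}",
            f"density valleys:        {len(self.graph.valley_idx)}",
            f"clusters:               {self.clusters.C}",
            f"root cluster:           {self.tree.root + 1}",
            f"tree edges:             {len(self.tree.edges)}",
            f"branch points (deg>=3): {int(np.sum(deg >= 3))}",
            f"terminal lineages:      {n_lineages}",
            "pseudotime range:       "
            f"[{self.pseudotime.pseudotime.min():.4g}, "
            f"{self.pseudotime.pseudotime.max():.4g}]",
        ]
        if self.spearman is not None:
            lines.append(f"Spearman vs true time:  {self.spearman:.4f}")
        return "\n".join(lines)

    def write_tables(self, outdir) -> None:
        """Write the per-cell table, embeddings and the tree as TSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"

        def dump(df: pd.DataFrame, name: str) -> None:
            df.to_csv(outdir / name, sep="\t", index=False, float_format=fmt)

        dump(self.cell_table(), "cells.tsv")
        dump(self.tsne.to_frame(), "tsne.tsv")
        dump(self.iso.to_frame(), "isomap.tsv")
        dump(self.tree.to_frame(), "tree.tsv")

    def plot_trajectory(self, ax=None, color_by: str = "pseudotime"):
        """Scatter the isometric embedding with the tree overlaid (needs
        matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        values = (
            self.pseudotime.pseudotime
            if color_by == "pseudotime"
            else self.clusters.labels
        )
        sc = ax.scatter(
            self.iso.coords[:, 0], self.iso.coords[:, 1], c=values, s=8, alpha=0.7
        )
        for i, j, _ in self.tree.edges:
            ax.plot(*zip(self.tree.centers[i][:2], self.tree.centers[j][:2]), "k-")
        ax.scatter(*self.tree.centers[:, :2].T, c="red", marker="x", zorder=3)
        ax.set_xlabel("isomap 1")
        ax.set_ylabel("isomap 2")
        plt.colorbar(sc, ax=ax, label=color_by)
        return ax


class TrajectoryModel:
    """Branching-trajectory and pseudo-time model for one expression matrix.

    Parameters mirror the pipeline stages; all have working defaults.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Genes x cells input, raw or already log-scale.
    metadata : CellMetadata, optional
        Needed for ``root="auto"`` and the Spearman evaluation.
    min_cells_frac, min_variance_quantile : float
        Gene filters (fraction of cells a gene must be detected in; variance
        quantile below which genes are dropped, 0 disables).
    n_pcs, var_explained
        PCA truncation: explicit count or cumulative variance target
        (default: 90% variance).
    perplexity, tsne_max_iter, seed
        t-SNE controls; the seed also fixes every stochastic stage.
    k : int
        kNN-graph neighbourhood size (the cell plus k-1 neighbours).
    bandwidth : float or "auto"
        KDE bandwidth in the t-SNE plane; "auto" is Scott's rule.
    linkage : str
        Hierarchical-clustering linkage (ward/complete/average/single).
    m_geodesic, d_out
        Neighbourhood size of the geodesic graph in PCA space and the
        output dimension of the isometric embedding.
    root : int or "auto"
        Trajectory root cluster, 1-based; "auto" uses the earliest
        time-label rule.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        metadata: Optional[CellMetadata] = None,
        *,
        min_cells_frac: float = 0.01,
        min_variance_quantile: float = 0.0,
        n_pcs: Optional[int] = None,
        var_explained: Optional[float] = None,
        perplexity: float = 30.0,
        tsne_max_iter: int = 500,
        seed: int = 0,
        k: int = 50,
        bandwidth: Union[float, str] = "auto",
        linkage: str = "ward",
        m_geodesic: int = 10,
        d_out: int = 2,
        root: Union[int, str] = "auto",
    ) -> None:
        self.matrix = matrix
        self.metadata = metadata
        self.config = {
            "min_cells_frac": min_cells_frac,
            "min_variance_quantile": min_variance_quantile,
            "n_pcs": n_pcs,
            "var_explained": var_explained,
            "perplexity": perplexity,
            "tsne_max_iter": tsne_max_iter,
            "seed": seed,
            "k": k,
            "bandwidth": bandwidth,
            "linkage": linkage,
            "m_geodesic": m_geodesic,
            "d_out": d_out,
            "root": root,
        }

    @classmethod
    def from_files(
        cls,
        matrix_path,
        metadata_path=None,
        *,
        format: Optional[str] = None,
        cells_as_rows: bool = False,
        is_log: bool = False,
        **kwargs,
    ) -> "TrajectoryModel":
        matrix = preprocessing.read_matrix(
            matrix_path, format=format, cells_as_rows=cells_as_rows, is_log=is_log
        )
        meta = CellMetadata.from_file(metadata_path) if metadata_path else None
        return cls(matrix, meta, **kwargs)

    def fit(self) -> TrajectoryResults:
        cfg = self.config
        m = self.matrix
        if not m.is_log:
            m = preprocessing.log2_transform(m)
        m, _ = preprocessing.filter_genes(
            m, cfg["min_cells_frac"], cfg["min_variance_quantile"]
        )
        pca = preprocessing.pca_reduce(
            m, n_pcs=cfg["n_pcs"], var_explained=cfg["var_explained"]
        )
        perplexity = min(cfg["perplexity"], (m.n_cells - 1) / 3)
        tsne = preprocessing.tsne_embed(
            pca, perplexity=perplexity, seed=cfg["seed"],
            max_iter=cfg["tsne_max_iter"],
        )
        k = min(cfg["k"], m.n_cells)
        graph = density.build_knn_graph(tsne, k=k)
        graph = density.estimate_density(graph, tsne, bandwidth=cfg["bandwidth"])
        graph = density.find_peaks_valleys(graph)
        clusters = density.iterative_cluster(tsne, graph, linkage=cfg["linkage"])

        landmarks = np.union1d(graph.peak_idx, graph.valley_idx)
        iso = isomap.landmark_isomap(
            pca, landmarks, m=cfg["m_geodesic"], d_out=cfg["d_out"]
        )

        centers = trajectory.cluster_centers(iso, clusters)
        tree = trajectory.build_mst(centers)
        root = cfg["root"]
        if root != "auto":
            root = int(root) - 1  # user-facing clusters are 1-based
        tree = trajectory.set_root(
            tree, root, meta=self.metadata, clusters=clusters,
            cell_ids=m.cell_ids,
        )
        pt = trajectory.assign_and_time(iso, tree)

        spearman = None
        if self.metadata is not None and self.metadata.time_labels_for(
            m.cell_ids
        ) is not None:
            spearman = trajectory.evaluate_spearman(pt, self.metadata)

        return TrajectoryResults(
            matrix=m,
            pca=pca,
            tsne=tsne,
            iso=iso,
            graph=graph,
            clusters=clusters,
            tree=tree,
            pseudotime=pt,
            spearman=spearman,
            config=dict(cfg),
        )
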