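"""Density-based peak/valley detection and iterative hierarchical clustering.

The number of cell clusters is not a user parameter here: it is read off the
density landscape of the 2-D t-SNE embedding.  A cell whose kernel density
estimate is strictly higher (lower) than all of its k-1 nearest neighbours
is a peak (valley).  Hierarchical clustering is then cut at the number of
peaks and refined until every cluster holds exactly one peak, so the number
of clusters always equals the number of density peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial import cKDTree
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import KernelDensity, kneighbors_graph

from .containers import Embedding

log = logging.getLogger(__name__)

__all__ = [
    "DensityGraph",
    "ClusterAssignment",
    "build_knn_graph",
    "estimate_density",
    "find_peaks_valleys",
    "iterative_cluster",
    "scott_bandwidth",
]

# exact KDE below this size; tolerance-pruned tree evaluation above
_EXACT_KDE_MAX_N = 2000
# exact (scipy) hierarchical clustering below this size; above it, Ward with
# a sparse kNN connectivity graph avoids the O(N^2) distance matrix
_EXACT_LINKAGE_MAX_N = 4000


@dataclass
class DensityGraph:
    """kNN neighbourhoods over cells plus per-cell density and peak/valley flags.

    ``k`` counts the cell itself, so each cell stores its k-1 nearest other
    cells in ascending distance order.  ``density``/``is_peak``/``is_valley``
    are None until the corresponding stage has run.
    """

    k: int
    neighbor_idx: np.ndarray  # N x (k-1) int
    neighbor_dist: np.ndarray  # N x (k-1) float, rows non-decreasing
    density: Optional[np.ndarray] = None
    is_peak: Optional[np.ndarray] = None
    is_valley: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.neighbor_idx.shape[0]

    @property
    def peak_idx(self) -> np.ndarray:
        if self.is_peak is None:
            raise ValueError("peaks not yet computed")
        return np.flatnonzero(self.is_peak)

    @property
    def valley_idx(self) -> np.ndarray:
        if self.is_valley is None:
            raise ValueError("valleys not yet computed")
        return np.flatnonzero(self.is_valley)


@dataclass
class ClusterAssignment:
    """Dense 1..C per-cell labels with a one-to-one cluster-peak mapping."""

    labels: np.ndarray  # N ints in 1..C
    peak_of_cluster: np.ndarray  # C cell indices; cluster c has peak peak_of_cluster[c-1]
    C: int

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def build_knn_graph(emb: Embedding, k: int = 50) -> DensityGraph:
    """k-1 nearest neighbours per cell under Euclidean distance, via a kd-tree."""
    n = emb.n_cells
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, N={n}], got {k}")
    tree = cKDTree(emb.coords)
    dist, idx = tree.query(emb.coords, k=k)
    # drop each cell itself from its neighbour list; with duplicated
    # coordinates the self-match need not come first, so mask by index
    neighbor_idx = np.empty((n, k - 1), dtype=np.intp)
    neighbor_dist = np.empty((n, k - 1), dtype=float)
    for i in range(n):
        mask = idx[i] != i
        if mask.sum() == k:  # self never returned (all k slots taken by ties)
            mask[-1] = False
        neighbor_idx[i] = idx[i][mask][: k - 1]
        neighbor_dist[i] = dist[i][mask][: k - 1]
    return DensityGraph(k=k, neighbor_idx=neighbor_idx, neighbor_dist=neighbor_dist)


def scott_bandwidth(coords: np.ndarray) -> float:
    """Scott's-rule bandwidth N**(-1/(d+4)) times the mean marginal spread."""
    n, d = coords.shape
    sigma = float(np.sqrt(coords.var(axis=0, ddof=1).mean()))
    if sigma == 0.0:
        sigma = 1.0  # degenerate: all points identical
    return sigma * n ** (-1.0 / (d + 4))


def estimate_density(
    graph: DensityGraph,
    emb: Embedding,
    bandwidth: Union[float, str] = "auto",
) -> DensityGraph:
    """Gaussian kernel density estimate at every cell's own coordinates.

    ``"auto"`` uses Scott's rule on the embedding.  Evaluation is exact for
    small datasets and uses the kd-tree with a 1e-6 relative tolerance for
    large ones, so no N x N matrix is ever formed.
    """
    if bandwidth == "auto":
        bandwidth = scott_bandwidth(emb.coords)
        log.info("estimate_density: Scott bandwidth %.4g", bandwidth)
    if not np.isscalar(bandwidth) or bandwidth <= 0:
        raise ValueError("bandwidth must be positive or 'auto'")
    rtol = 0.0 if emb.n_cells <= _EXACT_KDE_MAX_N else 1e-6
    kde = KernelDensity(kernel="gaussian", bandwidth=float(bandwidth), rtol=rtol)
    kde.fit(emb.coords)
    density = np.exp(kde.score_samples(emb.coords))
    return replace(graph, density=density)


def find_peaks_valleys(graph: DensityGraph) -> DensityGraph:
    """Flag cells strictly denser (sparser) than all their k-1 neighbours.

    Ties with any neighbour disqualify a cell from both flags.  A landscape
    with no peak at all (possible only through massive ties) is rejected:
    the downstream clustering has no anchor in that case.
    """
    if graph.density is None:
        raise ValueError("density not yet estimated")
    neighbor_density = graph.density[graph.neighbor_idx]
    own = graph.density[:, None]
    is_peak = np.all(own > neighbor_density, axis=1)
    is_valley = np.all(own < neighbor_density, axis=1)
    n_ties = int(np.sum(~is_peak & np.all(own >= neighbor_density, axis=1)))
    if n_ties:
        log.info("find_peaks_valleys: %d cells tied with a neighbour", n_ties)
    if not is_peak.any():
        raise ValueError(
            "no density peak found (density ties everywhere); "
            "change the bandwidth or k"
        )
    log.info(
        "find_peaks_valleys: %d peaks, %d valleys", is_peak.sum(), is_valley.sum()
    )
    return replace(graph, is_peak=is_peak, is_valley=is_valley)


def _cut_tree(coords: np.ndarray, n_clusters: int, linkage: str) -> np.ndarray:
    """Hierarchical clustering of ``coords`` into ``n_clusters`` labels (0-based)."""
    n = coords.shape[0]
    if n_clusters >= n:
        return np.arange(n)
    if n <= _EXACT_LINKAGE_MAX_N:
        z = scipy_linkage(coords, method=linkage)
        return fcluster(z, t=n_clusters, criterion="maxclust") - 1
    connectivity = kneighbors_graph(coords, n_neighbors=15, include_self=False)
    model = AgglomerativeClustering(
        n_clusters=n_clusters, linkage=linkage, connectivity=connectivity
    )
    return model.fit_predict(coords)


def iterative_cluster(
    emb: Embedding, graph: DensityGraph, linkage: str = "ward"
) -> ClusterAssignment:
    """Cluster cells so that every final cluster contains exactly one peak.

    Procedure: cut a dendrogram over the t-SNE coordinates at the number of
    peaks; any cluster still holding p > 1 peaks is re-clustered on its own
    cells into p parts, until all clusters hold at most one peak; clusters
    left without a peak are merged into the cluster of their nearest peak
    (minimum Euclidean distance from the peak cell to any member cell, ties
    to the lower peak index).  Labels are finally renumbered 1..C with
    clusters ordered by their peak's cell index.
    """
    if graph.is_peak is None:
        raise ValueError("peaks not yet detected")
    if linkage not in ("ward", "complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    coords = emb.coords
    peaks = graph.peak_idx
    n = coords.shape[0]

    labels = _cut_tree(coords, len(peaks), linkage)
    next_label = labels.max() + 1
    # refine: recursion acts on strictly smaller cell subsets, so it ends
    for _ in range(n):
        multi = None
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            p = np.intersect1d(peaks, members, assume_unique=True)
            if len(p) > 1:
                multi = (c, members, len(p))
                break
        if multi is None:
            break
        c, members, n_peaks_in = multi
        sub = _cut_tree(coords[members], n_peaks_in, linkage)
        labels[members] = next_label + sub
        next_label += n_peaks_in

    # merge peakless clusters into the cluster of their nearest peak
    peak_label = {int(labels[p]): p for p in peaks}
    merged = labels.copy()
    for c in np.unique(labels):
        if int(c) in peak_label:
            continue
        members = np.flatnonzero(labels == c)
        d_to_peaks = np.linalg.norm(
            coords[members][None, :, :] - coords[peaks][:, None, :], axis=2
        ).min(axis=1)
        nearest = peaks[int(np.argmin(d_to_peaks))]  # argmin ties -> lower index
        merged[members] = labels[nearest]
        log.info(
            "iterative_cluster: merged peakless cluster of %d cells into peak %d",
            len(members),
            nearest,
        )
    labels = merged

    # dense relabel 1..C ordered by peak cell index
    final = np.zeros(n, dtype=int)
    for new, p in enumerate(np.sort(peaks), start=1):
        final[labels == labels[p]] = new
    assert np.all(final > 0), "every cell must land in a peak's cluster"
    return ClusterAssignment(
        labels=final, peak_of_cluster=np.sort(peaks), C=len(peaks)
    )
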