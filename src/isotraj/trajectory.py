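"""MST trajectory over cluster centers, cell projection, and pseudo-time.

The main trajectory is the minimum spanning tree of the complete Euclidean
graph on cluster centers in the isometric embedding.  After rooting, each
cell is dropped orthogonally onto its nearest tree edge; its pseudo-time is
the tree-path distance from the root to the near end of that edge plus the
offset of the projection point along it, giving one global time axis for
all cells regardless of branch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import CellMetadata, Embedding
from .density import ClusterAssignment

log = logging.getLogger(__name__)

__all__ = [
    "TrajectoryTree",
    "PseudotimeResult",
    "cluster_centers",
    "build_mst",
    "set_root",
    "project_cell",
    "assign_and_time",
    "evaluate_spearman",
]


@dataclass
class TrajectoryTree:
    """A spanning tree over cluster centers, optionally rooted.

    ``edges`` holds (i, j, weight) with weight the Euclidean distance
    between centers i and j.  Once rooted, each edge is oriented with its
    root-nearer endpoint first and ``path_dist`` holds tree-path distances
    from the root to every center.
    """

    centers: np.ndarray  # C x d
    edges: List[Tuple[int, int, float]]
    root: Optional[int] = None
    path_dist: Optional[np.ndarray] = None

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_clusters, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.edges, columns=["i", "j", "weight"])
        if self.path_dist is not None:
            df["path_dist_i"] = self.path_dist[df["i"]]
            df["path_dist_j"] = self.path_dist[df["j"]]
        return df


@dataclass
class PseudotimeResult:
    """Per-cell edge assignment, projection, and global pseudo-time."""

    cell_ids: np.ndarray
    edge_assigned: np.ndarray  # N x 2 (near endpoint, far endpoint)
    proj_coord: np.ndarray  # N x d
    proj_offset: np.ndarray  # N, in [0, edge length]
    pseudotime: np.ndarray  # N, >= 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "edge_i": self.edge_assigned[:, 0],
                "edge_j": self.edge_assigned[:, 1],
                "proj_offset": self.proj_offset,
                "pseudotime": self.pseudotime,
            }
        )


def cluster_centers(iso: Embedding, clusters: ClusterAssignment) -> np.ndarray:
    """Arithmetic mean of member-cell coordinates per cluster, C x d."""
    centers = np.empty((clusters.C, iso.n_dims), dtype=float)
    for c in range(1, clusters.C + 1):
        members = clusters.members(c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        centers[c - 1] = iso.coords[members].mean(axis=0)
    return centers


def build_mst(centers: np.ndarray) -> TrajectoryTree:
    """Minimum spanning tree of the complete Euclidean graph on centers.

    Kruskal with edges sorted by (weight, i, j), so equal-weight ties are
    resolved lexicographically and the result is reproducible.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 1:
        raise ValueError("centers must be a non-empty C x d matrix")
    c = centers.shape[0]
    candidates = sorted(
        (float(np.linalg.norm(centers[i] - centers[j])), i, j)
        for i in range(c)
        for j in range(i + 1, c)
    )
    parent = list(range(c))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: List[Tuple[int, int, float]] = []
    for w, i, j in candidates:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, w))
            if len(edges) == c - 1:
                break
    return TrajectoryTree(centers=centers, edges=edges)


def set_root(
    tree: TrajectoryTree,
    root: Union[int, str] = "auto",
    meta: Optional[CellMetadata] = None,
    clusters: Optional[ClusterAssignment] = None,
    cell_ids: Optional[np.ndarray] = None,
) -> TrajectoryTree:
    """Root the tree and compute path distances from the root.

    ``root="auto"`` picks the cluster containing the most cells labelled
    with the earliest time point (requires metadata with ``time_label``);
    ties go to the lower cluster index.  An explicit root is a 0-based
    cluster index.  Edges are re-oriented root-nearer endpoint first.
    """
    c = tree.n_clusters
    if root == "auto":
        if meta is None or clusters is None or cell_ids is None:
            raise ValueError(
                "root='auto' needs cell metadata with time labels; "
                "pass an explicit root otherwise"
            )
        times = meta.time_labels_for(cell_ids)
        if times is None or np.all(np.isnan(times)):
            raise ValueError(
                "root='auto' needs a 'time_label' metadata column; "
                "pass an explicit root otherwise"
            )
        t0 = np.nanmin(times)
        counts = np.array(
            [
                int(np.sum(times[clusters.members(k + 1)] == t0))
                for k in range(c)
            ]
        )
        root_idx = int(np.argmax(counts))  # argmax ties -> lower index
        log.info(
            "set_root: auto root cluster %d (%d cells at initial time %.4g)",
            root_idx + 1,
            counts[root_idx],
            t0,
        )
    else:
        root_idx = int(root)
        if not 0 <= root_idx < c:
            raise ValueError(f"root must be a cluster index in [0, {c})")

    adjacency: List[List[Tuple[int, float]]] = [[] for _ in range(c)]
    for i, j, w in tree.edges:
        adjacency[i].append((j, w))
        adjacency[j].append((i, w))
    path_dist = np.full(c, np.inf)
    path_dist[root_idx] = 0.0
    oriented: List[Tuple[int, int, float]] = []
    stack = [root_idx]
    seen = {root_idx}
    while stack:
        u = stack.pop()
        for v, w in adjacency[u]:
            if v not in seen:
                seen.add(v)
                path_dist[v] = path_dist[u] + w
                oriented.append((u, v, w))
                stack.append(v)
    if len(seen) != c:
        raise ValueError("edges do not form a spanning tree")
    oriented.sort(key=lambda e: (path_dist[e[0]], e[0], e[1]))
    return TrajectoryTree(
        centers=tree.centers, edges=oriented, root=root_idx, path_dist=path_dist
    )


def project_cell(
    point: np.ndarray, edge: Tuple[int, int, float], centers: np.ndarray
) -> Tuple[np.ndarray, float, float]:
    """Orthogonal projection of a point onto one tree edge, clamped.

    Returns (projection point, offset from the near endpoint along the
    edge in [0, weight], residual distance from the point to the
    projection).  The near endpoint is the first of the oriented edge.
    """
    i, j, w = edge
    vi, vj = centers[i], centers[j]
    if w <= 0.0:
        return vi.copy(), 0.0, float(np.linalg.norm(point - vi))
    direction = (vj - vi) / w
    offset = float(np.clip(np.dot(point - vi, direction), 0.0, w))
    proj = vi + offset * direction
    return proj, offset, float(np.linalg.norm(point - proj))


def assign_and_time(iso: Embedding, tree: TrajectoryTree) -> PseudotimeResult:
    """Assign each cell to its nearest edge and compute global pseudo-time.

    pseudotime = path_dist(near endpoint) + projection offset.  Residual
    ties go to the edge nearer the root, then lexicographic.  With a single
    cluster (no edges) every cell sits at the root with pseudo-time 0.
    """
    if tree.root is None or tree.path_dist is None:
        raise ValueError("tree must be rooted first")
    n, d = iso.coords.shape
    if not tree.edges:
        root_coord = tree.centers[tree.root]
        return PseudotimeResult(
            cell_ids=iso.cell_ids,
            edge_assigned=np.full((n, 2), tree.root, dtype=int),
            proj_coord=np.tile(root_coord, (n, 1)),
            proj_offset=np.zeros(n),
            pseudotime=np.zeros(n),
        )

    coords = iso.coords
    n_edges = len(tree.edges)
    residual = np.empty((n_edges, n))
    offsets = np.empty((n_edges, n))
    projections = np.empty((n_edges, n, d))
    # edges are already sorted root-outward, so argmin's first-minimum rule
    # realises the tie-break toward the root
    for e, (i, j, w) in enumerate(tree.edges):
        vi, vj = tree.centers[i], tree.centers[j]
        if w <= 0.0:
            off = np.zeros(n)
            proj = np.tile(vi, (n, 1))
        else:
            direction = (vj - vi) / w
            off = np.clip((coords - vi) @ direction, 0.0, w)
            proj = vi + off[:, None] * direction
        offsets[e] = off
        projections[e] = proj
        residual[e] = np.linalg.norm(coords - proj, axis=1)
    best = np.argmin(residual, axis=0)
    cell_rows = np.arange(n)
    edge_arr = np.array([(i, j) for i, j, _ in tree.edges], dtype=int)
    near = edge_arr[best, 0]
    proj_offset = offsets[best, cell_rows]
    pseudotime = tree.path_dist[near] + proj_offset
    return PseudotimeResult(
        cell_ids=iso.cell_ids,
        edge_assigned=edge_arr[best],
        proj_coord=projections[best, cell_rows],
        proj_offset=proj_offset,
        pseudotime=pseudotime,
    )


def evaluate_spearman(
    pt: PseudotimeResult, meta: CellMetadata
) -> float:
    """Spearman rank correlation of pseudo-time against true time labels.

    Average ranks for ties.  Returns NaN with a warning when either side is
    constant (correlation undefined); requires at least 3 labelled cells.
    """
    times = meta.time_labels_for(pt.cell_ids)
    if times is None:
        raise ValueError("metadata has no 'time_label' column")
    ok = ~np.isnan(times)
    if ok.sum() < 3:
        raise ValueError("need time labels for at least 3 cells")
    x, y = pt.pseudotime[ok], times[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant pseudotime or labels: Spearman undefined (NA)",
                      stacklevel=2)
        return float("nan")
    rho, _ = spearmanr(x, y)
    return float(rho)
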