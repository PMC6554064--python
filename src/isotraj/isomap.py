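"""Landmark Isomap: isometric embedding from landmark geodesic distances.

Full Isomap needs the complete N x N geodesic matrix and an O(N^3)
eigendecomposition.  With n landmark cells (here the density peaks and
valleys, n << N) only the n x N landmark-to-cell geodesics are required:
classical MDS of the n x n landmark block gives landmark coordinates, and
every other cell is triangulated from its squared distances to the
landmarks.  Nothing quadratic in N is ever materialised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .containers import Embedding

log = logging.getLogger(__name__)

__all__ = [
    "GeodesicDistances",
    "build_geodesic_graph",
    "landmark_geodesics",
    "landmark_mds",
    "embed_all",
    "landmark_isomap",
    "augment_landmarks",
]


@dataclass
class GeodesicDistances:
    """Shortest-path distances from each landmark to every cell."""

    dist: np.ndarray  # n x N
    landmark_idx: np.ndarray  # n cell indices

    @property
    def n_landmarks(self) -> int:
        return self.dist.shape[0]

    def landmark_block(self) -> np.ndarray:
        """The n x n landmark-to-landmark distance matrix, symmetrised."""
        block = self.dist[:, self.landmark_idx]
        return 0.5 * (block + block.T)


def build_geodesic_graph(pca: Embedding, m: int = 10) -> sp.csr_matrix:
    """Symmetric m-nearest-neighbour graph over cells in PCA space.

    Edge weights are Euclidean distances.  A disconnected graph is repaired
    by repeatedly adding the shortest edge between two components, so every
    cell keeps a finite geodesic distance (and hence a pseudo-time).
    """
    n = pca.n_cells
    if not 1 <= m < n:
        raise ValueError(f"m must be in [1, N-1], got {m}")
    coords = pca.coords
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=m + 1)
    rows = np.repeat(np.arange(n), m + 1)
    # duplicate points produce zero-length edges; floor them at a negligible
    # weight so sparse storage does not silently drop them
    weights = np.maximum(dist.ravel(), 1e-12)
    graph = sp.coo_matrix((weights, (rows, idx.ravel())), shape=(n, n)).tocsr()
    graph = graph.maximum(graph.T)
    graph.setdiag(0)
    graph.eliminate_zeros()

    n_comp, comp = connected_components(graph, directed=False)
    while n_comp > 1:
        best = None  # (dist, i, j)
        for c in range(n_comp):
            inside = np.flatnonzero(comp == c)
            outside = np.flatnonzero(comp != c)
            out_tree = cKDTree(coords[outside])
            d, j = out_tree.query(coords[inside], k=1)
            a = int(np.argmin(d))
            cand = (float(d[a]), int(inside[a]), int(outside[int(j[a])]))
            if best is None or cand < best:
                best = cand
        d, i, j = best
        graph = graph.tolil()
        graph[i, j] = d
        graph[j, i] = d
        graph = graph.tocsr()
        log.info("build_geodesic_graph: joined components with edge %d-%d (%.4g)", i, j, d)
        n_comp, comp = connected_components(graph, directed=False)
    return graph


def landmark_geodesics(graph: sp.csr_matrix, landmark_idx) -> GeodesicDistances:
    """Single-source shortest paths (Dijkstra) from each landmark."""
    landmark_idx = np.asarray(landmark_idx, dtype=np.intp)
    dist = dijkstra(graph, directed=False, indices=landmark_idx)
    if not np.all(np.isfinite(dist)):
        raise RuntimeError("unreachable cells: geodesic graph is not connected")
    return GeodesicDistances(dist=np.asarray(dist, dtype=float), landmark_idx=landmark_idx)


def _canonical_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    flip = vectors[np.argmax(np.abs(vectors), axis=0), np.arange(vectors.shape[1])] < 0
    out = vectors.copy()
    out[:, flip] *= -1.0
    return out


def landmark_mds(d_ll: np.ndarray, d_out: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Classical MDS of the landmark-landmark geodesic distances.

    Double-centers -0.5 * D^2 and keeps the top ``d_out`` eigenpairs with
    positive eigenvalues; coordinates are eigenvectors scaled by the square
    roots of the eigenvalues, with signs canonicalised for reproducibility.

    Returns (coords n x d, eigenvalues d).  d may be less than ``d_out`` if
    the spectrum has fewer positive eigenvalues.
    """
    d_ll = np.asarray(d_ll, dtype=float)
    if d_ll.ndim != 2 or d_ll.shape[0] != d_ll.shape[1]:
        raise ValueError("landmark distance matrix must be square")
    if not np.allclose(d_ll, d_ll.T, atol=1e-8):
        raise ValueError("landmark distance matrix must be symmetric")
    if d_out < 1:
        raise ValueError("d_out must be >= 1")
    n = d_ll.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d_ll**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(eigvals.max(), 0.0) * 1e-12
    n_pos = int(positive.sum())
    if n_pos < d_out:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; output reduced to {n_pos} dims",
            stacklevel=2,
        )
    d = min(d_out, n_pos)
    if d == 0:
        raise ValueError("no positive eigenvalue: degenerate landmark distances")
    vecs = _canonical_signs(eigvecs[:, :d])
    vals = eigvals[:d]
    log.info("landmark_mds eigenvalues: %s", np.array2string(eigvals[: d_out + 3]))
    return vecs * np.sqrt(vals), vals


def embed_all(
    gd: GeodesicDistances, landmark_coords: np.ndarray, eigvals: np.ndarray,
    cell_ids=None,
) -> Embedding:
    """Triangulate every cell from its squared geodesic distances to landmarks.

    The landmark-MDS out-of-sample rule: with L the landmark coordinate
    matrix and L# its pseudo-inverse transpose (rows v_i / sqrt(lambda_i)),
    a cell with squared-distance vector delta_x embeds at
    ``0.5 * L# @ (delta_mean - delta_x)``.  Landmarks map exactly onto their
    own MDS coordinates.
    """
    delta = gd.dist**2  # n x N
    d_ll2 = gd.landmark_block() ** 2
    delta_mean = d_ll2.mean(axis=1)  # n
    l_pinv = (landmark_coords / eigvals).T  # d x n
    coords = 0.5 * (l_pinv @ (delta_mean[:, None] - delta)).T  # N x d
    if cell_ids is None:
        cell_ids = np.array([f"cell_{i}" for i in range(coords.shape[0])])
    return Embedding(
        coords,
        "isomap",
        cell_ids,
        meta={"n_landmarks": gd.n_landmarks, "eigvals": np.asarray(eigvals).tolist()},
    )


def augment_landmarks(
    coords: np.ndarray, landmark_idx: np.ndarray, n_required: int
) -> np.ndarray:
    """Grow a landmark set to ``n_required`` points by max-min sampling.

    Deterministic farthest-point sampling in the given coordinate space;
    used when peaks and valleys alone are too few to anchor the embedding
    (landmark MDS needs at least d_out + 1 landmarks).
    """
    landmark_idx = np.asarray(sorted(set(int(i) for i in landmark_idx)), dtype=np.intp)
    n = coords.shape[0]
    if n_required > n:
        raise ValueError("cannot sample more landmarks than cells")
    if len(landmark_idx) == 0:
        landmark_idx = np.array([0], dtype=np.intp)
    current = list(landmark_idx)
    min_dist = np.min(
        np.linalg.norm(coords[:, None, :] - coords[current][None, :, :], axis=2),
        axis=1,
    )
    while len(current) < n_required:
        pick = int(np.argmax(min_dist))
        current.append(pick)
        log.info("augment_landmarks: added cell %d", pick)
        min_dist = np.minimum(
            min_dist, np.linalg.norm(coords - coords[pick], axis=1)
        )
    return np.array(sorted(current), dtype=np.intp)


def landmark_isomap(
    pca: Embedding,
    landmark_idx,
    m: int = 10,
    d_out: int = 2,
) -> Embedding:
    """Convenience wrapper: graph, geodesics, landmark MDS, triangulation."""
    if d_out < 2:
        raise ValueError("d_out must be >= 2")
    landmark_idx = np.asarray(landmark_idx, dtype=np.intp)
    if len(landmark_idx) < d_out + 1:
        landmark_idx = augment_landmarks(pca.coords, landmark_idx, d_out + 1)
    graph = build_geodesic_graph(pca, m=m)
    gd = landmark_geodesics(graph, landmark_idx)
    coords, eigvals = landmark_mds(gd.landmark_block(), d_out=d_out)
    emb = embed_all(gd, coords, eigvals, cell_ids=pca.cell_ids)
    emb.meta.update({"m": m, "landmark_idx": landmark_idx.tolist()})
    return emb
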