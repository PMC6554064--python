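"""Cluster centers, MST, rooting, projection, pseudo-time, evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isotraj.containers import CellMetadata, Embedding
from isotraj.density import ClusterAssignment
from isotraj.trajectory import (
    assign_and_time,
    build_mst,
    cluster_centers,
    evaluate_spearman,
    project_cell,
    set_root,
)

from conftest import make_embedding


def prufer_min_spanning_weight(centers):
    """Brute-force minimum over all labelled spanning trees (Prüfer codes)."""
    c = len(centers)
    if c == 1:
        return 0.0
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    if c == 2:
        return d[0, 1]
    best = np.inf
    for code in itertools.product(range(c), repeat=c - 2):
        degree = np.ones(c, dtype=int)
        for v in code:
            degree[v] += 1
        code_list = list(code)
        leaves = sorted(i for i in range(c) if degree[i] == 1)
        weight = 0.0
        for v in code_list:
            leaf = leaves.pop(0)
            weight += d[leaf, v]
            degree[v] -= 1
            if degree[v] == 1:
                import bisect

                bisect.insort(leaves, v)
        weight += d[leaves[0], leaves[1]]
        best = min(best, weight)
    return best


def _clusters(labels):
    labels = np.asarray(labels)
    c = labels.max()
    peaks = np.array([np.flatnonzero(labels == i + 1)[0] for i in range(c)])
    return ClusterAssignment(labels=labels, peak_of_cluster=peaks, C=int(c))


class TestClusterCenters:
    def test_definitions(self, rng):
        coords = np.array([[0.0, 0], [2, 0], [5, 5], [1, 1], [3, 3]])
        iso = make_embedding(coords, space="isomap")
        clusters = _clusters([1, 1, 2, 2, 2])
        centers = cluster_centers(iso, clusters)
        np.testing.assert_allclose(centers[0], [1.0, 0.0])
        np.testing.assert_allclose(centers[1], [3.0, 3.0])

    def test_singleton_and_mean_exactness(self, rng):
        coords = rng.normal(size=(21, 2))
        iso = make_embedding(coords, space="isomap")
        clusters = _clusters([1] + [2] * 20)
        centers = cluster_centers(iso, clusters)
        np.testing.assert_array_equal(centers[0], coords[0])
        np.testing.assert_allclose(centers[1], coords[1:].mean(axis=0), atol=1e-12)


class TestMST:
    def test_single_center(self):
        tree = build_mst(np.array([[1.0, 2.0]]))
        assert tree.edges == []

    def test_three_collinear(self):
        tree = build_mst(np.array([[0.0, 0], [1, 0], [3, 0]]))
        assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2)]
        assert tree.total_weight == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(size=(7, 2))
        tree = build_mst(centers)
        assert len(tree.edges) == 6
        assert tree.total_weight == pytest.approx(
            prufer_min_spanning_weight(centers), abs=1e-10
        )

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(c=st.integers(2, 6), seed=st.integers(0, 10_000))
    def test_minimality_property(self, c, seed):
        centers = np.random.default_rng(seed).normal(size=(c, 2))
        tree = build_mst(centers)
        assert len(tree.edges) == c - 1
        assert tree.total_weight == pytest.approx(
            prufer_min_spanning_weight(centers), abs=1e-10
        )


class TestSetRoot:
    def test_unit_path(self):
        centers = np.array([[0.0, 0], [1, 0], [2, 0]])
        tree = set_root(build_mst(centers), root=0)
        np.testing.assert_allclose(tree.path_dist, [0.0, 1.0, 2.0])
        assert tree.root == 0
        # edges oriented root-nearer endpoint first, root-outward order
        assert [(i, j) for i, j, _ in tree.edges] == [(0, 1), (1, 2)]

    def test_star_rooted_at_leaf(self):
        # hub 0 with leaves at distances 2, 3, 4; root at the distance-2 leaf
        centers = np.array([[0.0, 0], [2, 0], [0, 3], [-4, 0]])
        tree = set_root(build_mst(centers), root=1)
        np.testing.assert_allclose(tree.path_dist, [2.0, 0.0, 5.0, 6.0])

    def test_auto_root_from_time_labels(self):
        coords = np.array([[0.0, 0]] * 3 + [[10.0, 0]] * 3)
        iso = make_embedding(coords, space="isomap")
        clusters = _clusters([1, 1, 1, 2, 2, 2])
        meta = CellMetadata(pd.DataFrame({
            "cell_id": iso.cell_ids,
            "time_label": [5.0, 5.0, 5.0, 1.0, 1.0, 5.0],
        }))
        tree = build_mst(cluster_centers(iso, clusters))
        rooted = set_root(tree, "auto", meta=meta, clusters=clusters,
                          cell_ids=iso.cell_ids)
        assert rooted.root == 1  # cluster 2 holds most earliest-time cells

    def test_auto_without_labels_errors(self):
        tree = build_mst(np.array([[0.0, 0], [1, 0]]))
        with pytest.raises(ValueError, match="auto"):
            set_root(tree, "auto")


class TestProjection:
    def test_point_at_near_endpoint(self):
        centers = np.array([[0.0, 0], [2, 0]])
        proj, off, res = project_cell(np.array([0.0, 0]), (0, 1, 2.0), centers)
        assert off == 0.0 and res == 0.0

    def test_interior_projection(self):
        centers = np.array([[0.0, 0], [2, 0]])
        proj, off, res = project_cell(np.array([1.0, 5.0]), (0, 1, 2.0), centers)
        np.testing.assert_allclose(proj, [1.0, 0.0])
        assert off == pytest.approx(1.0)
        assert res == pytest.approx(5.0)

    def test_clamped_past_far_endpoint(self):
        centers = np.array([[0.0, 0], [2, 0]])
        proj, off, res = project_cell(np.array([3.0, 1.0]), (0, 1, 2.0), centers)
        np.testing.assert_allclose(proj, [2.0, 0.0])
        assert off == pytest.approx(2.0)
        assert res == pytest.approx(np.sqrt(2.0))

    def test_zero_length_edge(self):
        centers = np.array([[1.0, 1], [1, 1]])
        proj, off, res = project_cell(np.array([4.0, 5.0]), (0, 1, 0.0), centers)
        np.testing.assert_allclose(proj, [1.0, 1.0])
        assert off == 0.0
        assert res == pytest.approx(5.0)


class TestAssignAndTime:
    def _path_tree(self):
        centers = np.array([[0.0, 0], [1, 0], [3, 0]])
        return set_root(build_mst(centers), root=0)

    def test_cell_at_root_has_zero_pseudotime(self):
        tree = self._path_tree()
        iso = make_embedding([[0.0, 0], [3, 0]], space="isomap")
        pt = assign_and_time(iso, tree)
        assert pt.pseudotime[0] == 0.0
        assert pt.pseudotime[1] == pytest.approx(3.0)

    def test_hand_geometry(self):
        tree = self._path_tree()
        iso = make_embedding([[2.0, 0.1]], space="isomap")
        pt = assign_and_time(iso, tree)
        assert pt.edge_assigned[0].tolist() == [1, 2]
        assert pt.pseudotime[0] == pytest.approx(2.0)  # path_dist(1)=1 + offset 1

    def test_cells_on_vertices(self):
        tree = self._path_tree()
        iso = make_embedding(tree.centers, space="isomap")
        pt = assign_and_time(iso, tree)
        np.testing.assert_allclose(pt.pseudotime, tree.path_dist, atol=1e-12)

    def test_pseudotime_bounded_by_edge_endpoints(self, rng):
        centers = rng.normal(size=(6, 2)) * 5
        tree = set_root(build_mst(centers), root=0)
        iso = make_embedding(rng.normal(size=(200, 2)) * 5, space="isomap")
        pt = assign_and_time(iso, tree)
        near = pt.edge_assigned[:, 0]
        far = pt.edge_assigned[:, 1]
        assert np.all(pt.pseudotime >= tree.path_dist[near] - 1e-12)
        assert np.all(pt.pseudotime <= tree.path_dist[far] + 1e-12)
        assert np.all(np.isfinite(pt.pseudotime))

    def test_rerooting_at_leaf_reverses_order(self, rng):
        centers = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        x = np.sort(rng.uniform(0, 3, size=50))
        iso = make_embedding(np.c_[x, np.zeros(50)], space="isomap")
        mst = build_mst(centers)
        fwd = assign_and_time(iso, set_root(mst, root=0)).pseudotime
        rev = assign_and_time(iso, set_root(mst, root=3)).pseudotime
        from scipy.stats import spearmanr

        rho, _ = spearmanr(fwd, rev)
        assert rho == pytest.approx(-1.0)

    def test_single_cluster_all_zero(self):
        tree = set_root(build_mst(np.array([[1.0, 1.0]])), root=0)
        iso = make_embedding([[0.0, 0], [5, 5]], space="isomap")
        pt = assign_and_time(iso, tree)
        np.testing.assert_array_equal(pt.pseudotime, [0.0, 0.0])


class TestSpearman:
    def _result(self, pseudotime):
        n = len(pseudotime)
        iso = make_embedding(np.zeros((n, 2)), space="isomap")
        tree = set_root(build_mst(np.array([[0.0, 0], [1, 0]])), root=0)
        pt = assign_and_time(iso, tree)
        pt.pseudotime = np.asarray(pseudotime, dtype=float)
        return pt

    def _meta(self, cell_ids, labels):
        return CellMetadata(pd.DataFrame({"cell_id": cell_ids,
                                          "time_label": labels}))

    def test_perfect_and_reversed(self):
        pt = self._result([1.0, 2.0, 3.0, 4.0])
        meta = self._meta(pt.cell_ids, [1, 2, 3, 4])
        assert evaluate_spearman(pt, meta) == pytest.approx(1.0)
        meta = self._meta(pt.cell_ids, [4, 3, 2, 1])
        assert evaluate_spearman(pt, meta) == pytest.approx(-1.0)

    def test_hand_rank_with_ties(self):
        # labels (1,1,2,3) have average ranks (1.5,1.5,3,4); pseudotime
        # (0.1,0.2,0.15,0.9) ranks (1,3,2,4); Pearson of ranks = 2/sqrt(10)
        pt = self._result([0.1, 0.2, 0.15, 0.9])
        meta = self._meta(pt.cell_ids, [1, 1, 2, 3])
        assert evaluate_spearman(pt, meta) == pytest.approx(0.6324555320336759)

    def test_constant_is_nan_with_warning(self):
        pt = self._result([2.0, 2.0, 2.0, 2.0])
        meta = self._meta(pt.cell_ids, [1, 2, 3, 4])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(evaluate_spearman(pt, meta))

    def test_too_few_labels(self):
        pt = self._result([1.0, 2.0, 3.0])
        meta = CellMetadata(pd.DataFrame({
            "cell_id": pt.cell_ids,
            "time_label": [1.0, np.nan, np.nan],
        }))
        with pytest.raises(ValueError, match="3 cells"):
            evaluate_spearman(pt, meta)
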