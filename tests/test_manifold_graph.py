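import numpy as np
import pytest
import scipy.sparse as sp

from comanifold import (
    DataBlock,
    FuzzySet,
    SpaceCoords,
    assemble_multigraph,
    cross_fuzzy_from_space,
    cross_fuzzy_from_table,
    fuzzy_set_from_space,
    knn_search,
    membership_strengths,
    smooth_knn_calibrate,
    symmetrize_union,
    write_multigraph,
)
from comanifold.data_model import CrossDistanceTable
from comanifold.manifold_graph import SmoothKnnParams, calibrate_smooth_knn

from .oracles import brute_fuzzy_graph, brute_knn, brute_sigma


def space_of(points, name="s"):
    return SpaceCoords((name,), {name: np.atleast_2d(points)})


class TestKnnSearch:
    def test_collinear_hand_geometry(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        res = knn_search(space_of(pts), k=2)
        # nearest neighbors: 0->1 (d=1), 1->0 (d=1), 2->1 (d=2)
        assert list(res.indices[:, 0]) == [1, 0, 1]
        np.testing.assert_allclose(res.distances[:, 0], [1.0, 1.0, 2.0])
        # with k=2 on 3 points each list is the other two, sorted
        assert sorted(res.indices[0]) == [1, 2]
        assert np.all(np.diff(res.distances, axis=1) >= 0)

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(50, 2))
        res = knn_search(space_of(pts), k=5)
        idx, dis = brute_knn(pts, 5)
        np.testing.assert_allclose(res.distances, dis, atol=1e-12)
        np.testing.assert_array_equal(res.indices, idx)

    def test_k_clipped_with_warning(self, rng, caplog):
        pts = rng.normal(size=(4, 2))
        res = knn_search(space_of(pts), k=10)
        assert res.k == 3

    def test_approximate_agrees_with_exact(self, rng):
        pts = rng.normal(size=(1500, 8))
        exact = knn_search(space_of(pts), k=10, exact=True)
        approx = knn_search(space_of(pts), k=10, exact=False, seed=0)
        same = [
            set(exact.indices[i]) == set(approx.indices[i]) for i in range(1500)
        ]
        assert np.mean(same) >= 0.95


class TestCalibration:
    def test_nearest_neighbor_membership_is_one(self, rng):
        d = np.sort(rng.random(10)) + 0.5
        rho, sigma = smooth_knn_calibrate(d)
        assert np.exp(-max(0.0, d[0] - rho) / sigma) == 1.0

    def test_scale_equivariance(self, rng):
        d = np.sort(rng.random(8)) + 0.2
        rho1, sig1 = smooth_knn_calibrate(d)
        rho2, sig2 = smooth_knn_calibrate(5.0 * d)
        assert rho2 == pytest.approx(5 * rho1, rel=1e-9)
        assert sig2 == pytest.approx(5 * sig1, rel=1e-6)
        np.testing.assert_allclose(
            np.exp(-np.maximum(0, d - rho1) / sig1),
            np.exp(-np.maximum(0, 5 * d - rho2) / sig2),
            atol=1e-8,
        )

    def test_bisection_against_independent_root_finder(self):
        d = [1.0, 2.0, 3.0, 4.0]
        rho, sigma = smooth_knn_calibrate(d, k=4)
        rho_o, sigma_o = brute_sigma(d)
        assert rho == rho_o
        assert sigma == pytest.approx(sigma_o, rel=1e-9)
        total = sum(np.exp(-max(0, x - rho) / sigma) for x in d)
        assert total == pytest.approx(2.0, abs=1e-5)  # log2(4)

    def test_constraint_holds_on_random_rows(self, rng):
        d = np.sort(rng.random((200, 15)) + 0.05, axis=1)
        rho, sigma = calibrate_smooth_knn(d)
        mass = np.exp(-np.maximum(0, d - rho[:, None]) / sigma[:, None]).sum(axis=1)
        np.testing.assert_allclose(mass, np.log2(15), atol=1e-5)

    def test_all_zero_distances_floored(self):
        rho, sigma = smooth_knn_calibrate([0.0, 0.0, 0.0])
        assert sigma > 0 and rho == 0.0


class TestMemberships:
    def test_formula_on_five_point_instance(self, rng):
        pts = rng.normal(size=(5, 3))
        neigh = knn_search(space_of(pts), k=3)
        rho, sigma = calibrate_smooth_knn(neigh.distances)
        params = SmoothKnnParams(rho, sigma, ("s",))
        directed = membership_strengths(neigh, params).toarray()
        for i in range(5):
            for c in range(3):
                j = neigh.indices[i, c]
                expected = np.exp(
                    -max(0.0, neigh.distances[i, c] - rho[i]) / sigma[i]
                )
                assert directed[i, j] == pytest.approx(expected, abs=1e-12)
        assert directed[np.arange(5), neigh.indices[:, 0]] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a,b,expected", [(0.5, 0.5, 0.75), (0.4, 0.0, 0.4), (1.0, 0.3, 1.0)]
    )
    def test_t_conorm_union(self, a, b, expected):
        m = sp.csr_matrix(np.array([[0.0, a], [b, 0.0]]))
        out = symmetrize_union(m).toarray()
        assert out[0, 1] == pytest.approx(expected)
        assert out[1, 0] == pytest.approx(expected)


class TestCrossFromTable:
    def test_single_pair_membership_one(self):
        table = CrossDistanceTable([("a", 0, "b", 0, 0.7)])
        fs = cross_fuzzy_from_table(table)
        assert fs.matrix.toarray()[0, 1] == pytest.approx(1.0)

    def test_ten_anchor_formula_oracle(self, rng):
        pos_a = rng.random(10)
        pos_b = rng.random(10)
        rows = [
            ("a", i, "b", j, abs(pos_a[i] - pos_b[j]))
            for i in range(10)
            for j in range(10)
        ]
        fs = cross_fuzzy_from_table(CrossDistanceTable(rows), k=5)
        mat = fs.matrix.toarray()
        pos = {p: i for i, p in enumerate(fs.index)}
        # directed strengths recomputed independently, then t-conorm union
        directed = np.zeros_like(mat)
        for i in range(10):
            dists = sorted((abs(pos_a[i] - pos_b[j]), j) for j in range(10))[:5]
            rho, sigma = brute_sigma([d for d, _ in dists])
            for d, j in dists:
                directed[pos[("a", i)], pos[("b", j)]] = np.exp(
                    -max(0.0, d - rho) / sigma
                )
        for j in range(10):
            dists = sorted((abs(pos_a[i] - pos_b[j]), i) for i in range(10))[:5]
            rho, sigma = brute_sigma([d for d, _ in dists])
            for d, i in dists:
                directed[pos[("b", j)], pos[("a", i)]] = np.exp(
                    -max(0.0, d - rho) / sigma
                )
        expected = directed + directed.T - directed * directed.T
        np.testing.assert_allclose(mat, expected, atol=1e-9)


class TestAssembly:
    def test_single_dataset_reduces_to_own_set(self, rng):
        pts = rng.normal(size=(25, 3))
        fs = fuzzy_set_from_space(space_of(pts, "only"))
        graph = assemble_multigraph({"only": 25}, {"only": fs})
        np.testing.assert_allclose(
            graph.matrix.toarray(), fs.matrix.toarray(), atol=1e-12
        )

    def test_no_shared_information_is_block_diagonal(self, rng, caplog):
        fa = fuzzy_set_from_space(space_of(rng.normal(size=(12, 2)), "a"))
        fb = fuzzy_set_from_space(space_of(rng.normal(size=(15, 2)), "b"))
        graph = assemble_multigraph({"a": 12, "b": 15}, {"a": fa, "b": fb})
        m = graph.matrix.toarray()
        assert np.all(m[:12, 12:] == 0)
        assert "block-disconnected" in caplog.text

    def test_duplicate_twin_datasets_link_strongly(self, rng):
        pts = rng.normal(size=(20, 6))
        a = DataBlock("a", pts, [f"f{i}" for i in range(6)])
        b = DataBlock("b", pts.copy(), [f"f{i}" for i in range(6)])
        shared = SpaceCoords(("a", "b"), {"a": pts, "b": pts.copy()})
        cs = cross_fuzzy_from_space(shared, k=5)
        fa = fuzzy_set_from_space(space_of(pts, "a"))
        fb = fuzzy_set_from_space(space_of(pts.copy(), "b"))
        graph = assemble_multigraph({"a": 20, "b": 20}, {"a": fa, "b": fb}, [cs])
        cross = graph.matrix.toarray()[:20, 20:]
        # each point's strongest cross edge is its duplicate, membership 1
        assert np.array_equal(cross.argmax(axis=1), np.arange(20))
        np.testing.assert_allclose(np.diag(cross), 1.0, atol=1e-12)

    def test_missing_own_set_raises(self, rng):
        fa = fuzzy_set_from_space(space_of(rng.normal(size=(5, 2)), "a"))
        with pytest.raises(ValueError, match="own-space"):
            assemble_multigraph({"a": 5, "b": 4}, {"a": fa})

    def test_symmetry_and_range_after_merges(self, rng):
        pts = rng.normal(size=(30, 4))
        a = pts[:15]
        b = pts[15:]
        fa = fuzzy_set_from_space(space_of(a, "a"), k=5)
        fb = fuzzy_set_from_space(space_of(b, "b"), k=5)
        shared = SpaceCoords(("a", "b"), {"a": a, "b": b})
        cs = cross_fuzzy_from_space(shared, k=5)
        table = CrossDistanceTable([("a", 0, "b", 0, 0.1), ("a", 1, "b", 2, 0.2)])
        ct = cross_fuzzy_from_table(table)
        graph = assemble_multigraph({"a": 15, "b": 15}, {"a": fa, "b": fb}, [cs], ct)
        m = graph.matrix
        assert (m != m.T).nnz == 0
        assert m.data.min() > 0 and m.data.max() <= 1 + 1e-12
        tags = graph.edge_tags()
        assert set(tags["space_tag"]) <= {"own:a", "own:b", "shared:a+b", "cross:table"}

    def test_within_dataset_edges_ignore_shared_spaces(self, rng):
        pts_a = rng.normal(size=(18, 4))
        pts_b = rng.normal(size=(18, 4)) + 0.5
        fa = fuzzy_set_from_space(space_of(pts_a, "a"), k=5)
        fb = fuzzy_set_from_space(space_of(pts_b, "b"), k=5)
        shared = SpaceCoords(("a", "b"), {"a": pts_a, "b": pts_b})
        cs = cross_fuzzy_from_space(shared, k=5)
        with_shared = assemble_multigraph(
            {"a": 18, "b": 18}, {"a": fa, "b": fb}, [cs]
        ).matrix.toarray()
        without = assemble_multigraph(
            {"a": 18, "b": 18}, {"a": fa, "b": fb}
        ).matrix.toarray()
        np.testing.assert_array_equal(with_shared[:18, :18], without[:18, :18])
        np.testing.assert_array_equal(with_shared[18:, 18:], without[18:, 18:])

    def test_graph_permutation_equivariance(self, rng):
        pts = rng.normal(size=(20, 3))
        perm = rng.permutation(20)
        g1 = assemble_multigraph(
            {"a": 20}, {"a": fuzzy_set_from_space(space_of(pts, "a"), k=4)}
        ).matrix.toarray()
        g2 = assemble_multigraph(
            {"a": 20}, {"a": fuzzy_set_from_space(space_of(pts[perm], "a"), k=4)}
        ).matrix.toarray()
        np.testing.assert_allclose(g2, g1[np.ix_(perm, perm)], atol=1e-12)


class TestPipelineProperties:
    def test_single_space_pipeline_equals_brute_force(self, rng):
        pts = rng.normal(size=(60, 4))
        fs = fuzzy_set_from_space(space_of(pts), k=6)
        expected = brute_fuzzy_graph(pts, k=6)
        np.testing.assert_allclose(fs.matrix.toarray(), expected, atol=1e-10)

    def test_fuzzy_set_scale_invariance(self, rng):
        pts = rng.normal(size=(40, 3))
        f1 = fuzzy_set_from_space(space_of(pts), k=5).matrix.toarray()
        f2 = fuzzy_set_from_space(space_of(pts * 37.5), k=5).matrix.toarray()
        np.testing.assert_allclose(f1, f2, atol=1e-8)


def test_multigraph_export_round_trip(tmp_path, rng):
    pts = rng.normal(size=(10, 2))
    graph = assemble_multigraph(
        {"a": 10}, {"a": fuzzy_set_from_space(space_of(pts, "a"), k=3)}
    )
    write_multigraph(graph, tmp_path, stem="g")
    from scipy.io import mmread

    back = sp.csr_matrix(mmread(tmp_path / "g.mtx"))
    np.testing.assert_allclose(back.toarray(), graph.matrix.toarray(), atol=1e-12)
    lines = (tmp_path / "g.index.tsv").read_text().splitlines()
    assert len(lines) == 10 and lines[0] == "a\t0"


class TestCalibrationProperties:
    """Property-based checks of the smooth-kNN normalization."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=4, max_size=20).map(sorted),
        st.floats(0.1, 50.0),
    )
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_mass_constraint_and_scale_equivariance(self, dists, scale):
        d = np.asarray(dists)
        if np.unique(d).size < d.size:  # ties can make the target unattainable
            return
        rho, sigma = smooth_knn_calibrate(d)
        mass = np.exp(-np.maximum(0.0, d - rho) / sigma).sum()
        assert mass == pytest.approx(np.log2(d.size), abs=1e-5)
        rho2, sigma2 = smooth_knn_calibrate(scale * d)
        np.testing.assert_allclose(
            np.exp(-np.maximum(0.0, d - rho) / sigma),
            np.exp(-np.maximum(0.0, scale * d - rho2) / sigma2),
            atol=1e-6,
        )

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_t_conorm_union_bounds(self, a, b):
        m = sp.csr_matrix(np.array([[0.0, a], [b, 0.0]]))
        out = symmetrize_union(m).toarray()[0, 1]
        assert out == pytest.approx(a + b - a * b, abs=1e-12)
        assert max(a, b) - 1e-12 <= out <= min(1.0, a + b) + 1e-12
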