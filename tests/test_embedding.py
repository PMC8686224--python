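import numpy as np
import pytest
import scipy.sparse as sp

from comanifold import (
    DataBlock,
    EmbeddingConfig,
    FuzzySet,
    assemble_multigraph,
    cross_entropy,
    fit_curve_params,
    fuzzy_set_from_space,
    integrate,
    optimize_embedding,
    spectral_init,
)
from comanifold.data_model import SpaceCoords
from comanifold.embedding import embedding_memberships, layout_graph

from .conftest import two_clique_graph


class TestCurveParams:
    def test_kernel_at_zero_and_monotone(self):
        a, b = fit_curve_params(0.5, 1.0)
        r = np.linspace(0, 5, 200)
        nu = 1.0 / (1.0 + a * r ** (2 * b))
        assert nu[0] == 1.0
        assert np.all(np.diff(nu) <= 0)

    def test_against_coarse_grid_search(self):
        """Independent grid search over (a, b) at min_dist=0.1, spread=1."""
        xv = np.linspace(0, 3, 300)
        yv = np.where(xv < 0.1, 1.0, np.exp(-(xv - 0.1) / 1.0))
        best, best_err = None, np.inf
        for a in np.linspace(0.5, 3.0, 120):
            for b in np.linspace(0.5, 2.0, 80):
                err = np.sum((1.0 / (1.0 + a * xv ** (2 * b)) - yv) ** 2)
                if err < best_err:
                    best, best_err = (a, b), err
        a, b = fit_curve_params(0.1, 1.0)
        assert a == pytest.approx(best[0], rel=0.05)
        assert b == pytest.approx(best[1], rel=0.05)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            fit_curve_params(0.0, 1.0)
        with pytest.raises(ValueError):
            fit_curve_params(2.0, 1.0)


class TestSpectralInit:
    def test_disconnected_cliques_get_disjoint_boxes(self):
        graph = two_clique_graph(bridge=0.0)
        coords = spectral_init(graph, 2, seed=0)
        a, b = coords[:10], coords[10:]
        disjoint_x = a[:, 0].max() < b[:, 0].min() or b[:, 0].max() < a[:, 0].min()
        assert disjoint_x

    def test_single_point_graph(self):
        coords = spectral_init(sp.csr_matrix((1, 1)), 2, seed=0)
        np.testing.assert_array_equal(coords, np.zeros((1, 2)))

    def test_deterministic_at_fixed_seed(self, rng):
        pts = rng.normal(size=(40, 3))
        fs = fuzzy_set_from_space(
            SpaceCoords(("a",), {"a": pts}), k=5
        )
        graph = assemble_multigraph({"a": 40}, {"a": fs})
        c1 = spectral_init(graph, 2, seed=3)
        c2 = spectral_init(graph, 2, seed=3)
        np.testing.assert_array_equal(c1, c2)


class TestCrossEntropy:
    def test_zero_at_equal_memberships(self):
        # the divergence form of the loss vanishes when nu matches mu
        assert cross_entropy([0.5], [0.5]) == pytest.approx(0.0, abs=1e-12)
        assert cross_entropy([0.2, 0.9], [0.2, 0.9]) == pytest.approx(0.0, abs=1e-9)

    def test_perfect_confident_edge_vanishes(self):
        assert cross_entropy([1.0], [1.0 - 1e-9]) == pytest.approx(0.0, abs=1e-6)

    def test_direct_formula_evaluation(self):
        expected = 0.9 * np.log(9) + 0.1 * np.log(1 / 9)
        assert cross_entropy([0.9], [0.1]) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.7578, abs=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy([0.5, 0.5], [0.5])


def single_edge_graph(mu=1.0):
    m = np.array([[0.0, mu], [mu, 0.0]])
    fs = FuzzySet(sp.csr_matrix(m), ("x",), [("x", 0), ("x", 1)])
    return assemble_multigraph({"x": 2}, {"x": fs})


class TestOptimize:
    def test_single_strong_edge_attracts(self):
        graph = single_edge_graph(1.0)
        init = np.array([[0.0, 0.0], [10.0, 0.0]])
        emb = optimize_embedding(
            graph, init, EmbeddingConfig(seed=0, n_epochs=50)
        )
        assert np.linalg.norm(emb.coords[0] - emb.coords[1]) < 10.0

    def test_two_cliques_with_weak_bridge_separate(self, clique_pair):
        init = spectral_init(clique_pair, 2, seed=0)
        emb = optimize_embedding(
            clique_pair, init, EmbeddingConfig(seed=0, n_epochs=200)
        )
        c = emb.coords
        intra = np.mean(
            [np.linalg.norm(c[i] - c[j]) for i in range(10) for j in range(i + 1, 10)]
        )
        inter = np.mean(
            [np.linalg.norm(c[i] - c[j]) for i in range(10) for j in range(10, 20)]
        )
        assert intra < inter

    def test_loss_non_increasing_over_epochs(self, clique_pair):
        """Average edge cross entropy at epochs {0, E/2, E} on two cliques,
        starting from a spread-out random configuration."""
        cfg = EmbeddingConfig(seed=0, n_epochs=200)
        init = np.random.default_rng(0).uniform(-20, 20, size=(20, 2))
        emb, snaps = optimize_embedding(
            clique_pair, init, cfg, snapshot_epochs=(0, 100)
        )
        a, b = cfg.resolved_curve()
        upper = sp.coo_matrix(sp.triu(clique_pair.matrix, k=1))
        def loss(coords):
            nu = embedding_memberships(coords, upper.row, upper.col, a, b)
            return cross_entropy(upper.data, np.clip(nu, 1e-12, 1 - 1e-12)) / len(upper.data)
        l0, lh, le = loss(snaps[0]), loss(snaps[100]), loss(emb.coords)
        assert lh <= l0 * 1.05
        assert le <= lh * 1.05

    def test_bitwise_determinism(self, clique_pair):
        init = spectral_init(clique_pair, 2, seed=1)
        e1 = optimize_embedding(clique_pair, init, EmbeddingConfig(seed=1, n_epochs=80))
        e2 = optimize_embedding(clique_pair, init, EmbeddingConfig(seed=1, n_epochs=80))
        np.testing.assert_array_equal(e1.coords, e2.coords)


class TestWeightSemantics:
    def _graph_pair(self, rng, randomize_a=False):
        """Two datasets with cross edges; optionally scramble a's own edges."""
        pts_a = rng.normal(size=(15, 3))
        pts_b = rng.normal(size=(15, 3))
        fa = fuzzy_set_from_space(SpaceCoords(("a",), {"a": pts_a}), k=4)
        fb = fuzzy_set_from_space(SpaceCoords(("b",), {"b": pts_b}), k=4)
        if randomize_a:
            scrambled = fa.matrix.copy()
            vals = np.random.default_rng(99).uniform(0.05, 1.0, size=scrambled.nnz)
            scrambled.data = vals
            scrambled = scrambled.maximum(scrambled.T)
            fa = FuzzySet(scrambled, ("a",), fa.index)
        from comanifold import cross_fuzzy_from_space

        shared = SpaceCoords(("a", "b"), {"a": pts_a, "b": pts_b})
        cs = cross_fuzzy_from_space(shared, k=4)
        return assemble_multigraph({"a": 15, "b": 15}, {"a": fa, "b": fb}, [cs])

    def test_zero_weight_makes_within_edges_irrelevant(self):
        cfg = EmbeddingConfig(
            seed=5, n_epochs=100, weights={"a": 0.0, "b": 1.0}
        )
        embs = []
        for randomize in (False, True):
            rng = np.random.default_rng(7)
            graph = self._graph_pair(rng, randomize_a=randomize)
            init = spectral_init(layout_graph(graph, cfg.weights), 2, seed=5)
            embs.append(optimize_embedding(graph, init, cfg).coords)
        np.testing.assert_array_equal(embs[0], embs[1])

    def test_nonzero_weight_is_sensitive_to_within_edges(self):
        cfg = EmbeddingConfig(seed=5, n_epochs=100)
        embs = []
        for randomize in (False, True):
            rng = np.random.default_rng(7)
            graph = self._graph_pair(rng, randomize_a=randomize)
            init = spectral_init(layout_graph(graph, cfg.weights), 2, seed=5)
            embs.append(optimize_embedding(graph, init, cfg).coords)
        assert not np.array_equal(embs[0], embs[1])


class TestIntegrate:
    def test_empty_block_list_raises(self):
        with pytest.raises(ValueError):
            integrate([])

    def test_single_block_graph_matches_single_space_pipeline(self, rng):
        block = DataBlock("solo", rng.normal(size=(30, 6)), [f"f{i}" for i in range(6)])
        cfg = EmbeddingConfig(seed=0, n_epochs=20)
        graph, emb = integrate([block], config=cfg, n_dims=4, k=5)
        from comanifold.data_model import reduce_dimension

        fs = fuzzy_set_from_space(reduce_dimension(block, 4, seed=0), k=5)
        np.testing.assert_allclose(
            graph.matrix.toarray(), fs.matrix.toarray(), atol=1e-12
        )
        assert emb.coords.shape == (30, 2)

    def test_duplicate_twin_blocks_land_together(self, rng):
        x = rng.normal(size=(40, 10))
        a = DataBlock("a", x, [f"f{i}" for i in range(10)])
        b = DataBlock("b", x.copy(), [f"f{i}" for i in range(10)])
        cfg = EmbeddingConfig(seed=2, n_epochs=300)
        graph, emb = integrate([a, b], config=cfg, n_dims=5, k=5)
        c = emb.coords
        twin = np.linalg.norm(c[:40] - c[40:], axis=1)
        all_pairs = np.linalg.norm(
            c[None, :, :] - c[:, None, :], axis=2
        )[np.triu_indices(80, k=1)]
        assert np.median(twin) < np.quantile(all_pairs, 0.05)

    def test_duplicate_dataset_ids_rejected(self, rng):
        a = DataBlock("x", rng.normal(size=(5, 3)), ["a", "b", "c"])
        b = DataBlock("x", rng.normal(size=(5, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="duplicate"):
            integrate([a, b])

    def test_stage_errors_are_labelled(self, rng):
        block = DataBlock("x", rng.normal(size=(12, 3)), ["a", "b", "c"])
        bad_own = {"x": SpaceCoords(("x",), {"x": rng.normal(size=(5, 2))})}
        with pytest.raises(RuntimeError, match="graph assembly"):
            integrate([block], own_spaces=bad_own, config=EmbeddingConfig(n_epochs=5))
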