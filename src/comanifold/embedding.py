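"""Joint low-dimensional layout of the cross-dataset neighborhood graph.

The embedding minimizes the fuzzy cross entropy between the graph's
membership function ``mu`` and the embedding-space membership function
``nu(r) = 1 / (1 + a * r^(2b))`` by stochastic gradient descent over
edges with negative sampling.  Each dataset carries a weight ``omega`` in
``[0, 1]`` that scales its terms in the loss: within-dataset edges use
the dataset's weight, cross-dataset edges the arithmetic mean of the two
weights.  Setting a dataset's weight to zero removes its within-dataset
edges from the layout entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import curve_fit
from scipy.sparse.csgraph import connected_components

from . import _layout
from .data_model import CrossDistanceTable, DataBlock, SpaceCoords, build_shared_space, reduce_dimension
from .manifold_graph import (
    DEFAULT_K,
    FuzzySet,
    MultiGraph,
    assemble_multigraph,
    cross_fuzzy_from_space,
    cross_fuzzy_from_table,
    fuzzy_set_from_space,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "Embedding",
    "fit_curve_params",
    "spectral_init",
    "cross_entropy",
    "embedding_memberships",
    "optimize_embedding",
    "integrate",
]

_NU_CLAMP = 1e-12


@dataclass
class EmbeddingConfig:
    """Layout hyperparameters.

    ``weights`` maps dataset ids to their influence ``omega`` on the loss
    (default: 1.0 for every dataset).  ``a``/``b`` parameterize the
    embedding-space membership curve and are fitted from
    ``min_dist``/``spread`` when left unset.  ``n_epochs`` defaults, for
    graphs up to 10,000 points, to 500 (one dataset) or 2000 (several
    datasets, whose mutual registration converges more slowly), and to
    200/400 above.  With
    ``scale_repulsion`` the dataset weight scales both the attractive and
    the repulsive updates of an edge; without it, attractive only.
    """

    n_components: int = 2
    weights: dict[str, float] | None = None
    min_dist: float = 0.5
    spread: float = 1.0
    a: float | None = None
    b: float | None = None
    n_epochs: int | None = None
    learning_rate: float = 1.0
    negative_sample_rate: int = 5
    repulsion_strength: float = 1.0
    scale_repulsion: bool = True
    repulsion_scope: str = "space"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_epochs is not None and self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0 < self.min_dist < self.spread + 1e-12:
            raise ValueError("need 0 < min_dist < spread")
        if self.weights is not None:
            for ds, w in self.weights.items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"weight of {ds!r} must be in [0, 1]")
        if (self.a is None) != (self.b is None):
            raise ValueError("set both or neither of a, b")
        if self.a is not None and (self.a <= 0 or self.b <= 0):
            raise ValueError("a and b must be positive")
        if self.repulsion_scope not in ("space", "global"):
            raise ValueError("repulsion_scope must be 'space' or 'global'")

    def resolved_curve(self) -> tuple[float, float]:
        if self.a is not None:
            return self.a, self.b
        return fit_curve_params(self.min_dist, self.spread)

    def resolved_epochs(self, n_points: int, n_datasets: int = 1) -> int:
        if self.n_epochs is not None:
            return self.n_epochs
        if n_datasets <= 1:
            return 500 if n_points <= 10_000 else 200
        # cross-dataset registration propagates through sparse cross edges
        # and converges noticeably more slowly than a single-space layout
        return 2000 if n_points <= 10_000 else 400


@dataclass
class Embedding:
    """N x d coordinates aligned to the graph's global point index."""

    coords: np.ndarray
    datasets: list[str]
    sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")
        if self.coords.shape[0] != sum(self.sizes.values()):
            raise ValueError("row count does not match the point index")

    def for_dataset(self, dataset_id: str) -> np.ndarray:
        start = 0
        for ds in self.datasets:
            if ds == dataset_id:
                return self.coords[start:start + self.sizes[ds]]
            start += self.sizes[ds]
        raise KeyError(dataset_id)

    @property
    def point_dataset(self) -> np.ndarray:
        return np.repeat(
            np.arange(len(self.datasets)), [self.sizes[d] for d in self.datasets]
        )


# ---------------------------------------------------------------------------
# membership curve
# ---------------------------------------------------------------------------


def fit_curve_params(min_dist: float, spread: float = 1.0) -> tuple[float, float]:
    """Fit ``(a, b)`` of ``nu(r) = 1/(1 + a r^(2b))`` to the piecewise target.

    The target is 1 for ``r <= min_dist`` and ``exp(-(r - min_dist)/spread)``
    beyond, evaluated on a fixed grid over ``[0, 3 * spread]``.
    """
    if not 0 < min_dist < spread + 1e-12:
        raise ValueError("need 0 < min_dist < spread")
    xv = np.linspace(0, spread * 3, 300)
    yv = np.where(xv < min_dist, 1.0, np.exp(-(xv - min_dist) / spread))

    def curve(x, a, b):
        return 1.0 / (1.0 + a * x ** (2.0 * b))

    try:
        params, _ = curve_fit(curve, xv, yv)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"membership curve fit failed to converge: {exc}") from exc
    a, b = float(params[0]), float(params[1])
    residual = float(np.sqrt(np.mean((curve(xv, a, b) - yv) ** 2)))
    if not (a > 0 and b > 0) or residual > 0.2:
        raise RuntimeError(
            f"membership curve fit did not converge (a={a:.3g}, b={b:.3g}, "
            f"rms residual={residual:.3g})"
        )
    return a, b


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _component_spectral(mat: sp.csr_matrix, d: int, seed: int) -> np.ndarray:
    """Spectral coordinates of one connected component."""
    from scipy.sparse.linalg import eigsh

    m = mat.shape[0]
    rng = np.random.default_rng(seed)
    if m <= d + 1:
        return rng.uniform(-1.0, 1.0, size=(m, d))
    deg = np.asarray(mat.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    norm = sp.diags(inv_sqrt) @ mat @ sp.diags(inv_sqrt)
    lap = sp.identity(m, format="csr") - norm
    k_eig = d + 1
    # shift-invert around 0 targets the smallest eigenpairs reliably;
    # plain which='SM' Lanczos can return unconverged vectors silently
    try:
        vals, vecs = eigsh(
            sp.csc_matrix(lap), k=k_eig, sigma=0.0, which="LM", v0=np.ones(m)
        )
    except Exception:
        try:
            vals, vecs = eigsh(
                lap,
                k=k_eig,
                which="SM",
                v0=np.ones(m),
                maxiter=max(50 * m, 5000),
                tol=0,
            )
        except Exception as exc:
            logger.warning("eigensolver failed (%s); falling back to random init", exc)
            return rng.uniform(-1.0, 1.0, size=(m, d))
    order = np.argsort(vals)
    coords = vecs[:, order[1:d + 1]]
    if coords.shape[1] < d:  # degenerate spectrum
        pad = rng.uniform(-1e-4, 1e-4, size=(m, d - coords.shape[1]))
        coords = np.hstack([coords, pad])
    return coords


def spectral_init(
    graph: MultiGraph | sp.spmatrix, d: int = 2, seed: int = 0
) -> np.ndarray:
    """Spectral layout of the graph for initializing the optimization.

    Coordinates come from the ``d`` nontrivial eigenvectors of the
    symmetric normalized Laplacian, rescaled so each connected component
    spans roughly ``[-5, 5]``; separate components are placed on a
    disjoint grid along the first axis so their bounding boxes do not
    overlap.  Deterministic for a fixed seed.
    """
    mat = graph.matrix if isinstance(graph, MultiGraph) else sp.csr_matrix(graph)
    n = mat.shape[0]
    if n == 1:
        return np.zeros((1, d))
    n_comp, labels = connected_components(mat, directed=False)
    coords = np.zeros((n, d))
    # deterministic component order: by size descending, then first index
    comp_order = sorted(
        range(n_comp),
        key=lambda c: (-int(np.sum(labels == c)), int(np.argmax(labels == c))),
    )
    # components are laid out along the first axis with gaps that scale
    # with component size: the optimizer expands each component roughly
    # like sqrt(n), and disconnected data must stay disconnected visually
    position = 0.0
    prev_halfwidth = 0.0
    for slot, c in enumerate(comp_order):
        idx = np.flatnonzero(labels == c)
        sub = sp.csr_matrix(mat[idx][:, idx])
        local = _component_spectral(sub, d, seed + slot)
        span = np.abs(local).max()
        if span > 0:
            local = local * (5.0 / span)
        halfwidth = 5.0 + 3.0 * np.sqrt(idx.size)
        if slot > 0:
            position += prev_halfwidth + halfwidth + 10.0
        prev_halfwidth = halfwidth
        offset = np.zeros(d)
        offset[0] = position
        coords[idx] = local + offset
    rng = np.random.default_rng(seed)
    coords = coords + rng.normal(scale=1e-4, size=coords.shape)
    return coords


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def cross_entropy(mu_edges: np.ndarray, nu_edges: np.ndarray) -> float:
    """Fuzzy-set cross entropy summed over paired edge lists (natural log)."""
    mu = np.asarray(mu_edges, dtype=np.float64)
    nu = np.asarray(nu_edges, dtype=np.float64)
    if mu.shape != nu.shape:
        raise ValueError("mu and nu edge lists must have the same length")
    nu = np.clip(nu, _NU_CLAMP, 1.0 - _NU_CLAMP)
    attract = np.where(mu > 0, mu * np.log(np.maximum(mu, _NU_CLAMP) / nu), 0.0)
    repel = np.where(
        mu < 1,
        (1.0 - mu) * np.log(np.maximum(1.0 - mu, _NU_CLAMP) / (1.0 - nu)),
        0.0,
    )
    return float(np.sum(attract + repel))


def embedding_memberships(
    coords: np.ndarray, rows: np.ndarray, cols: np.ndarray, a: float, b: float
) -> np.ndarray:
    """Low-dimensional memberships ``nu = 1/(1 + a r^(2b))`` for given pairs."""
    diff = coords[rows] - coords[cols]
    dist2 = np.einsum("ij,ij->i", diff, diff)
    return 1.0 / (1.0 + a * dist2 ** b)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def _edge_weights(
    graph: MultiGraph,
    weights: Mapping[str, float] | None,
    directed: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Edges of the graph with per-edge dataset weights.

    ``directed=True`` yields every nonzero of the symmetric matrix (each
    undirected edge twice, once per head), which is what the sampling
    optimizer consumes so that every point receives repulsive updates.
    """
    if directed:
        upper = sp.coo_matrix(graph.matrix)
        mask = upper.row != upper.col
        upper = sp.coo_matrix(
            (upper.data[mask], (upper.row[mask], upper.col[mask])),
            shape=graph.matrix.shape,
        )
    else:
        upper = sp.coo_matrix(sp.triu(graph.matrix, k=1))
    omega = {ds: 1.0 for ds in graph.datasets}
    if weights:
        unknown = set(weights) - set(omega)
        if unknown:
            raise ValueError(f"weights given for unknown datasets {sorted(unknown)}")
        omega.update(weights)
    per_point = np.array(
        [omega[graph.datasets[c]] for c in graph.point_dataset]
    )
    w = 0.5 * (per_point[upper.row] + per_point[upper.col])
    return upper.row.astype(np.int64), upper.col.astype(np.int64), upper.data, w


def layout_graph(graph: MultiGraph, weights: Mapping[str, float] | None) -> sp.csr_matrix:
    """Graph with zero-weight edges removed; used for the spectral init."""
    rows, cols, mu, w = _edge_weights(graph, weights)
    keep = w > 0
    upper = sp.csr_matrix(
        (mu[keep], (rows[keep], cols[keep])),
        shape=graph.matrix.shape,
    )
    return upper + upper.T


def optimize_embedding(
    graph: MultiGraph,
    init: np.ndarray | Embedding,
    config: EmbeddingConfig | None = None,
    snapshot_epochs: Sequence[int] = (),
) -> Embedding | tuple[Embedding, dict[int, np.ndarray]]:
    """Stochastic gradient layout of the graph from a given initialization.

    Edges are sampled proportionally to their membership ``mu``; each
    sampled edge receives an attractive update and
    ``negative_sample_rate`` repulsive updates against uniformly sampled
    points, all scaled by the edge's dataset weight and a linearly
    decaying learning rate.  Deterministic for a fixed seed (the kernel is
    single-threaded).  If ``snapshot_epochs`` is given, copies of the
    coordinates at those epochs are returned alongside the result.
    """
    config = config or EmbeddingConfig()
    coords = init.coords if isinstance(init, Embedding) else np.asarray(init)
    if coords.shape[0] != graph.n_points:
        raise ValueError(
            f"init has {coords.shape[0]} rows for a graph of {graph.n_points} points"
        )
    if coords.shape[1] != config.n_components:
        raise ValueError("init dimensionality does not match n_components")
    a, b = config.resolved_curve()
    n_epochs = config.resolved_epochs(graph.n_points, len(graph.datasets))

    rows, cols, mu, w = _edge_weights(graph, config.weights, directed=True)
    keep = w > 0
    rows, cols, mu, w = rows[keep], cols[keep], mu[keep], w[keep]
    if rows.size == 0:
        logger.warning("layout graph has no edges; returning the initialization")
        return _finish(coords, graph, snapshot_epochs, {})
    mu_max = mu.max()
    keep = mu >= mu_max / n_epochs
    rows, cols, mu, w = rows[keep], cols[keep], mu[keep], w[keep]

    epochs_per_sample = (mu_max / mu).astype(np.float64)
    emb = np.ascontiguousarray(coords, dtype=np.float32)
    attract_w = w.astype(np.float32)
    repulse_w = attract_w if config.scale_repulsion else np.ones_like(attract_w)
    # negative-sampling pools: per-space (the union of the edge's endpoint
    # datasets) or the whole point set
    n_total = graph.n_points
    if config.repulsion_scope == "global":
        pool1_start = np.zeros(rows.size, dtype=np.int64)
        pool1_len = np.full(rows.size, n_total, dtype=np.int64)
        pool2_start = np.zeros(rows.size, dtype=np.int64)
        pool2_len = np.zeros(rows.size, dtype=np.int64)
    else:
        offsets = graph.offsets
        starts = np.array([offsets[ds] for ds in graph.datasets], dtype=np.int64)
        lens = np.array([graph.sizes[ds] for ds in graph.datasets], dtype=np.int64)
        codes = graph.point_dataset
        head_ds = codes[rows]
        tail_ds = codes[cols]
        pool1_start = starts[head_ds]
        pool1_len = lens[head_ds]
        is_cross = head_ds != tail_ds
        pool2_start = np.where(is_cross, starts[tail_ds], 0).astype(np.int64)
        pool2_len = np.where(is_cross, lens[tail_ds], 0).astype(np.int64)
    eons = epochs_per_sample.copy()
    eonn = epochs_per_sample / config.negative_sample_rate
    rng_state = np.array(
        [np.uint64(config.seed * 2654435761 + 0x9E3779B97F4A7C15) | np.uint64(1)],
        dtype=np.uint64,
    )
    snapshots: dict[int, np.ndarray] = {}
    marks = sorted({int(e) for e in snapshot_epochs if 0 <= int(e) <= n_epochs})
    prev = 0
    for mark in marks + [n_epochs]:
        if mark > prev:
            _layout.optimize_epochs(
                emb, rows, cols, attract_w, repulse_w,
                pool1_start, pool1_len, pool2_start, pool2_len,
                epochs_per_sample, eons, eonn,
                prev, mark, n_epochs,
                a, b, config.repulsion_strength,
                config.learning_rate, config.negative_sample_rate,
                rng_state,
            )
            prev = mark
        if mark < n_epochs or mark in {int(e) for e in snapshot_epochs}:
            snapshots[mark] = emb.astype(np.float64).copy()
    return _finish(emb, graph, snapshot_epochs, snapshots)


def _finish(coords, graph, snapshot_epochs, snapshots):
    result = Embedding(
        np.asarray(coords, dtype=np.float64), list(graph.datasets), dict(graph.sizes)
    )
    if snapshot_epochs:
        return result, snapshots
    return result


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------


def integrate(
    blocks: Sequence[DataBlock],
    shared: Sequence[SpaceCoords] | None = None,
    cross: CrossDistanceTable | None = None,
    config: EmbeddingConfig | None = None,
    own_spaces: Mapping[str, SpaceCoords] | None = None,
    n_dims: int = 50,
    k: int = DEFAULT_K,
    exact_knn: bool | None = None,
    reduce_method: str = "pca",
) -> tuple[MultiGraph, Embedding]:
    """Full pipeline: ambient spaces -> MultiGraph -> joint embedding.

    Per dataset, its own ambient space is its matrix reduced to
    ``min(n_dims, rank)`` dimensions (or a pre-reduced space passed via
    ``own_spaces``).  Unless ``shared`` is supplied, a shared feature
    space is built for every pair of datasets with overlapping feature
    names.  ``cross`` optionally supplies explicit anchor distances.
    Dataset weights come from ``config.weights`` (falling back to each
    block's own ``weight`` attribute).
    """
    if not blocks:
        raise ValueError("integrate: at least one DataBlock is required")
    ids = [b.dataset_id for b in blocks]
    if len(set(ids)) != len(ids):
        raise ValueError("integrate: duplicate dataset ids")
    config = config or EmbeddingConfig()
    if config.weights is None:
        config = replace(config, weights={b.dataset_id: b.weight for b in blocks})
    seed = config.seed

    # stage: own ambient spaces
    spaces: dict[str, SpaceCoords] = {}
    for block in blocks:
        try:
            if own_spaces and block.dataset_id in own_spaces:
                spaces[block.dataset_id] = own_spaces[block.dataset_id]
            else:
                d = min(n_dims, block.n_points, block.n_features)
                spaces[block.dataset_id] = reduce_dimension(
                    block, d, method=reduce_method, seed=seed
                )
        except Exception as exc:
            raise RuntimeError(
                f"own-space reduction failed for {block.dataset_id!r}: {exc}"
            ) from exc

    # stage: shared feature spaces
    if shared is None:
        shared = []
        for i, bi in enumerate(blocks):
            for bj in blocks[i + 1:]:
                if set(bi.feature_names) & set(bj.feature_names):
                    shared.append(build_shared_space(bi, bj, d=n_dims, seed=seed))

    # stage: fuzzy sets and graph assembly
    try:
        own_sets = {
            ds: fuzzy_set_from_space(spaces[ds], k=k, exact=exact_knn, seed=seed)
            for ds in ids
        }
        shared_sets = [
            cross_fuzzy_from_space(space, k=k, exact=exact_knn, seed=seed)
            for space in shared
        ]
        cross_set = cross_fuzzy_from_table(cross, k=k) if cross is not None else None
        graph = assemble_multigraph(
            {b.dataset_id: b.n_points for b in blocks},
            own_sets,
            shared_sets,
            cross_set,
        )
    except Exception as exc:
        raise RuntimeError(f"graph assembly failed: {exc}") from exc

    # stage: layout
    try:
        init = spectral_init(
            layout_graph(graph, config.weights), config.n_components, seed
        )
        emb = optimize_embedding(graph, init, config)
    except Exception as exc:
        raise RuntimeError(f"embedding optimization failed: {exc}") from exc
    return graph, emb
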