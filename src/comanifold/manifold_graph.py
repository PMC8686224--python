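"""Manifold-distance normalization and cross-dataset graph assembly.

Within every ambient space (a dataset's own reduced space, a shared
feature space, or a user-supplied cross-distance table) raw distances are
normalized per point by a local connectivity radius ``rho`` (distance to
the nearest neighbor) and a bandwidth ``sigma`` calibrated so that the
total membership mass of each point's neighborhood equals ``log2(k)``.
The calibrated pair realizes a constant-radius ball on the latent
manifold: memberships ``exp(-max(0, d - rho) / sigma)`` are comparable
across spaces of different scale and dimensionality.

Directed memberships are symmetrized with the probabilistic t-conorm
``a + b - a*b`` and the per-space fuzzy sets are merged into a single
symmetric neighborhood graph over all points of all datasets (the
*MultiGraph*): within-dataset edges come from each dataset's own space,
cross-dataset edges from shared feature spaces and/or explicit
cross-distance anchors, with duplicate edges merged by the same t-conorm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .data_model import CrossDistanceTable, SpaceCoords

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_K",
    "NeighborLists",
    "SmoothKnnParams",
    "FuzzySet",
    "MultiGraph",
    "knn_search",
    "smooth_knn_calibrate",
    "calibrate_smooth_knn",
    "membership_strengths",
    "symmetrize_union",
    "fuzzy_set_from_space",
    "cross_fuzzy_from_space",
    "cross_fuzzy_from_table",
    "assemble_multigraph",
    "write_multigraph",
]

#: Default neighborhood size for own and shared spaces.
DEFAULT_K = 15

#: Points per space above which approximate kNN is used by default.
APPROX_KNN_THRESHOLD = 5000

_SIGMA_FLOOR = 1.0
_CALIBRATION_TOL = 1e-5
_BISECTION_ITER = 64


@dataclass
class NeighborLists:
    """k nearest neighbors per point of one space, self excluded."""

    indices: np.ndarray  # (n, k) int
    distances: np.ndarray  # (n, k) float, sorted ascending per row
    space_id: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices/distances shape mismatch")
        if np.any(np.diff(self.distances, axis=1) < -1e-12):
            raise ValueError("neighbor distances must be sorted ascending")

    @property
    def k(self) -> int:
        return self.indices.shape[1]


@dataclass
class SmoothKnnParams:
    """Per-point local connectivity radius and bandwidth of one space."""

    rho: np.ndarray  # (n,)
    sigma: np.ndarray  # (n,) strictly positive
    space_id: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if np.any(self.rho < 0):
            raise ValueError("rho must be non-negative")


@dataclass
class FuzzySet:
    """Symmetric fuzzy simplicial set over the points of one space.

    ``index`` names each row/column of ``matrix`` as a
    ``(dataset_id, local_index)`` pair so cross-space sets can be mapped
    into the global point index at assembly time.
    """

    matrix: sp.csr_matrix  # symmetric, zero diagonal, values in (0, 1]
    space_id: tuple[str, ...]
    index: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("fuzzy set matrix must be square")
        if len(self.index) != self.matrix.shape[0]:
            raise ValueError("index length must match matrix size")
        if self.matrix.nnz:
            if (self.matrix != self.matrix.T).nnz:
                raise ValueError("fuzzy set matrix must be symmetric")
            if self.matrix.data.min() <= 0 or self.matrix.data.max() > 1 + 1e-12:
                raise ValueError("memberships must lie in (0, 1]")


@dataclass
class MultiGraph:
    """The single cross-dataset neighborhood graph.

    The global point index is the concatenation of the datasets in the
    user-supplied order; ``point_dataset[i]`` is the dataset code of global
    point ``i`` and ``point_local[i]`` its row in that dataset.  Edge
    provenance is kept for the upper triangle as parallel arrays of
    ``(row, col, tag)``.
    """

    matrix: sp.csr_matrix
    datasets: list[str]
    sizes: dict[str, int]
    tag_names: list[str] = field(default_factory=list)
    tag_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    tag_cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    tag_codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    @property
    def offsets(self) -> dict[str, int]:
        out, acc = {}, 0
        for ds in self.datasets:
            out[ds] = acc
            acc += self.sizes[ds]
        return out

    @property
    def point_dataset(self) -> np.ndarray:
        return np.repeat(
            np.arange(len(self.datasets)), [self.sizes[d] for d in self.datasets]
        )

    @property
    def point_local(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(self.sizes[d]) for d in self.datasets]
        )

    def global_index(self) -> list[tuple[str, int]]:
        return [
            (ds, i) for ds in self.datasets for i in range(self.sizes[ds])
        ]

    def edge_tags(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": self.tag_rows,
                "col": self.tag_cols,
                "space_tag": [self.tag_names[c] for c in self.tag_codes],
            }
        )


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------


def _space_points(space: SpaceCoords | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(space, SpaceCoords):
        pts, _ = space.stacked()
        return pts, space.space_id
    pts = np.asarray(space, dtype=np.float64)
    return pts, ("",)


def knn_search(
    space: SpaceCoords | np.ndarray,
    k: int = DEFAULT_K,
    metric: str = "euclidean",
    exact: bool | None = None,
    seed: int = 0,
) -> NeighborLists:
    """k nearest neighbors of every point of a space, self excluded.

    ``exact=None`` picks brute force below :data:`APPROX_KNN_THRESHOLD`
    points and NN-descent above it; pass ``True``/``False`` to force a
    mode.  Euclidean is the only supported metric (all ambient spaces are
    PCA/SVD component scores).
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    pts, space_id = _space_points(space)
    n = pts.shape[0]
    if k >= n:
        logger.warning("k=%d >= n=%d points; clipping k to %d", k, n, n - 1)
        k = n - 1
    if exact is None:
        exact = n <= APPROX_KNN_THRESHOLD
    if exact:
        nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean")
        nn.fit(pts)
        dist, idx = nn.kneighbors(pts)
    else:
        from pynndescent import NNDescent

        # build with a wider internal neighborhood than requested: NN-descent
        # recall improves markedly and the surplus is discarded
        index = NNDescent(
            pts,
            n_neighbors=max(k + 1, 30),
            metric="euclidean",
            random_state=seed,
            n_jobs=1,
        )
        idx, dist = index.neighbor_graph
        idx, dist = idx[:, : k + 1], dist[:, : k + 1]
    # remove self per row (usually column 0; with duplicate points it may
    # appear later or, for approximate search, not at all)
    rows = np.arange(n)
    keep_idx = np.empty((n, k), dtype=np.int64)
    keep_dist = np.empty((n, k), dtype=np.float64)
    for i in rows:
        mask = idx[i] != i
        sel = np.flatnonzero(mask)[:k]
        if sel.size < k:  # self never returned: take first k
            sel = np.arange(k)
        keep_idx[i] = idx[i, sel]
        keep_dist[i] = dist[i, sel]
    return NeighborLists(keep_idx, keep_dist, space_id)


# ---------------------------------------------------------------------------
# smooth-kNN calibration
# ---------------------------------------------------------------------------


def calibrate_smooth_knn(
    distances: np.ndarray, counts: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row calibration of ``(rho, sigma)``.

    ``distances`` is ``(n, k)`` sorted ascending per row; rows with fewer
    valid entries than ``k`` can be flagged via ``counts`` (invalid tail
    entries are ignored).  For each row ``rho`` is the distance to the
    nearest neighbor, and ``sigma`` solves

        sum_j exp(-max(0, d_j - rho) / sigma) = log2(count)

    by bisection on ``(1e-8 * mean_d, 1e3 * mean_d]``.  Rows whose
    distances are all zero get the fixed bandwidth floor ``1.0`` (their
    memberships are 1 regardless of sigma).
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2:
        raise ValueError("distances must be 2-D (points x neighbors)")
    n, k = d.shape
    if counts is None:
        counts = np.full(n, k, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    valid = np.arange(k)[None, :] < counts[:, None]
    rho = d[:, 0].copy()
    adj = np.maximum(0.0, d - rho[:, None])
    adj[~valid] = 0.0
    with np.errstate(invalid="ignore"):
        mean_d = np.where(counts > 0, d.sum(axis=1, where=valid) / np.maximum(counts, 1), 0.0)
    target = np.log2(np.maximum(counts, 1)).astype(np.float64)
    degenerate = mean_d <= 0
    mean_safe = np.where(degenerate, 1.0, mean_d)
    lo = 1e-8 * mean_safe
    hi = 1e3 * mean_safe
    sigma = np.empty(n)
    for _ in range(_BISECTION_ITER):
        mid = 0.5 * (lo + hi)
        s = np.exp(-adj / mid[:, None])
        s[~valid] = 0.0
        total = s.sum(axis=1)
        too_big = total > target
        hi = np.where(too_big, mid, hi)
        lo = np.where(too_big, lo, mid)
    sigma = 0.5 * (lo + hi)
    if degenerate.any():
        logger.warning(
            "%d rows have all-zero neighbor distances; sigma floored at %g",
            int(degenerate.sum()), _SIGMA_FLOOR,
        )
        sigma[degenerate] = _SIGMA_FLOOR
    return rho, sigma


def smooth_knn_calibrate(distances: Sequence[float], k: int | None = None) -> tuple[float, float]:
    """Calibrate ``(rho, sigma)`` for a single sorted neighbor-distance row."""
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a 1-D row of at least 2 sorted distances")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted ascending")
    if k is None:
        k = d.size
    rho, sigma = calibrate_smooth_knn(d[None, :k])
    return float(rho[0]), float(sigma[0])


def membership_strengths(
    neighbors: NeighborLists, params: SmoothKnnParams
) -> sp.csr_matrix:
    """Directed memberships ``exp(-max(0, d - rho_p) / sigma_p)`` as sparse."""
    n, k = neighbors.indices.shape
    if params.rho.shape[0] != n:
        raise ValueError("params were not calibrated on these neighbor lists")
    vals = np.exp(
        -np.maximum(0.0, neighbors.distances - params.rho[:, None])
        / params.sigma[:, None]
    )
    rows = np.repeat(np.arange(n), k)
    mat = sp.csr_matrix(
        (vals.ravel(), (rows, neighbors.indices.ravel())), shape=(n, n)
    )
    mat.setdiag(0.0)
    mat.eliminate_zeros()
    return mat


def symmetrize_union(directed: sp.spmatrix) -> sp.csr_matrix:
    """Probabilistic t-conorm union ``a + b - a*b`` of directed strengths."""
    a = sp.csr_matrix(directed)
    if a.shape[0] != a.shape[1]:
        raise ValueError("membership matrix must be square")
    sym = a + a.T - a.multiply(a.T)
    sym = sp.csr_matrix(sym)
    sym.data = np.clip(sym.data, 0.0, 1.0)
    sym.eliminate_zeros()
    return sym


def fuzzy_set_from_space(
    space: SpaceCoords,
    k: int = DEFAULT_K,
    exact: bool | None = None,
    seed: int = 0,
) -> FuzzySet:
    """Own-space fuzzy simplicial set: kNN, calibration, strengths, union."""
    neigh = knn_search(space, k=k, exact=exact, seed=seed)
    rho, sigma = calibrate_smooth_knn(neigh.distances)
    params = SmoothKnnParams(rho, sigma, space.space_id)
    directed = membership_strengths(neigh, params)
    _, index = space.stacked()
    return FuzzySet(symmetrize_union(directed), space.space_id, index)


def _ball_damping(
    nearest: np.ndarray,
    own_points: np.ndarray,
    quantile: float = 0.05,
    slack: float = 2.0,
    smooth_k: int = 15,
) -> np.ndarray:
    """Per-query gating of cross memberships at the shared-space scale.

    The neighborhood radius of the shared space is a constant-radius ball
    on the manifold: its scale ``r0`` is estimated as the ``quantile`` of
    the nearest cross-dataset distances over all query points of one
    search direction (the best-matched points).  A query whose nearest
    other-dataset point lies beyond ``slack * r0`` has no true counterpart
    there.  The in-ball indicator is then smoothed by a majority vote over
    each query's own-dataset neighborhood (``smooth_k`` nearest same-
    dataset points in the shared space), so whole populations that are
    present in only one dataset are cut away coherently — borderline
    points follow their region — instead of being falsely anchored to the
    other dataset.  Directions whose distances are all on one scale
    (everything matched, or uniformly noisy) are left untouched.
    """
    r0 = float(np.quantile(nearest, quantile))
    if r0 <= 0:
        return np.ones_like(nearest)
    in_ball = (nearest <= slack * r0).astype(np.float64)
    if in_ball.all() or own_points.shape[0] <= 2:
        return in_ball
    kk = min(smooth_k + 1, own_points.shape[0])
    nn = NearestNeighbors(n_neighbors=kk, algorithm="brute", metric="euclidean")
    nn.fit(own_points)
    _, idx = nn.kneighbors(own_points)  # includes self
    votes = in_ball[idx].mean(axis=1)
    return (votes > 0.5).astype(np.float64)


def cross_fuzzy_from_space(
    space: SpaceCoords,
    k: int = DEFAULT_K,
    exact: bool | None = None,
    seed: int = 0,
    calibration: str = "ball",
) -> FuzzySet:
    """Cross-dataset fuzzy set within a shared feature space.

    For each point, its k nearest neighbors among the points of the *other*
    datasets in the space are calibrated per point exactly as within-space
    edges and converted to memberships
    ``exp(-max(0, d - rho) / sigma)``; same-dataset pairs inside a shared
    space are discarded (own-space geometry already covers them).

    With ``calibration="ball"`` (default) each query point's memberships
    are additionally damped by :func:`_ball_damping` at the shared space's
    own scale, so populations without a counterpart in the other dataset
    are not forcibly attached to it; ``calibration="point"`` keeps the
    plain per-point calibration.
    """
    if len(space.space_id) < 2:
        raise ValueError("cross memberships need a space covering >= 2 datasets")
    if calibration not in ("ball", "point"):
        raise ValueError("calibration must be 'ball' or 'point'")
    pts, index = space.stacked()
    ds_of = np.array([ds for ds, _ in index])
    n = pts.shape[0]
    searches = []
    gate = np.ones(n)
    for ds in space.space_id:
        own = np.flatnonzero(ds_of == ds)
        other = np.flatnonzero(ds_of != ds)
        kk = min(k, other.size)
        if kk < 1:
            continue
        nn = NearestNeighbors(n_neighbors=kk, algorithm="brute", metric="euclidean")
        nn.fit(pts[other])
        dist, idx = nn.kneighbors(pts[own])
        searches.append((own, other, dist, idx))
        if calibration == "ball":
            gate[own] = _ball_damping(dist[:, 0], pts[own])
    rows_all, cols_all, vals_all = [], [], []
    for own, other, dist, idx in searches:
        rho, sigma = calibrate_smooth_knn(dist)
        vals = np.exp(-np.maximum(0.0, dist - rho[:, None]) / sigma[:, None])
        # an edge is credible only if *both* endpoints lie inside the
        # shared space's matched-scale ball of the other dataset
        vals = vals * gate[own][:, None] * gate[other[idx]]
        rows_all.append(np.repeat(own, dist.shape[1]))
        cols_all.append(other[idx.ravel()])
        vals_all.append(vals.ravel())
    directed = sp.csr_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n),
    )
    return FuzzySet(symmetrize_union(directed), space.space_id, index)


def cross_fuzzy_from_table(
    table: CrossDistanceTable, k: int = DEFAULT_K
) -> FuzzySet:
    """Cross-dataset fuzzy set from explicitly supplied distances.

    Each anchored point's cross distances are calibrated with
    ``k = min(k, available)`` and converted to memberships exactly as
    within-space edges; points absent from the table are simply
    unanchored.
    """
    df = table.pairs
    # duplex view: every entry seen from both endpoints
    fwd = df.rename(columns={"dataset_a": "ds_p", "index_a": "ix_p",
                             "dataset_b": "ds_q", "index_b": "ix_q"})
    rev = df.rename(columns={"dataset_b": "ds_p", "index_b": "ix_p",
                             "dataset_a": "ds_q", "index_a": "ix_q"})
    dup = pd.concat([fwd, rev], ignore_index=True)
    points = sorted(
        set(zip(dup["ds_p"], dup["ix_p"])) | set(zip(dup["ds_q"], dup["ix_q"]))
    )
    pos = {p: i for i, p in enumerate(points)}
    n = len(points)
    rows, cols, vals = [], [], []
    for (ds_p, ix_p), grp in dup.groupby(["ds_p", "ix_p"], sort=True):
        grp = grp.sort_values("distance", kind="mergesort").head(k)
        d = grp["distance"].to_numpy(dtype=np.float64)
        if d.size == 1:
            strengths = np.array([1.0])  # the single neighbor sits at rho
        else:
            rho, sigma = calibrate_smooth_knn(d[None, :])
            strengths = np.exp(-np.maximum(0.0, d - rho[0]) / sigma[0])
        p = pos[(ds_p, ix_p)]
        for (ds_q, ix_q), s in zip(zip(grp["ds_q"], grp["ix_q"]), strengths):
            rows.append(p)
            cols.append(pos[(ds_q, ix_q)])
            vals.append(s)
    directed = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    space_id = tuple(sorted(set(dup["ds_p"])))
    return FuzzySet(symmetrize_union(directed), space_id, list(points))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _to_global_triplets(
    fset: FuzzySet, offsets: Mapping[str, int], cross_only: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coo = sp.coo_matrix(sp.triu(fset.matrix, k=0))
    idx_ds = np.array([ds for ds, _ in fset.index])
    idx_loc = np.array([loc for _, loc in fset.index], dtype=np.int64)
    for ds in np.unique(idx_ds):
        if ds not in offsets:
            raise ValueError(f"fuzzy set references unknown dataset {ds!r}")
    off = np.array([offsets[ds] for ds in idx_ds], dtype=np.int64)
    g = off + idx_loc
    rows, cols, vals = g[coo.row], g[coo.col], coo.data
    if cross_only:
        keep = idx_ds[coo.row] != idx_ds[coo.col]
        rows, cols, vals = rows[keep], cols[keep], vals[keep]
    keep = rows != cols
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    lo = np.minimum(rows, cols)
    hi = np.maximum(rows, cols)
    return lo, hi, vals


def assemble_multigraph(
    sizes: Mapping[str, int],
    own_sets: Mapping[str, FuzzySet],
    shared_sets: Sequence[FuzzySet] = (),
    cross_set: FuzzySet | None = None,
) -> MultiGraph:
    """Merge per-space fuzzy sets into the single cross-dataset graph.

    ``sizes`` fixes the dataset order of the global index.  Within-dataset
    edges come only from each dataset's own-space set; cross-dataset edges
    from shared-space sets (restricted to pairs from different datasets)
    and/or an explicit cross set.  Duplicate edges are merged with the
    probabilistic t-conorm; the surviving tag is the source with the
    largest membership.
    """
    datasets = list(sizes)
    if not datasets:
        raise ValueError("at least one dataset required")
    for ds in datasets:
        if ds not in own_sets:
            raise ValueError(f"dataset {ds!r} has no own-space fuzzy set")
        if own_sets[ds].matrix.shape[0] != sizes[ds]:
            raise ValueError(f"own-space set of {ds!r} does not cover all its points")
    offsets: dict[str, int] = {}
    acc = 0
    for ds in datasets:
        offsets[ds] = acc
        acc += sizes[ds]
    n_total = acc

    sources: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    covered_pairs: set[frozenset[str]] = set()
    for ds in datasets:
        lo, hi, vals = _to_global_triplets(own_sets[ds], offsets, cross_only=False)
        sources.append((f"own:{ds}", lo, hi, vals))
    for fset in shared_sets:
        lo, hi, vals = _to_global_triplets(fset, offsets, cross_only=True)
        tag = "shared:" + "+".join(fset.space_id)
        sources.append((tag, lo, hi, vals))
        for a in fset.space_id:
            for b in fset.space_id:
                if a != b:
                    covered_pairs.add(frozenset((a, b)))
    if cross_set is not None:
        lo, hi, vals = _to_global_triplets(cross_set, offsets, cross_only=True)
        sources.append(("cross:table", lo, hi, vals))
        for a in cross_set.space_id:
            for b in cross_set.space_id:
                if a != b:
                    covered_pairs.add(frozenset((a, b)))
    for i, a in enumerate(datasets):
        for b in datasets[i + 1:]:
            if frozenset((a, b)) not in covered_pairs:
                logger.warning(
                    "no shared space or cross table links datasets %r and %r; "
                    "the graph is block-disconnected across this pair", a, b,
                )

    tag_names = [t for t, *_ in sources]
    lo = np.concatenate([s[1] for s in sources])
    hi = np.concatenate([s[2] for s in sources])
    vals = np.concatenate([s[3] for s in sources])
    codes = np.concatenate(
        [np.full(len(s[1]), c, dtype=np.int64) for c, s in enumerate(sources)]
    )

    key = lo * n_total + hi
    order = np.argsort(key, kind="mergesort")
    key, lo, hi, vals, codes = key[order], lo[order], hi[order], vals[order], codes[order]
    uniq, start = np.unique(key, return_index=True)
    group = np.searchsorted(uniq, key)
    # t-conorm across sources: mu = 1 - prod(1 - mu_s)
    one_minus = np.ones(len(uniq))
    np.multiply.at(one_minus, group, 1.0 - vals)
    merged = 1.0 - one_minus
    # dominant tag: source with the largest membership in each group
    best = np.full(len(uniq), -1, dtype=np.int64)
    best_val = np.full(len(uniq), -1.0)
    for i in range(len(vals)):
        g = group[i]
        if vals[i] > best_val[g]:
            best_val[g] = vals[i]
            best[g] = i
    tag_rows, tag_cols, tag_codes = lo[best], hi[best], codes[best]
    merged = np.clip(merged, 0.0, 1.0)

    upper = sp.csr_matrix(
        (merged, (lo[start], hi[start])), shape=(n_total, n_total)
    )
    full = upper + upper.T
    full = sp.csr_matrix(full)
    full.eliminate_zeros()
    return MultiGraph(
        matrix=full,
        datasets=datasets,
        sizes=dict(sizes),
        tag_names=tag_names,
        tag_rows=tag_rows,
        tag_cols=tag_cols,
        tag_codes=tag_codes,
    )


def write_multigraph(graph: MultiGraph, out_dir: str | Path, stem: str = "multigraph") -> None:
    """Export as Matrix Market plus global-index and edge-tag TSVs."""
    from scipy.io import mmwrite

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / f"{stem}.mtx"), sp.coo_matrix(graph.matrix), symmetry="general")
    with open(out_dir / f"{stem}.index.tsv", "w") as fh:
        for ds, loc in graph.global_index():
            fh.write(f"{ds}\t{loc}\n")
    graph.edge_tags().to_csv(out_dir / f"{stem}.tags.tsv", sep="\t", index=False)
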