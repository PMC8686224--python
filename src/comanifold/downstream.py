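"""Consumers of the joint graph and embedding.

Label transfer between datasets (5-NN majority vote in the embedding, or
harmonic-function propagation directly on the graph) and the four
benchmark metrics used to assess an integration: transfer balanced
accuracy, mean silhouette under cell-type labels, alignment (dataset
mixing among nearest neighbors), and structure (Pearson correlation of
high- and low-dimensional pairwise distances).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .embedding import Embedding
from .manifold_graph import MultiGraph

logger = logging.getLogger(__name__)

__all__ = [
    "UNLABELED",
    "LabelSet",
    "MetricReport",
    "transfer_labels_knn",
    "transfer_labels_harmonic",
    "balanced_accuracy",
    "silhouette_mean",
    "alignment_score",
    "structure_score",
]

UNLABELED = ""

_STRUCTURE_PAIR_CAP = 1_000_000


@dataclass
class LabelSet:
    """Per-point labels aligned to a global point index; "" = unlabeled."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        for i, lab in enumerate(self.labels):
            if lab is None or (isinstance(lab, float) and np.isnan(lab)):
                self.labels[i] = UNLABELED
        self.labels = self.labels.astype(str)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels) - {UNLABELED})

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class MetricReport:
    """The four benchmark metrics plus the parameters they were run with."""

    transfer: float | None = None
    silhouette: float | None = None
    alignment: float | None = None
    structure: float | None = None
    parameters: dict = None

    def __post_init__(self) -> None:
        self.parameters = dict(self.parameters or {})
        checks = {
            "transfer": (0.0, 1.0),
            "silhouette": (-1.0, 1.0),
            "alignment": (0.0, 1.0),
            "structure": (-1.0, 1.0),
        }
        for name, (lo, hi) in checks.items():
            val = getattr(self, name)
            if val is not None and not (lo - 1e-9 <= val <= hi + 1e-9):
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        row = {k: v for k, v in asdict(self).items() if k != "parameters"}
        pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# label transfer
# ---------------------------------------------------------------------------


def transfer_labels_knn(
    embedding: Embedding | np.ndarray,
    labels: LabelSet | np.ndarray,
    query_mask: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Majority vote among the k nearest *labeled* neighbors in the embedding.

    ``query_mask`` selects the points to predict; the reference set is
    every labeled point outside the query set.  Ties are broken by the
    class of the nearest neighbor among the tied classes.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    labels = labels if isinstance(labels, LabelSet) else LabelSet(labels)
    query_mask = np.asarray(query_mask, dtype=bool)
    ref_mask = labels.labeled_mask & ~query_mask
    ref_idx = np.flatnonzero(ref_mask)
    if ref_idx.size == 0:
        raise ValueError("no labeled reference points outside the query set")
    kk = min(k, ref_idx.size)
    nn = NearestNeighbors(n_neighbors=kk, algorithm="brute", metric="euclidean")
    nn.fit(coords[ref_idx])
    query_idx = np.flatnonzero(query_mask)
    _, nbrs = nn.kneighbors(coords[query_idx])
    ref_labels = labels.labels[ref_idx]
    out = np.empty(query_idx.size, dtype=object)
    for row, nb in enumerate(nbrs):
        votes: dict[str, int] = {}
        for pos in nb:
            lab = ref_labels[pos]
            votes[lab] = votes.get(lab, 0) + 1
        top = max(votes.values())
        tied = {lab for lab, c in votes.items() if c == top}
        if len(tied) == 1:
            out[row] = tied.pop()
        else:  # nearest neighbor among the tied classes (nbrs are sorted)
            for pos in nb:
                if ref_labels[pos] in tied:
                    out[row] = ref_labels[pos]
                    break
    return out.astype(str)


def transfer_labels_harmonic(
    graph: MultiGraph | sp.spmatrix,
    labels: LabelSet | np.ndarray,
    tol: float = 1e-8,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Harmonic-function node classification on the graph.

    Labeled points are clamped to class-indicator rows; every unlabeled
    point's class probabilities solve the harmonic condition (each equals
    the weighted average of its neighbors') via a sparse linear solve.
    Returns ``(probabilities, classes, unassignable_mask)``; rows of
    connected components without any labeled point are flagged
    unassignable and left as zeros.
    """
    W = graph.matrix if isinstance(graph, MultiGraph) else sp.csr_matrix(graph)
    labels = labels if isinstance(labels, LabelSet) else LabelSet(labels)
    n = W.shape[0]
    if len(labels) != n:
        raise ValueError("labels not aligned to the graph")
    classes = labels.classes
    if not classes:
        raise ValueError("harmonic transfer requires at least one labeled point")
    cls_pos = {c: i for i, c in enumerate(classes)}
    labeled = labels.labeled_mask
    probs = np.zeros((n, len(classes)))
    for i in np.flatnonzero(labeled):
        probs[i, cls_pos[labels.labels[i]]] = 1.0

    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(W, directed=False)
    unassignable = np.zeros(n, dtype=bool)
    for c in range(n_comp):
        members = comp == c
        if not np.any(labeled & members) and np.any(~labeled & members):
            unassignable |= members & ~labeled
    solve_mask = ~labeled & ~unassignable
    u = np.flatnonzero(solve_mask)
    if u.size:
        l = np.flatnonzero(labeled)
        W_uu = W[u][:, u]
        W_ul = W[u][:, l]
        deg = np.asarray(W[u].sum(axis=1)).ravel()
        A = sp.csr_matrix(sp.diags(deg) - W_uu)
        B = np.asarray(W_ul @ probs[l])
        # the grounded Laplacian is SPD when every component has a label,
        # so conjugate gradients converge; direct LU is the fallback
        from scipy.sparse.linalg import cg, splu

        sol = np.empty((u.size, len(classes)))
        ok = True
        for j in range(len(classes)):
            sol[:, j], info = cg(A, B[:, j], rtol=tol, atol=0.0)
            if info != 0:
                ok = False
                break
        if not ok:  # pragma: no cover - CG non-convergence
            sol = splu(sp.csc_matrix(A)).solve(B)
        probs[u] = np.clip(sol, 0.0, 1.0)
        # normalize away round-off so rows sum to exactly 1
        sums = probs[u].sum(axis=1, keepdims=True)
        probs[u] = np.divide(probs[u], sums, out=probs[u], where=sums > 0)
    if unassignable.any():
        logger.warning(
            "%d points live in components with no labeled point and are "
            "unassignable", int(unassignable.sum()),
        )
    return probs, classes, unassignable


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def balanced_accuracy(true_labels: np.ndarray, predicted: np.ndarray) -> float:
    """Unweighted mean of per-class recall over classes present in truth."""
    t = np.asarray(true_labels, dtype=str)
    p = np.asarray(predicted, dtype=str)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels must have the same length")
    classes = sorted(set(t) - {UNLABELED})
    if not classes:
        raise ValueError("no labeled points in the truth")
    pred_only = sorted(set(p) - set(t) - {UNLABELED})
    if pred_only:
        logger.warning(
            "classes %s appear only in predictions (zero true members); excluded",
            pred_only,
        )
    recalls = []
    for c in classes:
        mask = t == c
        recalls.append(float(np.mean(p[mask] == c)))
    return float(np.mean(recalls))


def silhouette_mean(
    embedding: Embedding | np.ndarray, labels: LabelSet | np.ndarray
) -> float:
    """Mean silhouette over all labeled points (Euclidean distances).

    Points of singleton classes score 0, with a warning.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    labels = labels if isinstance(labels, LabelSet) else LabelSet(labels)
    mask = labels.labeled_mask
    labs = labels.labels[mask]
    x = coords[mask]
    uniq, counts = np.unique(labs, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 classes")
    if (counts == 1).any():
        logger.warning(
            "singleton classes %s scored 0 in the silhouette",
            list(uniq[counts == 1]),
        )
    scores = silhouette_samples(x, labs, metric="euclidean")
    return float(np.mean(scores))


def alignment_score(
    embedding: Embedding | np.ndarray,
    dataset_ids: np.ndarray | None = None,
    k: int = 5,
) -> float:
    """Mean fraction of each point's k nearest neighbors from another dataset."""
    if isinstance(embedding, Embedding):
        coords = embedding.coords
        if dataset_ids is None:
            dataset_ids = embedding.point_dataset
    else:
        coords = np.asarray(embedding)
    if dataset_ids is None:
        raise ValueError("dataset_ids required for a bare coordinate array")
    ds = np.asarray(dataset_ids)
    n = coords.shape[0]
    if len(np.unique(ds)) < 2:
        logger.warning("alignment is 0 by definition for a single dataset")
        return 0.0
    if n <= k:
        raise ValueError(f"alignment needs more than k={k} points")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean")
    nn.fit(coords)
    _, nbrs = nn.kneighbors(coords)
    other = ds[nbrs[:, 1:]] != ds[:, None]
    return float(np.mean(other))


def structure_score(
    space_coords: np.ndarray,
    embedded_coords: np.ndarray,
    seed: int = 0,
) -> float | None:
    """Pearson correlation of high- vs low-dimensional pairwise distances.

    All ``N (N-1) / 2`` pairs are used up to one million; above that a
    seeded uniform subsample of one million pairs keeps the metric
    desk-scale.  Returns ``None`` when a distance vector has zero
    variance (correlation undefined).
    """
    hi = np.asarray(space_coords, dtype=np.float64)
    lo = np.asarray(embedded_coords, dtype=np.float64)
    if hi.shape[0] != lo.shape[0]:
        raise ValueError("coordinate sets must cover the same points")
    n = hi.shape[0]
    if n < 3:
        raise ValueError("structure score needs at least 3 points")
    n_pairs = n * (n - 1) // 2
    if n_pairs <= _STRUCTURE_PAIR_CAP:
        iu = np.triu_indices(n, k=1)
        rows, cols = iu
    else:
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, n, size=_STRUCTURE_PAIR_CAP)
        cols = rng.integers(0, n, size=_STRUCTURE_PAIR_CAP)
        keep = rows != cols
        rows, cols = rows[keep], cols[keep]
    d_hi = np.linalg.norm(hi[rows] - hi[cols], axis=1)
    d_lo = np.linalg.norm(lo[rows] - lo[cols], axis=1)
    if d_hi.std() == 0 or d_lo.std() == 0:
        logger.warning("zero-variance distance vector; structure score undefined")
        return None
    return float(np.corrcoef(d_hi, d_lo)[0, 1])
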