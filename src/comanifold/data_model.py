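"""Core containers, matrix/label I/O, and preprocessing conventions.

This module defines the in-memory types shared by the whole pipeline
(:class:`DataBlock`, :class:`SpaceCoords`, :class:`CrossDistanceTable`) and
the standard preprocessing steps used to prepare multimodal inputs:
TF-IDF weighting of binary accessibility matrices, PCA/SVD reduction of
each dataset's own feature space, and construction of shared feature
spaces from the intersection of feature names.

Conventions
-----------
* Dense matrices travel as TSV/CSV with a header row of feature names and
  a first column of point ids; sparse matrices as Matrix Market ``.mtx``
  with ``<stem>.features.txt`` / ``<stem>.points.txt`` sidecars.
* Labels are a two-column TSV ``point_id<TAB>label``; an empty label means
  "unlabeled".
* Cross-dataset distances are a five-column TSV
  ``dataset_a  index_a  dataset_b  index_b  distance``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD

logger = logging.getLogger(__name__)

__all__ = [
    "DataBlock",
    "SpaceCoords",
    "CrossDistanceTable",
    "ParseError",
    "load_matrix",
    "write_matrix",
    "load_labels",
    "write_labels",
    "load_cross_table",
    "write_cross_table",
    "tfidf_transform",
    "reduce_dimension",
    "build_shared_space",
    "default_weights",
]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted under its format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DataBlock:
    """One dataset: an ``n_points x n_features`` matrix plus metadata.

    Parameters
    ----------
    dataset_id
        Short identifier, unique across the datasets being integrated.
    matrix
        Numeric matrix, dense ``ndarray`` or scipy sparse, points in rows.
    feature_names
        One name per column, unique within the block.
    labels
        Optional per-point categorical labels; ``""`` marks unlabeled points.
    weight
        Influence of this dataset on the joint layout, in ``[0, 1]``.  The
        conventional defaults are 0.8 for a designated reference modality
        (typically scRNA-seq) and 0.2 for the others; see
        :func:`default_weights`.
    point_ids
        Optional per-point identifiers; generated as ``{id}:{row}`` if absent.
    """

    dataset_id: str
    matrix: np.ndarray | sp.spmatrix
    feature_names: list[str]
    labels: np.ndarray | None = None
    weight: float = 1.0
    point_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if sp.issparse(self.matrix):
            self.matrix = self.matrix.tocsr()
        else:
            self.matrix = np.asarray(self.matrix)
            if self.matrix.ndim != 2:
                raise ValueError(
                    f"block {self.dataset_id!r}: matrix must be 2-D, "
                    f"got shape {self.matrix.shape}"
                )
        self.feature_names = [str(f) for f in self.feature_names]
        if self.n_points < 1:
            raise ValueError(f"block {self.dataset_id!r}: needs at least one point")
        if len(self.feature_names) != self.matrix.shape[1]:
            raise ValueError(
                f"block {self.dataset_id!r}: {len(self.feature_names)} feature "
                f"names for {self.matrix.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"block {self.dataset_id!r}: duplicate feature names")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"block {self.dataset_id!r}: weight must be in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.n_points:
                raise ValueError(
                    f"block {self.dataset_id!r}: {len(self.labels)} labels "
                    f"for {self.n_points} points"
                )
        if self.point_ids is None:
            self.point_ids = [f"{self.dataset_id}:{i}" for i in range(self.n_points)]
        elif len(self.point_ids) != self.n_points:
            raise ValueError(
                f"block {self.dataset_id!r}: {len(self.point_ids)} point ids "
                f"for {self.n_points} points"
            )

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        m = self.matrix
        return np.asarray(m.todense()) if sp.issparse(m) else m


@dataclass
class SpaceCoords:
    """Reduced coordinates of one ambient space.

    An ambient space is either a dataset's own space (``space_id`` of length
    one) or a shared feature space covering two or more datasets.  Every
    point of every covered dataset has exactly one row.
    """

    space_id: tuple[str, ...]
    coords: dict[str, np.ndarray]  # dataset_id -> (n_points, dim)

    def __post_init__(self) -> None:
        self.space_id = tuple(self.space_id)
        dims = set()
        for ds, arr in self.coords.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"space {self.space_id}: coords of {ds!r} not 2-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"space {self.space_id}: non-finite coords in {ds!r}")
            self.coords[ds] = arr
            dims.add(arr.shape[1])
        if len(dims) != 1:
            raise ValueError(f"space {self.space_id}: inconsistent dimensions {dims}")
        if set(self.space_id) != set(self.coords):
            raise ValueError(
                f"space {self.space_id}: coords given for {sorted(self.coords)}"
            )
        if self.dim < 1:
            raise ValueError(f"space {self.space_id}: dimension must be >= 1")

    @property
    def dim(self) -> int:
        return next(iter(self.coords.values())).shape[1]

    def n_points(self, dataset_id: str) -> int:
        return self.coords[dataset_id].shape[0]

    def stacked(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """All points stacked in ``space_id`` order, with their identities."""
        arrays, index = [], []
        for ds in self.space_id:
            arr = self.coords[ds]
            arrays.append(arr)
            index.extend((ds, i) for i in range(arr.shape[0]))
        return np.vstack(arrays), index


@dataclass
class CrossDistanceTable:
    """Explicit distances between points of different datasets.

    ``pairs`` is a DataFrame with columns ``dataset_a, index_a, dataset_b,
    index_b, distance``.  Distances must be finite and non-negative and may
    cover any subset of cross-dataset point pairs (e.g. 1% anchor points
    whose latent manifold position is known).
    """

    pairs: pd.DataFrame

    COLUMNS = ("dataset_a", "index_a", "dataset_b", "index_b", "distance")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.pairs, columns=list(self.COLUMNS)).copy()
        df["index_a"] = df["index_a"].astype(int)
        df["index_b"] = df["index_b"].astype(int)
        df["distance"] = df["distance"].astype(float)
        if not np.all(np.isfinite(df["distance"])) or (df["distance"] < 0).any():
            raise ValueError("cross distances must be finite and non-negative")
        same = (df["dataset_a"] == df["dataset_b"]) & (df["index_a"] == df["index_b"])
        if same.any():
            raise ValueError("cross-distance table contains self-pairs")
        self.pairs = df

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("mtx", "tsv", "csv"):
        return suffix
    raise ParseError(f"{path}: cannot infer format from suffix {path.suffix!r}")


def _read_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise ParseError(f"{path}: required sidecar file is missing")
    return path.read_text().splitlines()


def load_matrix(
    path: str | Path, fmt: str | None = None, dataset_id: str | None = None
) -> DataBlock:
    """Read a points-by-features matrix from ``mtx``, ``tsv`` or ``csv``.

    Matrix Market input expects ``<stem>.features.txt`` and
    ``<stem>.points.txt`` sidecars (one name per line).  Delimited input
    expects a header row of feature names and a first column of point ids.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    fmt = fmt or _infer_format(path)
    dataset_id = dataset_id or path.stem
    if fmt == "mtx":
        from scipy.io import mmread

        try:
            matrix = sp.csr_matrix(mmread(str(path)))
        except Exception as exc:
            raise ParseError(f"{path}: malformed Matrix Market file ({exc})") from exc
        stem = path.name[: -len(path.suffix)]
        features = _read_sidecar(path.parent / (stem + ".features.txt"))
        points = _read_sidecar(path.parent / (stem + ".points.txt"))
        if len(features) != matrix.shape[1]:
            raise ParseError(
                f"{path}: feature sidecar has {len(features)} lines for "
                f"{matrix.shape[1]} columns"
            )
        if len(points) != matrix.shape[0]:
            raise ParseError(
                f"{path}: point sidecar has {len(points)} lines for "
                f"{matrix.shape[0]} rows"
            )
        return DataBlock(dataset_id, matrix, features, point_ids=points)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: failed to parse as {fmt} ({exc})") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: no feature columns found")
        try:
            values = df.to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric entries ({exc})") from exc
        return DataBlock(
            dataset_id,
            values,
            [str(c) for c in df.columns],
            point_ids=[str(i) for i in df.index],
        )
    raise ParseError(f"{path}: unsupported format {fmt!r}")


def write_matrix(block: DataBlock, path: str | Path, fmt: str | None = None) -> None:
    """Write a block in a format :func:`load_matrix` can round-trip."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        from scipy.io import mmwrite

        mmwrite(str(path), sp.coo_matrix(block.matrix))
        stem = path.name[: -len(path.suffix)]
        (path.parent / (stem + ".features.txt")).write_text(
            "\n".join(block.feature_names) + "\n"
        )
        (path.parent / (stem + ".points.txt")).write_text(
            "\n".join(block.point_ids) + "\n"
        )
        return
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.DataFrame(block.dense(), index=block.point_ids, columns=block.feature_names)
        df.to_csv(path, sep=sep)
        return
    raise ParseError(f"{path}: unsupported format {fmt!r}")


def load_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of ``point_id -> label`` (empty = unlabeled)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    out: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{lab}\n")


def load_cross_table(path: str | Path) -> CrossDistanceTable:
    """Read a five-column cross-distance TSV."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: failed to parse ({exc})") from exc
    missing = set(CrossDistanceTable.COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return CrossDistanceTable(df[list(CrossDistanceTable.COLUMNS)])


def write_cross_table(table: CrossDistanceTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def tfidf_transform(matrix: np.ndarray | sp.spmatrix) -> np.ndarray | sp.spmatrix:
    """TF-IDF weight a binary points-by-features matrix.

    ``tf(c, f)`` is the fraction of point *c*'s present features that are
    *f*; the smoothed inverse document frequency is
    ``idf(f) = log(1 + N / (1 + df_f))`` with ``df_f`` the number of points
    in which feature *f* is present.  The sparsity pattern is preserved.
    This is the standard weighting applied to binarized chromatin
    accessibility before SVD (latent semantic indexing).
    """
    is_sparse = sp.issparse(matrix)
    data = matrix.data if is_sparse else np.asarray(matrix)
    vals = np.unique(data if not is_sparse else data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("tfidf_transform expects a binary matrix (entries in {0, 1})")
    if is_sparse:
        mat = matrix.tocsr().astype(np.float64)
        row_sums = np.asarray(mat.sum(axis=1)).ravel()
    else:
        mat = np.asarray(matrix, dtype=np.float64)
        row_sums = mat.sum(axis=1)
    zero_rows = np.flatnonzero(row_sums == 0)
    if zero_rows.size:
        raise ValueError(
            f"tfidf_transform: all-zero rows not allowed (first offender: row "
            f"{zero_rows[0]})"
        )
    n = mat.shape[0]
    df = np.asarray(mat.sum(axis=0)).ravel() if is_sparse else mat.sum(axis=0)
    idf = np.log(1.0 + n / (1.0 + df))
    if is_sparse:
        tf = sp.diags(1.0 / row_sums) @ mat
        return (tf @ sp.diags(idf)).tocsr()
    return (mat / row_sums[:, None]) * idf[None, :]


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    flip = np.ones(components.shape[0])
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            flip[k] = -1.0
    return scores * flip[None, :]


def _reduce_matrix(
    matrix: np.ndarray | sp.spmatrix, d: int, method: str, seed: int
) -> np.ndarray:
    n, p = matrix.shape
    max_d = min(n, p)
    if d > max_d:
        raise ValueError(
            f"target dimension {d} exceeds min(n_points, n_features) = {max_d}; "
            f"use d <= {max_d}"
        )
    if method == "pca":
        dense = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix)
        if not np.all(np.isfinite(dense)):
            raise ValueError("matrix contains non-finite entries")
        solver = "full" if max_d <= 1500 else "randomized"
        model = PCA(n_components=d, svd_solver=solver, random_state=seed)
        scores = model.fit_transform(dense)
    elif method == "truncated_svd":
        if d >= max_d:
            # TruncatedSVD requires n_components < n_features; fall back to
            # a full SVD of the (uncentered) matrix in the degenerate case.
            dense = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix)
            u, s, vt = np.linalg.svd(dense, full_matrices=False)
            scores = _fix_signs(vt[:d], u[:, :d] * s[:d])
            return scores
        model = TruncatedSVD(n_components=d, random_state=seed)
        scores = model.fit_transform(matrix)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return _fix_signs(model.components_, scores)


def reduce_dimension(
    block: DataBlock, d: int, method: str = "pca", seed: int = 0
) -> SpaceCoords:
    """Reduce one dataset's own feature space to ``d`` component scores.

    ``pca`` centers the data; ``truncated_svd`` does not (the convention
    for TF-IDF-weighted accessibility matrices).  Components are ordered
    by decreasing explained variance with a deterministic sign convention.
    """
    scores = _reduce_matrix(block.matrix, d, method, seed)
    return SpaceCoords((block.dataset_id,), {block.dataset_id: scores})


def build_shared_space(
    block_i: DataBlock,
    block_j: DataBlock,
    d: int = 50,
    seed: int = 0,
    method: str = "pca",
    log1p: bool = False,
) -> SpaceCoords:
    """Construct the shared feature space of two datasets.

    Features absent from either dataset are removed, both matrices are
    restricted to the intersection in one canonical (sorted) order, stacked,
    and jointly reduced to ``d`` dimensions.  Inputs are assumed already
    normalized per modality; ``log1p`` optionally applies ``log(1 + x)`` to
    the restricted matrices before the joint reduction.
    """
    shared = sorted(set(block_i.feature_names) & set(block_j.feature_names))
    if not shared:
        raise ValueError(
            f"blocks {block_i.dataset_id!r} and {block_j.dataset_id!r} share "
            f"no features; cannot build a shared space"
        )
    if len(shared) < d:
        logger.warning(
            "shared space %s/%s: only %d shared features; lowering d from %d",
            block_i.dataset_id, block_j.dataset_id, len(shared), d,
        )
        d = len(shared)
    cols_i = [block_i.feature_names.index(f) for f in shared]
    cols_j = [block_j.feature_names.index(f) for f in shared]
    sub_i = block_i.dense()[:, cols_i]
    sub_j = block_j.dense()[:, cols_j]
    stacked = np.vstack([sub_i, sub_j])
    if log1p:
        stacked = np.log1p(stacked)
    d = min(d, min(stacked.shape))
    scores = _reduce_matrix(stacked, d, method, seed)
    n_i = block_i.n_points
    return SpaceCoords(
        (block_i.dataset_id, block_j.dataset_id),
        {block_i.dataset_id: scores[:n_i], block_j.dataset_id: scores[n_i:]},
    )


def default_weights(
    blocks: Sequence[DataBlock], reference: str | None = None
) -> dict[str, float]:
    """Per-dataset layout weights ω.

    With a designated ``reference`` modality the conventional defaults are
    0.8 for the reference and 0.2 for every other dataset.  Without one,
    all datasets get equal weight 1.0 (equal shares normalized so the
    largest is 1).
    """
    ids = [b.dataset_id for b in blocks]
    if reference is not None:
        if reference not in ids:
            raise ValueError(f"reference {reference!r} is not one of {ids}")
        return {i: (0.8 if i == reference else 0.2) for i in ids}
    # equal shares 1/|datasets|, normalized so the maximum weight is 1
    return {i: 1.0 for i in ids}
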