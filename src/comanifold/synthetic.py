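"""Synthetic multimodal scenarios for controlled evaluation.

Three generators emulate the statistical structure of classic multimodal
integration benchmarks without any download:

* :func:`make_swiss_roll_pair` — a 3-D Swiss-roll dataset and a 2-D
  rectangle describing the same rectangular manifold, with the latent
  manifold position of a small fraction of anchor points supplied as
  explicit cross-dataset distances.
* :func:`make_split_image_pair` — two image-half datasets (left/right
  28x15 slices of 28x28 class images, flattened to 420 features) that
  overlap in a 28x2 pixel sliver, with strong Gaussian noise added to the
  first dataset.  Class prototypes are smooth random fields standing in
  for digit glyphs; a synthetic construction that keeps the essentials:
  ten classes, class-separating halves, and an ambiguous shared sliver.
* :func:`make_cluster_overlap_pair` — two Gaussian-mixture datasets
  observed through different random linear maps, sharing a configurable
  number of clusters, to probe robustness to partial population overlap.

All generators are bitwise-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_model import CrossDistanceTable, DataBlock

__all__ = [
    "SyntheticScenario",
    "make_swiss_roll_pair",
    "make_split_image_pair",
    "make_cluster_overlap_pair",
]


@dataclass
class SyntheticScenario:
    """Generated blocks plus ground truth and the parameters used."""

    blocks: list[DataBlock]
    cross: CrossDistanceTable | None = None
    positions: dict[str, np.ndarray] | None = None  # latent manifold position
    params: dict = field(default_factory=dict)
    seed: int = 0

    def block(self, dataset_id: str) -> DataBlock:
        for b in self.blocks:
            if b.dataset_id == dataset_id:
                return b
        raise KeyError(dataset_id)


def _arc_length(t: np.ndarray) -> np.ndarray:
    """Arc length of the spiral r = t from the axis: (t sqrt(1+t^2) + asinh t)/2."""
    return 0.5 * (t * np.sqrt(1.0 + t * t) + np.arcsinh(t))


def make_swiss_roll_pair(
    n: int = 10_000,
    anchored_fraction: float = 0.01,
    seed: int = 0,
    y_extent: float = 21.0,
) -> SyntheticScenario:
    """Swiss roll (3-D) and rectangle (2-D) sampled from one latent manifold.

    The roll is the canonical surface ``(t cos t, y, t sin t)`` with ``t``
    uniform on ``[3 pi / 2, 9 pi / 2]`` and ``y`` uniform on
    ``[0, y_extent]``.  The rectangle's first coordinate is the unrolled
    length coordinate: the manifold position of every point is its
    normalized arc length along the spiral, in ``[0, 1]``, and the
    rectangle is sampled uniformly in that coordinate (its second axis is
    ``y`` rescaled to the same units).  For ``anchored_fraction`` of the
    points of each dataset, cross-dataset distances are the absolute
    differences between manifold positions.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if not 0 < anchored_fraction <= 1:
        raise ValueError("anchored_fraction must be in (0, 1]")
    n_anchor = int(round(n * anchored_fraction))
    if n_anchor < 2:
        raise ValueError(
            f"anchored_fraction={anchored_fraction} yields {n_anchor} anchors; "
            f"need at least 2"
        )
    rng = np.random.default_rng(seed)
    t_lo, t_hi = 1.5 * np.pi, 4.5 * np.pi
    t = rng.uniform(t_lo, t_hi, size=n)
    y = rng.uniform(0.0, y_extent, size=n)
    roll = np.column_stack([t * np.cos(t), y, t * np.sin(t)])
    arc0, arc1 = _arc_length(np.array([t_lo, t_hi]))
    arc_range = arc1 - arc0
    pos_roll = (_arc_length(t) - arc0) / arc_range

    u = rng.uniform(0.0, 1.0, size=n)
    y2 = rng.uniform(0.0, y_extent / arc_range, size=n)
    rect = np.column_stack([u, y2])
    pos_rect = u

    anchors_roll = np.sort(rng.choice(n, size=n_anchor, replace=False))
    anchors_rect = np.sort(rng.choice(n, size=n_anchor, replace=False))
    rows = []
    for ia in anchors_roll:
        for ib in anchors_rect:
            rows.append(("roll", ia, "rect", ib, abs(pos_roll[ia] - pos_rect[ib])))
    cross = CrossDistanceTable(
        pd.DataFrame(rows, columns=list(CrossDistanceTable.COLUMNS))
    )
    blocks = [
        DataBlock("roll", roll, ["x", "y", "z"]),
        DataBlock("rect", rect, ["u", "v"]),
    ]
    return SyntheticScenario(
        blocks=blocks,
        cross=cross,
        positions={"roll": pos_roll, "rect": pos_rect},
        params={
            "n": n,
            "anchored_fraction": anchored_fraction,
            "n_anchors": n_anchor,
            "t_range": (t_lo, t_hi),
            "arc_range": arc_range,
            "y_extent": y_extent,
            "anchors_roll": anchors_roll,
            "anchors_rect": anchors_rect,
        },
        seed=seed,
    )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Low-frequency random field: coarse Gaussian noise upsampled smoothly."""
    coarse = rng.normal(size=(4, 4))
    zoom = (shape[0] / 4, shape[1] / 4)
    img = ndimage.zoom(coarse, zoom, order=3)
    img = img - img.min()
    if img.max() > 0:
        img = img / img.max()
    return img * 255.0


def make_split_image_pair(
    n: int = 2000,
    n_classes: int = 10,
    image_shape: tuple[int, int] = (28, 28),
    half_width: int = 15,
    overlap: int = 2,
    noise_sd: float | None = None,
    jitter_sd: float = 25.0,
    sliver_blend: float = 0.5,
    seed: int = 0,
) -> SyntheticScenario:
    """Left/right image halves with a thin shared sliver and one noisy half.

    Each class has a smooth random-field prototype image; samples are the
    prototype plus per-pixel Gaussian jitter.  Every image is split into a
    left and a right ``28 x half_width`` half that overlap by
    ``28 x overlap`` columns; the overlap columns carry identical feature
    names in both blocks so a shared feature space can be recovered from
    names alone.  The overlap columns of all prototypes are blended toward
    one common pattern (``sliver_blend``) so the sliver is ambiguous
    between classes.  Gaussian noise with a standard deviation equal to
    the maximum pixel value (unless overridden) is added to the first
    block only.
    """
    if n < 10 * n_classes:
        raise ValueError(f"need n >= 10 * n_classes = {10 * n_classes}")
    n_rows, n_cols = image_shape
    if 2 * half_width - overlap != n_cols:
        raise ValueError("halves must tile the image: 2*half_width - overlap == cols")
    rng = np.random.default_rng(seed)
    # draw a surplus of candidate fields and keep a maximally spread subset,
    # so classes are mutually distinguishable (digit classes are)
    candidates = np.stack(
        [_smooth_field(rng, image_shape) for _ in range(3 * n_classes)]
    )
    flat = candidates.reshape(len(candidates), -1)
    chosen = [0]
    while len(chosen) < n_classes:
        dists = np.min(
            np.linalg.norm(flat[:, None] - flat[chosen][None], axis=2), axis=1
        )
        dists[chosen] = -1.0
        chosen.append(int(np.argmax(dists)))
    fields = candidates[chosen]
    common = _smooth_field(rng, image_shape)
    left_cols = np.arange(half_width)
    right_cols = np.arange(n_cols - half_width, n_cols)
    shared_cols = np.intersect1d(left_cols, right_cols)
    # threshold to high-contrast binary strokes (~30% coverage), emulating
    # the near-binary pixel statistics of handwritten-digit images
    thresholds = np.quantile(fields.reshape(n_classes, -1), 0.7, axis=1)
    protos = 255.0 * (fields > thresholds[:, None, None])
    common_bin = 255.0 * (common > np.quantile(common, 0.7))
    # make the shared sliver ambiguous: a fixed ``sliver_blend`` fraction of
    # its pixels shows one common stroke pattern in every class, leaving
    # only the remainder to carry class identity
    shared_mask = rng.random((n_rows, shared_cols.size)) < sliver_blend
    for c in range(n_classes):
        block = protos[c][:, shared_cols]
        block[shared_mask] = common_bin[:, shared_cols][shared_mask]
        protos[c][:, shared_cols] = block

    # balanced class assignment, shuffled
    classes = np.tile(np.arange(n_classes), n // n_classes + 1)[:n]
    rng.shuffle(classes)
    images = protos[classes] + rng.normal(0.0, jitter_sd, size=(n, n_rows, n_cols))
    if noise_sd is None:
        noise_sd = float(protos.max())  # the image dynamic-range maximum

    left = images[:, :, left_cols].reshape(n, -1)
    right = images[:, :, right_cols].reshape(n, -1)
    left = left + rng.normal(0.0, noise_sd, size=left.shape)

    def names(cols: np.ndarray) -> list[str]:
        return [f"px_{r}_{c}" for r in range(n_rows) for c in cols]

    labels = np.array([f"class_{c}" for c in classes], dtype=object)
    blocks = [
        DataBlock("left", left, names(left_cols), labels=labels.copy()),
        DataBlock("right", right, names(right_cols), labels=labels.copy()),
    ]
    return SyntheticScenario(
        blocks=blocks,
        params={
            "n": n,
            "n_classes": n_classes,
            "image_shape": image_shape,
            "half_width": half_width,
            "overlap": overlap,
            "n_shared_features": n_rows * overlap,
            "noise_sd": noise_sd,
            "jitter_sd": jitter_sd,
            "sliver_blend": sliver_blend,
            "classes": classes,
        },
        seed=seed,
    )


def make_cluster_overlap_pair(
    n_clusters: int = 10,
    m_shared: int = 10,
    n_per_cluster: int = 200,
    latent_dim: int = 10,
    n_features: tuple[int, int] = (60, 60),
    n_shared_features: int = 20,
    centroid_sd: float = 3.0,
    cluster_sd: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticScenario:
    """Two Gaussian-mixture datasets sharing ``m_shared`` of their clusters.

    Cluster centroids live in a common latent space.  Dataset A holds
    clusters ``c0..c{K-1}``; dataset B holds the first ``m_shared`` of
    those (same centroids, same labels) plus ``K - m_shared`` B-only
    clusters with fresh centroids.  Each dataset is observed through its
    own random linear map to its feature space, except for
    ``n_shared_features`` features produced by one map common to both
    datasets (the partial feature overlap a shared space can exploit).
    """
    if not 1 <= m_shared <= n_clusters:
        raise ValueError("m_shared must be in [1, n_clusters]")
    rng = np.random.default_rng(seed)
    n_bonly = n_clusters - m_shared
    # surplus candidates, greedy max-min subset: clusters are mutually
    # well-separated in the latent space (distinct populations)
    n_needed = n_clusters + n_bonly
    candidates = rng.normal(0.0, centroid_sd, size=(3 * n_needed, latent_dim))
    chosen = [0]
    while len(chosen) < n_needed:
        dists = np.min(
            np.linalg.norm(candidates[:, None] - candidates[chosen][None], axis=2),
            axis=1,
        )
        dists[chosen] = -1.0
        chosen.append(int(np.argmax(dists)))
    cent_a = candidates[chosen[:n_clusters]]
    cent_b = np.vstack([cent_a[:m_shared], candidates[chosen[n_clusters:]]])
    labels_a = np.array([f"c{i}" for i in range(n_clusters)])
    labels_b = np.concatenate(
        [labels_a[:m_shared], np.array([f"b{i}" for i in range(n_bonly)])]
    )

    shared_map = rng.normal(size=(latent_dim, n_shared_features))
    map_a = rng.normal(size=(latent_dim, n_features[0] - n_shared_features))
    map_b = rng.normal(size=(latent_dim, n_features[1] - n_shared_features))

    def sample(centroids: np.ndarray, labels: np.ndarray, own_map: np.ndarray,
               prefix: str, n_own: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
        latent = np.repeat(centroids, n_per_cluster, axis=0) + rng.normal(
            0.0, cluster_sd, size=(centroids.shape[0] * n_per_cluster, latent_dim)
        )
        shared_part = latent @ shared_map
        own_part = latent @ own_map
        mat = np.hstack([shared_part, own_part])
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
        names = [f"shared_{j}" for j in range(n_shared_features)] + [
            f"{prefix}_{j}" for j in range(n_own)
        ]
        labs = np.repeat(labels, n_per_cluster)
        return mat, labs, names

    mat_a, labs_a, names_a = sample(
        cent_a, labels_a, map_a, "fa", n_features[0] - n_shared_features
    )
    mat_b, labs_b, names_b = sample(
        cent_b, labels_b, map_b, "fb", n_features[1] - n_shared_features
    )
    blocks = [
        DataBlock("A", mat_a, names_a, labels=labs_a),
        DataBlock("B", mat_b, names_b, labels=labs_b),
    ]
    return SyntheticScenario(
        blocks=blocks,
        params={
            "n_clusters": n_clusters,
            "m_shared": m_shared,
            "n_per_cluster": n_per_cluster,
            "latent_dim": latent_dim,
            "n_features": n_features,
            "n_shared_features": n_shared_features,
            "shared_labels": list(labels_a[:m_shared]),
        },
        seed=seed,
    )
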