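"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain loops and scipy root finding,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def brute_sigma(distances, k=None):
    """Solve sum_j exp(-max(0, d_j - d_0) / sigma) = log2(k) by brentq."""
    d = list(distances)[: (k or len(distances))]
    rho = d[0]
    target = math.log2(len(d))

    def f(sigma):
        return sum(math.exp(-max(0.0, x - rho) / sigma) for x in d) - target

    lo, hi = 1e-12, 1e6 * (max(d) + 1.0)
    if f(lo) > 0 or f(hi) < 0:  # unattainable: ties at rho etc.
        return rho, lo
    return rho, brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)


def brute_fuzzy_graph(points, k):
    """Dense single-space fuzzy graph: kNN, calibration, strengths, union."""
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = math.sqrt(float(np.sum((points[i] - points[j]) ** 2)))
    directed = np.zeros((n, n))
    for i in range(n):
        order = [j for j in np.argsort(dist[i], kind="stable") if j != i][:k]
        drow = [dist[i, j] for j in order]
        rho, sigma = brute_sigma(drow)
        for j, dij in zip(order, drow):
            directed[i, j] = math.exp(-max(0.0, dij - rho) / sigma)
    sym = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = directed[i, j], directed[j, i]
            sym[i, j] = a + b - a * b
    return sym


def brute_knn(points, k):
    """All-pairs sort kNN (indices and distances), self excluded."""
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    idx = np.zeros((n, k), dtype=int)
    dis = np.zeros((n, k))
    for i in range(n):
        d = [
            (math.sqrt(float(np.sum((points[i] - points[j]) ** 2))), j)
            for j in range(n)
            if j != i
        ]
        d.sort()
        for c in range(k):
            dis[i, c], idx[i, c] = d[c]
    return idx, dis


def brute_balanced_accuracy(true_labels, predicted):
    classes = sorted(set(true_labels))
    recalls = []
    for c in classes:
        hits = sum(1 for t, p in zip(true_labels, predicted) if t == c and p == c)
        total = sum(1 for t in true_labels if t == c)
        recalls.append(hits / total)
    return sum(recalls) / len(recalls)


def brute_silhouette(points, labels):
    """Mean silhouette with explicit a/b loops; singleton classes score 0."""
    points = np.asarray(points, dtype=np.float64)
    n = len(labels)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = math.inf
        for c in set(labels) - {labels[i]}:
            others = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([np.linalg.norm(points[i] - points[j]) for j in others]))
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


def brute_alignment(points, dataset_ids, k=5):
    points = np.asarray(points, dtype=np.float64)
    n = len(dataset_ids)
    fracs = []
    for i in range(n):
        d = sorted(
            (np.linalg.norm(points[i] - points[j]), j) for j in range(n) if j != i
        )
        nbrs = [j for _, j in d[:k]]
        fracs.append(np.mean([dataset_ids[j] != dataset_ids[i] for j in nbrs]))
    return float(np.mean(fracs))


def brute_structure(high, low):
    high = np.asarray(high, dtype=np.float64)
    low = np.asarray(low, dtype=np.float64)
    n = high.shape[0]
    dh, dl = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dh.append(np.linalg.norm(high[i] - high[j]))
            dl.append(np.linalg.norm(low[i] - low[j]))
    dh, dl = np.array(dh), np.array(dl)
    return float(
        np.sum((dh - dh.mean()) * (dl - dl.mean()))
        / math.sqrt(np.sum((dh - dh.mean()) ** 2) * np.sum((dl - dl.mean()) ** 2))
    )
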