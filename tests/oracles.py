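"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the library code paths they check: DBSCAN is the
textbook queue algorithm on a full O(n^2) distance matrix, nearest-neighbor
deduplication is exhaustive pair enumeration, and straightness comes from an
explicit eigen-decomposition of the 2x2 scatter matrix.
"""

from __future__ import annotations

import numpy as np


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN: returns a label per point, -1 for noise.

    Points are visited in ascending index order; border points keep the
    label of the first cluster that reaches them.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            p = stack.pop()
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        stack.append(q)
        cluster += 1
    return labels


def brute_nn_dedup(points: np.ndarray) -> list[float]:
    """Deduplicated nearest-neighbor distances by exhaustive enumeration:
    the set {unordered pair (i, argmin_j d(i, j))} with set semantics."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    pairs = set()
    for i in range(n):
        best, best_j = np.inf, -1
        for j in range(n):
            if j == i:
                continue
            dij = float(np.linalg.norm(points[i] - points[j]))
            if dij < best:
                best, best_j = dij, j
        pairs.add(tuple(sorted((i, best_j))))
    return sorted(float(np.linalg.norm(points[i] - points[j])) for i, j in pairs)


def eigen_straightness(points: np.ndarray) -> float:
    """R^2 about the total-least-squares line via explicit 2x2 eigenvalues."""
    pts = np.asarray(points, dtype=float)
    c = pts - pts.mean(axis=0)
    sxx = float((c[:, 0] ** 2).sum())
    syy = float((c[:, 1] ** 2).sum())
    sxy = float((c[:, 0] * c[:, 1]).sum())
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = np.sqrt(max(tr**2 / 4 - det, 0.0))
    lam1 = tr / 2 + disc
    return lam1 / tr


def rotate(points: np.ndarray, theta: float, shift=(0.0, 0.0)) -> np.ndarray:
    r = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return np.asarray(points, dtype=float) @ r.T + np.asarray(shift)
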