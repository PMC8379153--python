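"""Grouping emitter clusters into origami objects, selection filters, and
row/line structure fitting for the rectangular design.

Straightness is measured with a rotation-invariant total-least-squares R^2
(principal-axis decomposition of the centroid scatter), so that randomly
oriented objects are judged purely on collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .clustering import EmitterCluster, table_coords

__all__ = [
    "OrigamiObject",
    "RoiSelectionParams",
    "TwoRowFit",
    "SelectionResult",
    "group_clusters",
    "straightness",
    "principal_axis",
    "select_linear_objects",
    "select_rois",
    "segment_structures",
    "fit_two_rows",
    "select_rows",
    "project_onto_axis",
]

UM_TO_NM = 1000.0


def _centroids(clusters: Sequence[EmitterCluster] | np.ndarray) -> np.ndarray:
    if isinstance(clusters, np.ndarray):
        arr = np.asarray(clusters, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("centroid array must be (n, 2)")
        return arr
    return np.asarray([c.centroid for c in clusters], dtype=float)


@dataclass(frozen=True)
class OrigamiObject:
    """A selected group of emitter clusters with its line statistics."""

    clusters: tuple[EmitterCluster, ...]
    straightness: float
    axis: tuple[float, float]
    kind: Literal["linear", "rectangular_row"] = "linear"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def centroids(self) -> np.ndarray:
        return _centroids(self.clusters)


@dataclass(frozen=True)
class RoiSelectionParams:
    """Density rule for rectangular-origami regions of interest: windows of
    ``roi_area`` um^2 containing more than ``min_localizations`` points."""

    min_localizations: int = 30
    roi_area: float = 4.0
    grouping_radius: float = 100.0

    def __post_init__(self) -> None:
        if self.min_localizations <= 0 or self.roi_area <= 0 or self.grouping_radius <= 0:
            raise ValueError("all ROI selection parameters must be positive")


@dataclass(frozen=True)
class TwoRowFit:
    """Two parallel rows fitted to one rectangular-origami ROI."""

    common_direction: tuple[float, float]
    row_offsets: tuple[float, float]  # perpendicular intercepts, nm
    assignments: np.ndarray  # row label (0/1) per ROI localization

    @property
    def row_spacing(self) -> float:
        return float(abs(self.row_offsets[1] - self.row_offsets[0]))


@dataclass(frozen=True)
class SelectionResult:
    """Accepted objects plus the bookkeeping of how many candidates passed.

    ``accepted_indices[i]`` is the position of ``objects[i]`` in the input
    candidate list."""

    objects: tuple[OrigamiObject, ...]
    n_candidates: int
    accepted_indices: tuple[int, ...] = ()

    @property
    def n_selected(self) -> int:
        return len(self.objects)

    @property
    def selection_rate(self) -> float:
        return self.n_selected / self.n_candidates if self.n_candidates else float("nan")


def group_clusters(
    clusters: Sequence[EmitterCluster], grouping_radius: float = 100.0
) -> list[list[EmitterCluster]]:
    """Single-linkage grouping of clusters into candidate origami objects.

    Two clusters share an object iff a chain of clusters connects them with
    consecutive centroid distances <= ``grouping_radius``.  Components are
    returned ordered by their minimum centroid (x, y).
    """
    if grouping_radius <= 0:
        raise ValueError("grouping_radius must be positive")
    if not clusters:
        return []
    pts = _centroids(clusters)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(grouping_radius, output_type="ndarray")
    n = len(clusters)
    if len(pairs):
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = csr_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    groups = []
    for comp in range(n_comp):
        members = [clusters[i] for i in np.flatnonzero(labels == comp)]
        members.sort(key=lambda c: c.centroid)
        groups.append(members)
    groups.sort(key=lambda g: g[0].centroid)
    return groups


def principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal direction and eigenvalues of centered 2D scatter.

    Returns ``(axis, eigvals)`` with ``axis`` the unit eigenvector of the
    largest eigenvalue and ``eigvals`` sorted descending.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    axis = vecs[:, 1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis  # fix sign for determinism
    return axis, vals[::-1]


def straightness(clusters: Sequence[EmitterCluster] | np.ndarray) -> float:
    """Total-least-squares R^2 of cluster centroids about their best line.

    ``R^2 = 1 - SS_perp / SS_total`` where ``SS_perp`` is the sum of squared
    perpendicular residuals about the principal axis and ``SS_total`` the
    total centroid scatter about the mean.  Exactly collinear centroids give
    1; isotropic scatter gives about 0.5.  Requires >= 3 clusters; identical
    centroids are an error (the line is undefined).
    """
    pts = _centroids(clusters)
    if len(pts) < 3:
        raise ValueError("straightness requires at least 3 clusters")
    _, vals = principal_axis(pts)
    total = float(vals.sum())
    if total <= 0.0:
        raise ValueError("straightness undefined: all centroids identical")
    return float(vals[0] / total)


def _make_object(
    clusters: Sequence[EmitterCluster], kind: str
) -> OrigamiObject:
    pts = _centroids(clusters)
    axis, vals = principal_axis(pts)
    total = float(vals.sum())
    r2 = float(vals[0] / total) if total > 0 else float("nan")
    return OrigamiObject(
        clusters=tuple(clusters),
        straightness=r2,
        axis=(float(axis[0]), float(axis[1])),
        kind=kind,  # type: ignore[arg-type]
    )


def select_linear_objects(
    candidates: Sequence[Sequence[EmitterCluster]],
    min_clusters: int = 5,
    r2_min: float = 0.9,
    kind: str = "linear",
) -> SelectionResult:
    """Keep candidates with >= ``min_clusters`` clusters lying on a straight
    line (TLS R^2 strictly above ``r2_min``)."""
    accepted = []
    indices = []
    for i, cand in enumerate(candidates):
        if len(cand) < max(min_clusters, 3):
            continue
        obj = _make_object(cand, kind)
        if obj.straightness > r2_min:
            accepted.append(obj)
            indices.append(i)
    return SelectionResult(
        objects=tuple(accepted),
        n_candidates=len(candidates),
        accepted_indices=tuple(indices),
    )


def select_rois(
    table: pd.DataFrame, params: RoiSelectionParams | None = None
) -> list[pd.DataFrame]:
    """Select dense regions of interest from a localization table.

    The field is tiled with square windows of area ``roi_area`` on a grid
    with half-window step; windows containing strictly more than
    ``min_localizations`` points are kept, overlapping kept windows are
    merged, and each merged region's localizations form one ROI (returned as
    a sub-DataFrame preserving original row indices).
    """
    params = params or RoiSelectionParams()
    if len(table) == 0:
        return []
    pts = table_coords(table)
    side = float(np.sqrt(params.roi_area)) * UM_TO_NM
    step = side / 2.0
    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    # Count per half-window cell; a window is a 2x2 block of cells.
    ix = np.floor((pts[:, 0] - x0) / step).astype(int)
    iy = np.floor((pts[:, 1] - y0) / step).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    counts = np.zeros((nx + 1, ny + 1), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    # window (i, j) covers cells {i, i+1} x {j, j+1}, origin at x0 + i*step
    win = (
        counts[:-1, :-1] + counts[1:, :-1] + counts[:-1, 1:] + counts[1:, 1:]
    )
    keep = np.argwhere(win > params.min_localizations)
    if len(keep) == 0:
        return []
    # Merge kept windows that overlap (grid neighbors within one step).
    m = len(keep)
    tree = cKDTree(keep.astype(float))
    pairs = tree.query_pairs(1.5, output_type="ndarray")  # chebyshev<=1 via r<1.5
    adj = (
        csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m))
        if len(pairs)
        else csr_matrix((m, m))
    )
    n_comp, labels = connected_components(adj, directed=False)
    cell_of_point = ix * (ny + 1) + iy
    rois = []
    order = sorted(range(n_comp), key=lambda c: tuple(keep[labels == c].min(axis=0)))
    for comp in order:
        cells = set()
        for i, j in keep[labels == comp]:
            cells.update(
                {
                    i * (ny + 1) + j,
                    (i + 1) * (ny + 1) + j,
                    i * (ny + 1) + (j + 1),
                    (i + 1) * (ny + 1) + (j + 1),
                }
            )
        mask = np.isin(cell_of_point, list(cells))
        rois.append(table.iloc[np.flatnonzero(mask)])
    return rois


def segment_structures(
    roi: pd.DataFrame, radius: float = 150.0, min_points: int = 10
) -> list[pd.DataFrame]:
    """Split an ROI into spatially connected structures.

    Density-selected ROIs are merged 2x2 um windows and can cover more than
    one origami; single-linkage components at ``radius`` (well above
    within-origami gaps, well below inter-origami distances in sparse
    fields) separate them.  Components with fewer than ``min_points``
    localizations (stray background) are dropped.
    """
    if len(roi) == 0:
        return []
    pts = table_coords(roi)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(roi)
    adj = (
        csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        if len(pairs)
        else csr_matrix((n, n))
    )
    n_comp, labels = connected_components(adj, directed=False)
    out = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if len(idx) >= min_points:
            out.append(roi.iloc[idx])
    out.sort(key=lambda df: (float(df["x_nm"].min()), float(df["y_nm"].min())))
    return out


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def _trim_to_core(pts: np.ndarray) -> np.ndarray:
    """Indices of points within a robust radius of the ROI's dense core.

    Guards the principal-axis estimate against the occasional background
    localization far from the origami inside a merged window.
    """
    center = np.median(pts, axis=0)
    d = np.linalg.norm(pts - center, axis=1)
    cut = max(10.0 * _mad(d), 200.0)
    return np.flatnonzero(d <= cut)


def _two_means_1d(t: np.ndarray) -> np.ndarray:
    """Deterministic 1D 2-means labels (0 = lower row), initialized at the
    25th/75th percentiles."""
    centers = np.percentile(t, [25.0, 75.0])
    lab = np.zeros(len(t), dtype=int)
    for _ in range(100):
        lab = (t > centers.mean()).astype(int)
        if lab.min() == lab.max():
            raise ValueError("degenerate ROI: one row empty after split")
        new = np.array([t[lab == 0].mean(), t[lab == 1].mean()])
        if np.max(np.abs(new - centers)) < 1e-6:
            break
        centers = new
    return lab


def fit_two_rows(roi: pd.DataFrame, min_pts: int = 5) -> TwoRowFit:
    """Fit two parallel rows to a rectangular-origami ROI.

    The common row direction and the two perpendicular intercepts are found
    by an alternating parallel-line fit: localizations are split by
    deterministic 1D 2-means on the perpendicular coordinate, the common
    direction is re-estimated as the principal axis of the *within-row
    centered* points (so unequal row extents cannot tilt it), and the split
    is repeated until stable.  Row offsets are robust (MAD-trimmed) means
    of the perpendicular coordinates; every localization is assigned to the
    nearer row.
    """
    if len(roi) < 2 * min_pts:
        raise ValueError(f"ROI too small: {len(roi)} < {2 * min_pts} localizations")
    pts = table_coords(roi)
    core = _trim_to_core(pts)
    cpts = pts[core]
    axis, _ = principal_axis(cpts)
    lab = None
    for _ in range(20):
        perp = np.array([-axis[1], axis[0]])
        t = cpts @ perp
        new_lab = _two_means_1d(t)
        if lab is not None and np.array_equal(new_lab, lab):
            break
        lab = new_lab
        # principal axis of within-row centered points: the two-parallel-line
        # total-least-squares direction given the current split
        centered = cpts.copy()
        for j in (0, 1):
            centered[lab == j] -= cpts[lab == j].mean(axis=0)
        axis, _ = principal_axis(centered)
    perp = np.array([-axis[1], axis[0]])
    t = cpts @ perp
    offsets = []
    for j in (0, 1):
        tj = t[lab == j]
        mad = _mad(tj)
        keep = np.abs(tj - np.median(tj)) <= max(5.0 * mad, 1.0)
        offsets.append(float(tj[keep].mean()))
    offsets = sorted(offsets)
    t_all = pts @ perp
    assignments = (np.abs(t_all - offsets[1]) < np.abs(t_all - offsets[0])).astype(int)
    return TwoRowFit(
        common_direction=(float(axis[0]), float(axis[1])),
        row_offsets=(offsets[0], offsets[1]),
        assignments=assignments,
    )


def select_rows(
    row_clusters: Sequence[Sequence[EmitterCluster]],
    min_clusters: int = 3,
    r2_min: float = 0.9,
) -> SelectionResult:
    """Row-level selection for the rectangular design: a row is kept if it
    has >= ``min_clusters`` clusters on a straight line (R^2 > ``r2_min``)."""
    return select_linear_objects(
        row_clusters, min_clusters=min_clusters, r2_min=r2_min, kind="rectangular_row"
    )


def project_onto_axis(points: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Signed scalar projections of points onto a unit direction, about the
    points' centroid.  Used for 1D multi-Gaussian fitting of row profiles."""
    pts = np.asarray(points, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / norm
    return (pts - pts.mean(axis=0)) @ d
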