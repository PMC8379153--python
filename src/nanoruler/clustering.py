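"""Emitter clustering: DBSCAN for linear origami, blurred-image local-maxima
seeded K-means for densely labeled rectangular origami.

DBSCAN on raw localization coordinates resolves emitters down to roughly the
cluster-cloud width times a small factor; for the 11-nm rectangular design it
merges neighboring sites, so those fields are clustered by finding local
maxima in a Gaussian-blurred rendered image and using them to seed Lloyd's
K-means on the raw coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from sklearn.cluster import DBSCAN

__all__ = [
    "ClusteringParams",
    "EmitterCluster",
    "KMeansResult",
    "cluster_dbscan",
    "render_blurred",
    "lloyd_kmeans",
    "maxima_seeded_kmeans",
    "table_coords",
]

Bounds = tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)


@dataclass(frozen=True)
class ClusteringParams:
    """Parameters for both clustering routes.

    eps / min_pts are the DBSCAN neighborhood radius (nm) and minimum
    neighborhood size (point itself included).  blur_sigma, render_pixel,
    maxima_min_distance and maxima_threshold control the rendered-image
    maxima used to seed K-means: the blurred image has an effective spot
    width of sqrt(cloud_sigma^2 + blur_sigma^2), which must stay below
    about half the site spacing for neighboring sites to remain separable.
    """

    eps: float = 10.0
    min_pts: int = 5
    blur_sigma: float = 1.5
    render_pixel: float = 2.0
    maxima_min_distance: float = 5.0
    maxima_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.blur_sigma <= 0 or self.render_pixel <= 0:
            raise ValueError("blur_sigma and render_pixel must be positive")
        if not (0.0 < self.maxima_threshold < 1.0):
            raise ValueError("maxima_threshold must be in (0, 1)")
        if self.maxima_min_distance <= 0:
            raise ValueError("maxima_min_distance must be positive")


@dataclass(frozen=True)
class EmitterCluster:
    """One dye's localization cloud: centroid plus membership."""

    centroid: tuple[float, float]
    member_indices: np.ndarray  # row indices into the source table

    @property
    def n_localizations(self) -> int:
        return int(len(self.member_indices))


def table_coords(table: pd.DataFrame) -> np.ndarray:
    """Extract an (n, 2) float coordinate array from a molecule list."""
    return np.column_stack(
        [np.asarray(table["x_nm"], dtype=float), np.asarray(table["y_nm"], dtype=float)]
    )


def _sorted_clusters(
    points: np.ndarray, labels: np.ndarray, min_members: int = 1
) -> list[EmitterCluster]:
    """Build EmitterClusters from a label array, ordered by centroid (x, y)."""
    out = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_members:
            continue
        c = points[idx].mean(axis=0)
        out.append(EmitterCluster(centroid=(float(c[0]), float(c[1])), member_indices=idx))
    out.sort(key=lambda cl: cl.centroid)
    return out


def cluster_dbscan(
    table: pd.DataFrame, params: ClusteringParams | None = None
) -> list[EmitterCluster]:
    """DBSCAN emitter clustering on localization coordinates.

    Standard DBSCAN semantics with the Euclidean metric: a core point has at
    least ``min_pts`` points (itself included) within ``eps``; clusters are
    connected components of core points plus reachable border points; noise
    is dropped.  Border points reachable from several clusters go to the
    cluster discovered first in ascending row order.  Returns clusters
    ordered by centroid (x, y).
    """
    params = params or ClusteringParams()
    if len(table) == 0:
        return []
    points = table_coords(table)
    if not np.all(np.isfinite(points)):
        raise ValueError("localization coordinates must be finite")
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(points)
    return _sorted_clusters(points, labels)


def render_blurred(
    table: pd.DataFrame,
    params: ClusteringParams | None = None,
    bounds: Bounds | None = None,
) -> tuple[np.ndarray, Bounds]:
    """2D localization histogram convolved with a Gaussian kernel.

    Returns ``(image, bounds)`` where ``image[row, col]`` maps row -> y and
    col -> x; the center of pixel ``(row, col)`` is at
    ``(xmin + (col + 0.5) * render_pixel, ymin + (row + 0.5) * render_pixel)``.
    Total intensity equals the localization count up to boundary truncation
    of the kernel.
    """
    params = params or ClusteringParams()
    points = table_coords(table)
    if bounds is None:
        if len(points) == 0:
            raise ValueError("bounds are required for an empty table")
        pad = 3.0 * params.blur_sigma + params.render_pixel
        bounds = (
            float(points[:, 0].min() - pad),
            float(points[:, 0].max() + pad),
            float(points[:, 1].min() - pad),
            float(points[:, 1].max() + pad),
        )
    xmin, xmax, ymin, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounds {bounds}")
    px = params.render_pixel
    nx = max(1, int(np.ceil((xmax - xmin) / px)))
    ny = max(1, int(np.ceil((ymax - ymin) / px)))
    hist, _, _ = np.histogram2d(
        points[:, 1],
        points[:, 0],
        bins=[ny, nx],
        range=[[ymin, ymin + ny * px], [xmin, xmin + nx * px]],
    )
    image = gaussian_filter(hist, sigma=params.blur_sigma / px, mode="constant")
    return image, (xmin, xmin + nx * px, ymin, ymin + ny * px)


@dataclass(frozen=True)
class KMeansResult:
    centers: np.ndarray  # (k, 2)
    labels: np.ndarray  # (n,)
    n_iter: int
    converged: bool
    objective_trace: np.ndarray  # within-cluster sum of squares per iteration


def lloyd_kmeans(
    points: np.ndarray,
    init_centers: np.ndarray,
    tol_nm: float = 0.1,
    max_iter: int = 100,
) -> KMeansResult:
    """Deterministic Lloyd's K-means from fixed initial centers.

    Iterates assignment / centroid update until the largest centroid shift
    falls below ``tol_nm`` or ``max_iter`` is reached.  Clusters that lose
    all members keep their previous center (and end up empty).  The
    within-cluster sum of squares is recorded per iteration; it is
    non-increasing, which is tested as an invariant.
    """
    points = np.asarray(points, dtype=float)
    centers = np.array(init_centers, dtype=float, copy=True)
    if centers.ndim != 2 or centers.shape[1] != points.shape[1]:
        raise ValueError("init_centers must be (k, ndim)")
    k = len(centers)
    labels = np.zeros(len(points), dtype=int)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(points)), labels].sum()))
        new_centers = centers.copy()
        for j in range(k):
            members = points[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1))) if k else 0.0
        centers = new_centers
        if shift < tol_nm:
            converged = True
            break
    return KMeansResult(
        centers=centers,
        labels=labels,
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def find_maxima(
    table: pd.DataFrame,
    params: ClusteringParams | None = None,
    bounds: Bounds | None = None,
) -> np.ndarray:
    """Local maxima of the blurred rendered image, in nm coordinates.

    Maxima are separated by at least ``maxima_min_distance`` and must reach
    ``maxima_threshold`` times the image maximum.
    """
    params = params or ClusteringParams()
    image, used_bounds = render_blurred(table, params, bounds)
    min_dist_px = max(1, int(round(params.maxima_min_distance / params.render_pixel)))
    peaks = peak_local_max(
        image,
        min_distance=min_dist_px,
        threshold_rel=params.maxima_threshold,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    xmin, _, ymin, _ = used_bounds
    px = params.render_pixel
    return np.column_stack(
        [xmin + (peaks[:, 1] + 0.5) * px, ymin + (peaks[:, 0] + 0.5) * px]
    )


def maxima_seeded_kmeans(
    table: pd.DataFrame,
    params: ClusteringParams | None = None,
    bounds: Bounds | None = None,
) -> list[EmitterCluster]:
    """Cluster localizations by K-means seeded at blurred-image maxima.

    The number of local maxima sets k and their positions the initial
    centers; Lloyd's algorithm then runs on the raw coordinates.  Clusters
    with fewer than ``min_pts`` members are discarded.  Returns clusters
    ordered by centroid (x, y); an input with no detectable maxima yields an
    empty list.
    """
    params = params or ClusteringParams()
    if len(table) == 0:
        return []
    seeds = find_maxima(table, params, bounds)
    if len(seeds) == 0:
        return []
    points = table_coords(table)
    result = lloyd_kmeans(points, seeds)
    return _sorted_clusters(points, result.labels, min_members=params.min_pts)
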