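"""Nearest-neighbor distance statistics, first-peak Gaussian fitting,
expansion rescaling, and the per-emitter gel-distortion estimator.

The quantitative core: each origami object contributes the Euclidean
distances from every cluster centroid to its nearest neighbor within the
same object, with mutual pairs counted once.  The first peak of the pooled
histogram is fitted with a Gaussian; comparing its width before and after
origami denaturation isolates the positional error the gel itself adds to
each emitter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.spatial.distance import cdist

from .geometry import OrigamiObject

__all__ = [
    "FWHM_FACTOR",
    "NNDistanceSet",
    "PeakFit",
    "DistortionEstimate",
    "MergedClusterReport",
    "nn_distances",
    "pool_nn_distances",
    "apply_expansion",
    "fit_first_peak",
    "estimate_distortion",
    "fit_multi_gaussian_1d",
    "merged_cluster_diagnostic",
]

#: FWHM of a Gaussian divided by its standard deviation.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class NNDistanceSet:
    """Pooled nearest-neighbor distances (nm), post-division by any applied
    expansion factor ("effective distances")."""

    distances: np.ndarray
    source: np.ndarray  # object/row identifier per distance
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        s = np.asarray(self.source)
        if d.ndim != 1 or s.shape != d.shape:
            raise ValueError("distances and source must be matching 1D arrays")
        if np.any(d <= 0):
            raise ValueError("all distances must be positive")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "source", s)

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class PeakFit:
    """Gaussian fitted to one histogram peak by unweighted least squares."""

    mean: float
    sigma: float
    amplitude: float
    fit_window: tuple[float, float]
    bin_width: float
    converged: bool
    n_distances: int = 0
    message: str = ""


@dataclass(frozen=True)
class DistortionEstimate:
    """Per-emitter positional error inferred from pre/post peak widths.

    ``sigma_emitter = sqrt((sigma_post^2 - sigma_pre^2) / 2)``: each of the
    two emitters in a nearest-neighbor distance receives an independent
    displacement whose component along the inter-emitter axis is Gaussian,
    so the added pairwise variance is twice the per-emitter variance
    (transverse second-order terms neglected; valid for spacing >> error).
    """

    sigma_pre: float
    sigma_post: float
    sigma_emitter: float
    fwhm_emitter: float
    valid: bool


def _nn_pairs(points: np.ndarray) -> set[tuple[int, int]]:
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    return {tuple(sorted((i, int(j)))) for i, j in enumerate(nn)}


def nn_distances(
    obj: OrigamiObject | np.ndarray, source_id: object = 0
) -> NNDistanceSet:
    """Deduplicated nearest-neighbor distances within one object.

    For each cluster centroid, the Euclidean distance to its nearest
    neighbor in the same object; the resulting unordered pairs are counted
    once each (a mutual nearest-neighbor pair contributes one distance).
    """
    pts = obj.centroids if isinstance(obj, OrigamiObject) else np.asarray(obj, float)
    if len(pts) < 2:
        raise ValueError("nn_distances requires at least 2 clusters")
    pairs = sorted(_nn_pairs(pts))
    dists = np.array([float(np.linalg.norm(pts[i] - pts[j])) for i, j in pairs])
    return NNDistanceSet(
        distances=dists, source=np.full(len(dists), source_id, dtype=object)
    )


def pool_nn_distances(objects: Sequence[OrigamiObject]) -> NNDistanceSet:
    """Concatenate per-object NN distance sets, tagging each distance with
    its object index."""
    if not objects:
        return NNDistanceSet(distances=np.empty(0), source=np.empty(0, dtype=object))
    parts = [nn_distances(obj, source_id=i) for i, obj in enumerate(objects)]
    return NNDistanceSet(
        distances=np.concatenate([p.distances for p in parts]),
        source=np.concatenate([p.source for p in parts]),
    )


def apply_expansion(nnd: NNDistanceSet, factor: float) -> NNDistanceSet:
    """Divide all distances by the gel expansion factor, giving effective
    (pre-expansion) distances.  ``factor`` must be >= 1."""
    if factor < 1.0:
        raise ValueError(f"expansion factor must be >= 1, got {factor}")
    return NNDistanceSet(
        distances=nnd.distances / factor,
        source=nnd.source,
        expansion_factor=nnd.expansion_factor * factor,
    )


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_first_peak(
    nnd: NNDistanceSet | np.ndarray,
    expected_spacing: float,
    bin_width: float = 2.0,
    window: tuple[float, float] | None = None,
    min_distances: int = 30,
) -> PeakFit:
    """Fit a Gaussian to the first nearest-neighbor-distance peak.

    The distances are histogrammed at ``bin_width`` and
    ``A exp(-(d - mu)^2 / (2 sigma^2))`` is fitted by unweighted least
    squares to the bin centers/counts inside ``window`` (default
    ``[0.5, 1.5] * expected_spacing``), starting from ``mu =
    expected_spacing``, ``sigma = 0.3 * expected_spacing`` and ``A`` the
    maximum bin count.  Failure modes (too few distances, a degenerate
    histogram, optimizer failure, or a fitted mean escaping the window)
    yield ``converged=False`` with a diagnostic message, never a silent
    number.
    """
    d = nnd.distances if isinstance(nnd, NNDistanceSet) else np.asarray(nnd, float)
    if expected_spacing <= 0 or bin_width <= 0:
        raise ValueError("expected_spacing and bin_width must be positive")
    lo, hi = window if window is not None else (
        0.5 * expected_spacing,
        1.5 * expected_spacing,
    )
    fail = lambda msg: PeakFit(  # noqa: E731
        mean=float("nan"),
        sigma=float("nan"),
        amplitude=float("nan"),
        fit_window=(lo, hi),
        bin_width=bin_width,
        converged=False,
        n_distances=int(np.sum((d >= lo) & (d <= hi))),
        message=msg,
    )
    in_win = d[(d >= lo) & (d <= hi)]
    if len(in_win) < min_distances:
        return fail(f"only {len(in_win)} distances in window, need {min_distances}")
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(in_win, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 4:
        return fail("degenerate histogram: fewer than 4 occupied bins")
    p0 = (float(counts.max()), expected_spacing, 0.3 * expected_spacing)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gauss, centers, counts.astype(float), p0=p0, maxfev=10000
            )
    except (RuntimeError, ValueError) as exc:
        return fail(f"optimizer failure: {exc}")
    a, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if not (lo < mu < hi) or not np.isfinite(sigma) or sigma <= 0:
        return fail(f"fit escaped window: mu={mu:.2f}, sigma={sigma:.2f}")
    return PeakFit(
        mean=mu,
        sigma=sigma,
        amplitude=a,
        fit_window=(lo, hi),
        bin_width=bin_width,
        converged=True,
        n_distances=len(in_win),
    )


def estimate_distortion(fit_pre: PeakFit, fit_post: PeakFit) -> DistortionEstimate:
    """Per-emitter gel distortion from pre/post-denaturation peak widths.

    The variance excess of the post peak over the pre peak is divided by two
    (two independent per-emitter displacements per distance) and rooted.  A
    post width below the pre width — possible by sampling noise at small
    true distortion — yields a flagged zero rather than an imaginary number.
    """
    if not (fit_pre.converged and fit_post.converged):
        raise ValueError("estimate_distortion requires converged pre and post fits")
    var_excess = fit_post.sigma**2 - fit_pre.sigma**2
    if var_excess < 0:
        return DistortionEstimate(
            sigma_pre=fit_pre.sigma,
            sigma_post=fit_post.sigma,
            sigma_emitter=0.0,
            fwhm_emitter=0.0,
            valid=False,
        )
    sigma_e = math.sqrt(var_excess / 2.0)
    return DistortionEstimate(
        sigma_pre=fit_pre.sigma,
        sigma_post=fit_post.sigma,
        sigma_emitter=sigma_e,
        fwhm_emitter=FWHM_FACTOR * sigma_e,
        valid=True,
    )


def fit_multi_gaussian_1d(
    projected: np.ndarray,
    n_peaks: int,
    bin_width: float = 1.0,
    min_points_per_peak: int = 20,
) -> list[PeakFit]:
    """Least-squares sum-of-Gaussians fit to a 1D projected profile.

    The histogram's ``n_peaks`` highest local maxima initialize the peak
    means; amplitudes start at the local counts and all widths at one
    quarter of the median inter-maximum gap (or the data std for a single
    peak).  Returns per-peak fits sorted by mean; if fewer local maxima are
    detected than requested, all peaks are returned unconverged.
    """
    x = np.asarray(projected, dtype=float)
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    lo, hi = float(x.min()), float(x.max())
    edges = np.arange(lo, hi + bin_width, bin_width)
    fail = lambda msg: [  # noqa: E731
        PeakFit(
            mean=float("nan"),
            sigma=float("nan"),
            amplitude=float("nan"),
            fit_window=(lo, hi),
            bin_width=bin_width,
            converged=False,
            n_distances=len(x),
            message=msg,
        )
    ] * n_peaks
    if len(x) < n_peaks * min_points_per_peak:
        return fail(f"need >= {min_points_per_peak} points per peak")
    if len(edges) < 3:
        return fail("degenerate histogram range")
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # local maxima: strictly above one neighbor, not below the other
    c = counts.astype(float)
    is_max = np.zeros(len(c), dtype=bool)
    is_max[1:-1] = (c[1:-1] >= c[:-2]) & (c[1:-1] >= c[2:]) & (c[1:-1] > 0)
    is_max[0] = c[0] > c[1] if len(c) > 1 else c[0] > 0
    is_max[-1] = c[-1] > c[-2] if len(c) > 1 else False
    # suppress plateaus: keep the first bin of any run of equal maxima
    idx = np.flatnonzero(is_max)
    idx = idx[np.concatenate([[True], np.diff(centers[idx]) > bin_width * 1.5])] if len(idx) else idx
    if len(idx) < n_peaks:
        return fail(f"found {len(idx)} local maxima, need {n_peaks}")
    top = idx[np.argsort(c[idx])[::-1][:n_peaks]]
    top = np.sort(top)
    mus0 = centers[top]
    amps0 = np.maximum(c[top], 1.0)
    if n_peaks > 1:
        sig0 = max(float(np.median(np.diff(mus0))) / 4.0, bin_width / 2.0)
    else:
        sig0 = max(float(x.std()), bin_width / 2.0)

    def model(xx, *p):
        out = np.zeros_like(xx)
        for j in range(n_peaks):
            out = out + _gauss(xx, p[3 * j], p[3 * j + 1], p[3 * j + 2])
        return out

    p0 = []
    for j in range(n_peaks):
        p0 += [amps0[j], mus0[j], sig0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, centers, c, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return fail(f"optimizer failure: {exc}")
    fits = []
    for j in range(n_peaks):
        a, mu, sigma = float(popt[3 * j]), float(popt[3 * j + 1]), abs(float(popt[3 * j + 2]))
        fits.append(
            PeakFit(
                mean=mu,
                sigma=sigma,
                amplitude=a,
                fit_window=(lo, hi),
                bin_width=bin_width,
                converged=bool(lo <= mu <= hi and sigma > 0),
                n_distances=len(x),
            )
        )
    fits.sort(key=lambda f: f.mean)
    return fits


@dataclass(frozen=True)
class MergedClusterReport:
    """Signatures of erroneously merged clusters in a set of objects.

    Merged clusters reduce an object's cluster count below the designed site
    count and push nearest-neighbor distances past ~1.5x the design spacing
    (missing emitters produce the latter signature too; the cluster-count
    deficit distinguishes the causes)."""

    n_objects: int
    frac_objects_below_design: float
    frac_distances_above_1p5: float
    mean_nn_distance: float


def merged_cluster_diagnostic(
    objects: Sequence[OrigamiObject],
    expected_spacing: float,
    design_site_count: int,
) -> MergedClusterReport:
    if not objects:
        return MergedClusterReport(0, float("nan"), float("nan"), float("nan"))
    below = np.mean([obj.n_clusters < design_site_count for obj in objects])
    nnd = pool_nn_distances(objects)
    frac_long = float(np.mean(nnd.distances > 1.5 * expected_spacing))
    return MergedClusterReport(
        n_objects=len(objects),
        frac_objects_below_design=float(below),
        frac_distances_above_1p5=frac_long,
        mean_nn_distance=float(nnd.distances.mean()),
    )
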