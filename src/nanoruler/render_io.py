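"""Molecule-list IO, STORM image rendering, and the end-to-end pipeline.

The pipeline composes the package: (optionally) simulate a field, cluster
localizations into emitters, group and select origami objects, pool
nearest-neighbor distances, fit the first peak, and (for paired
pre/post-denaturation runs) estimate the per-emitter gel distortion.  All
outputs are plain CSV/JSON and are byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .clustering import (
    ClusteringParams,
    EmitterCluster,
    cluster_dbscan,
    maxima_seeded_kmeans,
    table_coords,
)
from .geometry import (
    OrigamiObject,
    RoiSelectionParams,
    SelectionResult,
    fit_two_rows,
    group_clusters,
    project_onto_axis,
    segment_structures,
    select_linear_objects,
    select_rois,
    select_rows,
)
from .stats import (
    NNDistanceSet,
    PeakFit,
    apply_expansion,
    estimate_distortion,
    fit_first_peak,
    fit_multi_gaussian_1d,
    pool_nn_distances,
)
from .synthetic import SimulationConfig, design_by_name, simulate_field

logger = logging.getLogger("nanoruler")

__all__ = [
    "RenderParams",
    "PipelineConfig",
    "read_localizations",
    "write_localizations",
    "render_storm",
    "LinearFieldResult",
    "RectFieldResult",
    "analyze_linear_field",
    "analyze_rectangular_field",
    "distortion_experiment",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("x_nm", "y_nm", "frame")


@dataclass(frozen=True)
class RenderParams:
    """STORM rendering convention: each localization drawn as an isotropic
    2D Gaussian of ``spot_sigma`` nm on a ``pixel_size`` nm grid.
    ``camera_pixel`` is carried as metadata (the raw-camera sampling the
    molecule list came from)."""

    spot_sigma: float = 8.0
    pixel_size: float = 5.0
    camera_pixel: float = 153.0

    def __post_init__(self) -> None:
        if self.spot_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("spot_sigma and pixel_size must be positive")


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a molecule-list CSV with columns ``x_nm, y_nm, frame``.

    Extra columns are preserved untouched.  Missing required columns or
    non-finite coordinates raise a parse error naming the offender.
    """
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ("x_nm", "y_nm"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or non-finite {col} at data line {bad[0] + 2}"
            )
        table[col] = vals.astype(float)
    table["frame"] = pd.to_numeric(table["frame"]).astype(np.int64)
    logger.info("read %d localizations from %s", len(table), path)
    return table


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees exact float64 round-trip through the text file
    table.to_csv(path, index=False, float_format="%.17g")


def render_storm(
    table: pd.DataFrame,
    params: RenderParams | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Render a super-resolution image as a sum of 2D Gaussians.

    Each localization contributes an isotropic Gaussian of sigma
    ``spot_sigma`` sampled on a ``pixel_size`` grid (implemented as a
    binned histogram convolved with the Gaussian kernel).  Total intensity
    equals the localization count up to boundary truncation.  Returns
    ``(image, bounds)`` with ``image[row, col]``: row -> y, col -> x.
    """
    params = params or RenderParams()
    pts = table_coords(table) if len(table) else np.empty((0, 2))
    if bounds is None:
        if len(pts) == 0:
            raise ValueError("bounds are required for an empty table")
        pad = 3.0 * params.spot_sigma + params.pixel_size
        bounds = (
            float(pts[:, 0].min() - pad),
            float(pts[:, 0].max() + pad),
            float(pts[:, 1].min() - pad),
            float(pts[:, 1].max() + pad),
        )
    xmin, xmax, ymin, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounds {bounds}")
    px = params.pixel_size
    nx = max(1, int(np.ceil((xmax - xmin) / px)))
    ny = max(1, int(np.ceil((ymax - ymin) / px)))
    if len(pts):
        hist, _, _ = np.histogram2d(
            pts[:, 1],
            pts[:, 0],
            bins=[ny, nx],
            range=[[ymin, ymin + ny * px], [xmin, xmin + nx * px]],
        )
    else:
        hist = np.zeros((ny, nx))
    image = gaussian_filter(hist, sigma=params.spot_sigma / px, mode="constant")
    return image, (xmin, xmin + nx * px, ymin, ymin + ny * px)


# ---------------------------------------------------------------------------
# High-level analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearFieldResult:
    """Full linear-origami analysis of one field."""

    clusters: list[EmitterCluster]
    selection: SelectionResult
    nnd: NNDistanceSet
    peak_fit: PeakFit


@dataclass(frozen=True)
class RectFieldResult:
    """Full rectangular-origami analysis of one field.

    ``row_spacings`` holds one recovered spacing per analyzed ROI;
    ``perp_sigmas`` the per-row Gaussian widths of the row-transverse
    profile; ``nnd``/``peak_fit`` describe within-row nearest-neighbor
    distances of the selected rows (effective distances if an expansion
    factor was applied).
    """

    n_rois: int
    row_spacings: np.ndarray
    perp_sigmas: np.ndarray
    row_selection: SelectionResult
    nnd: NNDistanceSet
    peak_fit: PeakFit


def analyze_linear_field(
    table: pd.DataFrame,
    clustering: ClusteringParams | None = None,
    grouping_radius: float = 100.0,
    min_clusters: int = 5,
    r2_min: float = 0.9,
    expected_spacing: float = 28.0,
    expansion_factor: float = 1.0,
    bin_width: float = 2.0,
) -> LinearFieldResult:
    """Linear-origami pipeline: DBSCAN -> group -> select -> NN -> peak fit.

    ``expected_spacing`` is the design spacing in pre-expansion nm; for an
    expanded field pass the physical ``expansion_factor`` and distances are
    rescaled to effective distances before fitting.
    """
    clustering = clustering or ClusteringParams()
    clusters = cluster_dbscan(table, clustering)
    candidates = group_clusters(clusters, grouping_radius)
    selection = select_linear_objects(candidates, min_clusters, r2_min)
    nnd = pool_nn_distances(selection.objects)
    if expansion_factor != 1.0:
        nnd = apply_expansion(nnd, expansion_factor)
    fit = fit_first_peak(nnd, expected_spacing, bin_width=bin_width)
    logger.info(
        "linear field: %d clusters, %d/%d objects selected, %d NN distances, "
        "first peak %.2f +/- %.2f nm (converged=%s)",
        len(clusters),
        selection.n_selected,
        selection.n_candidates,
        len(nnd),
        fit.mean,
        fit.sigma,
        fit.converged,
    )
    return LinearFieldResult(clusters=clusters, selection=selection, nnd=nnd, peak_fit=fit)


def analyze_rectangular_field(
    table: pd.DataFrame,
    clustering: ClusteringParams | None = None,
    roi_params: RoiSelectionParams | None = None,
    min_row_clusters: int = 3,
    r2_min: float = 0.9,
    expected_spacing: float = 11.0,
    expansion_factor: float = 1.0,
    bin_width: float = 2.0,
) -> RectFieldResult:
    """Rectangular-origami pipeline.

    ROIs are selected by localization density, two parallel rows fitted per
    ROI, each row clustered by blurred-maxima-seeded K-means, rows kept if
    >= ``min_row_clusters`` clusters are collinear, and within-row
    nearest-neighbor distances pooled and fitted.  ``expected_spacing`` is
    in pre-expansion nm; for expanded fields pass ``expansion_factor`` and
    note that the clustering/ROI geometry runs in imaged coordinates (site
    spacing appears at ``expansion_factor * expected_spacing``).
    """
    clustering = clustering or ClusteringParams()
    roi_params = roi_params or RoiSelectionParams()
    rois = select_rois(table, roi_params)
    row_spacings: list[float] = []
    perp_sigmas: list[float] = []
    row_cluster_sets: list[list[EmitterCluster]] = []
    structure_of_row: list[int] = []
    spacing_of_structure: list[float] = []
    n_structures = 0
    for roi in rois:
        for structure in segment_structures(roi, min_points=2 * clustering.min_pts):
            try:
                fit2 = fit_two_rows(structure, min_pts=clustering.min_pts)
            except ValueError:
                continue
            sid = n_structures
            n_structures += 1
            spacing_of_structure.append(fit2.row_spacing)
            pts = table_coords(structure)
            perp = np.array([-fit2.common_direction[1], fit2.common_direction[0]])
            profile = project_onto_axis(pts, perp)
            pfits = fit_multi_gaussian_1d(profile, n_peaks=2, bin_width=1.0)
            for pf in pfits:
                if pf.converged:
                    perp_sigmas.append(pf.sigma)
            for row_label in (0, 1):
                row_table = structure.iloc[np.flatnonzero(fit2.assignments == row_label)]
                if len(row_table) < clustering.min_pts:
                    continue
                row_clusters = maxima_seeded_kmeans(row_table, clustering)
                if row_clusters:
                    row_cluster_sets.append(row_clusters)
                    structure_of_row.append(sid)
    row_selection = select_rows(row_cluster_sets, min_clusters=min_row_clusters, r2_min=r2_min)
    # a structure's row spacing counts once it has at least one accepted row
    accepted_sids = sorted({structure_of_row[i] for i in row_selection.accepted_indices})
    row_spacings = [spacing_of_structure[s] for s in accepted_sids]
    nnd = pool_nn_distances(row_selection.objects)
    if expansion_factor != 1.0:
        nnd = apply_expansion(nnd, expansion_factor)
    fit = fit_first_peak(nnd, expected_spacing, bin_width=bin_width)
    logger.info(
        "rect field: %d ROIs, %d/%d rows selected, %d NN distances, "
        "first peak %.2f +/- %.2f nm (converged=%s)",
        len(rois),
        row_selection.n_selected,
        row_selection.n_candidates,
        len(nnd),
        fit.mean,
        fit.sigma,
        fit.converged,
    )
    return RectFieldResult(
        n_rois=len(rois),
        row_spacings=np.asarray(row_spacings),
        perp_sigmas=np.asarray(perp_sigmas),
        row_selection=row_selection,
        nnd=nnd,
        peak_fit=fit,
    )


def distortion_experiment(
    design_name: str = "linear84",
    config: SimulationConfig | None = None,
    gel_distortion: float = 16.0,
    n_replicates: int = 3,
    clustering: ClusteringParams | None = None,
    min_clusters: int = 3,
    window_frac: tuple[float, float] = (0.25, 1.75),
) -> dict[str, Any]:
    """Paired pre/post-denaturation distortion measurement on simulated data.

    Simulates ``n_replicates`` independent pre/post field pairs of the
    sparse linear design (each pair shares one seed, so the post field is
    the pre field plus per-site gel displacement), runs the full linear
    pipeline on each, fits the first nearest-neighbor peak of each
    condition, and averages the per-replicate distortion estimates — the
    same mean-over-experiments a bar-plot comparison of gel chemistries
    reports.

    The fit window defaults to ``[0.25, 1.75] x spacing``: the sparse
    design's first peak does not overlap the second (that is its purpose),
    so a window covering about +/-2.5 sigma of the broadened post peak is
    safe and estimates its width with less truncation than the default
    ``[0.5, 1.5]`` used for closely spaced peaks.
    """
    design = design_by_name(design_name)
    if design.kind != "linear":
        raise ValueError("distortion_experiment requires a linear design")
    config = config or SimulationConfig()
    spacing = _design_spacing(design_name)
    window = (window_frac[0] * spacing, window_frac[1] * spacing)
    grouping_radius = max(100.0, 2.5 * spacing)
    estimates = []
    replicates = []
    for rep in range(n_replicates):
        cfg = config.with_(seed=config.seed + rep, gel_distortion=gel_distortion)
        fits = {}
        for condition in ("pre", "post"):
            table, _ = simulate_field(design, cfg, condition)  # type: ignore[arg-type]
            res = analyze_linear_field(
                table,
                clustering=clustering,
                grouping_radius=grouping_radius,
                min_clusters=min_clusters,
                expected_spacing=spacing,
            )
            fits[condition] = fit_first_peak(res.nnd, spacing, window=window)
        est = estimate_distortion(fits["pre"], fits["post"])
        estimates.append(est)
        replicates.append(
            {
                "seed": cfg.seed,
                "sigma_pre_nm": est.sigma_pre,
                "sigma_post_nm": est.sigma_post,
                "sigma_emitter_nm": est.sigma_emitter,
                "n_pre": fits["pre"].n_distances,
                "n_post": fits["post"].n_distances,
            }
        )
    sigma_mean = float(np.mean([e.sigma_emitter for e in estimates]))
    from .stats import FWHM_FACTOR

    return {
        "design": design_name,
        "gel_distortion_nm": gel_distortion,
        "n_replicates": n_replicates,
        "sigma_emitter_nm": sigma_mean,
        "sigma_emitter_sd_nm": float(np.std([e.sigma_emitter for e in estimates])),
        "fwhm_emitter_nm": FWHM_FACTOR * sigma_mean,
        "replicates": replicates,
    }


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs, with documented defaults.

    ``design`` selects a preset ('linear28', 'linear84', 'rect11');
    ``condition`` chooses whether simulated gel displacement is applied.
    If ``input_path`` is set the molecule list is read from disk instead of
    simulated (the simulation block is then ignored).
    """

    design: str = "linear28"
    condition: str = "pre"
    input_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    roi: RoiSelectionParams = field(default_factory=RoiSelectionParams)
    #: None -> auto: max(100 nm, 2.5 x design spacing), which tolerates the
    #: gap left by one missing emitter while staying far below inter-object
    #: distances in sparse fields.
    grouping_radius: float | None = None
    min_clusters: int = 5
    min_row_clusters: int = 3
    r2_min: float = 0.9
    bin_width: float = 2.0
    analysis_expansion_factor: float = 1.0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        nested = {
            "simulation": SimulationConfig,
            "clustering": ClusteringParams,
            "roi": RoiSelectionParams,
        }
        for key, klass in nested.items():
            if key in raw:
                block = raw.pop(key)
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(block) - known
                if unknown:
                    raise ValueError(f"unknown keys in {key!r} block: {sorted(unknown)}")
                if "field_size" in block:
                    block["field_size"] = tuple(block["field_size"])
                kwargs[key] = klass(**block)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _clusters_frame(clusters: Sequence[EmitterCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": np.arange(len(clusters)),
            "x_nm": [c.centroid[0] for c in clusters],
            "y_nm": [c.centroid[1] for c in clusters],
            "n_locs": [c.n_localizations for c in clusters],
        }
    )


def _peak_fit_dict(fit: PeakFit) -> dict[str, Any]:
    return {
        "mean_nm": fit.mean,
        "sigma_nm": fit.sigma,
        "amplitude": fit.amplitude,
        "fit_window_nm": list(fit.fit_window),
        "bin_width_nm": fit.bin_width,
        "converged": fit.converged,
        "n_distances": fit.n_distances,
        "message": fit.message,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute simulate (optional) -> cluster -> select -> NN -> fit.

    Returns the summary dict; when ``outdir`` is given, also writes the
    intermediate CSVs (localizations, ground truth, clusters, distances)
    and ``summary.json``.  Re-running the same config reproduces identical
    outputs.
    """
    from . import __version__

    design = design_by_name(config.design)
    if config.input_path is not None:
        table = read_localizations(config.input_path)
        truth = None
    else:
        table, truth = simulate_field(design, config.simulation, config.condition)  # type: ignore[arg-type]
    summary: dict[str, Any] = {
        "version": __version__,
        "design": config.design,
        "condition": config.condition,
        "seed": config.simulation.seed,
        "n_localizations": int(len(table)),
        "parameters": config.to_dict(),
    }
    expected = _design_spacing(config.design)
    grouping_radius = (
        config.grouping_radius
        if config.grouping_radius is not None
        else max(100.0, 2.5 * expected)
    )
    if design.kind == "linear":
        res = analyze_linear_field(
            table,
            clustering=config.clustering,
            grouping_radius=grouping_radius,
            min_clusters=config.min_clusters,
            r2_min=config.r2_min,
            expected_spacing=expected,
            expansion_factor=config.analysis_expansion_factor,
            bin_width=config.bin_width,
        )
        summary.update(
            {
                "n_clusters": len(res.clusters),
                "n_candidates": res.selection.n_candidates,
                "n_selected_objects": res.selection.n_selected,
                "n_nn_distances": len(res.nnd),
                "first_peak": _peak_fit_dict(res.peak_fit),
            }
        )
        clusters = res.clusters
        distances = res.nnd.distances
    else:
        res = analyze_rectangular_field(
            table,
            clustering=config.clustering,
            roi_params=config.roi,
            min_row_clusters=config.min_row_clusters,
            r2_min=config.r2_min,
            expected_spacing=expected,
            expansion_factor=config.analysis_expansion_factor,
            bin_width=config.bin_width,
        )
        summary.update(
            {
                "n_rois": res.n_rois,
                "mean_row_spacing_nm": float(np.mean(res.row_spacings))
                if len(res.row_spacings)
                else None,
                "n_selected_rows": res.row_selection.n_selected,
                "n_nn_distances": len(res.nnd),
                "first_peak": _peak_fit_dict(res.peak_fit),
            }
        )
        clusters = [c for obj in res.row_selection.objects for c in obj.clusters]
        distances = res.nnd.distances
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_localizations(table, outdir / "localizations.csv")
        if truth is not None:
            truth.to_csv(outdir / "ground_truth.csv", index=False)
        _clusters_frame(clusters).to_csv(outdir / "clusters.csv", index=False)
        pd.DataFrame({"distance_nm": distances}).to_csv(
            outdir / "nn_distances.csv", index=False
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("wrote pipeline outputs to %s", outdir)
    return summary


def _design_spacing(name: str) -> float:
    design = design_by_name(name)
    xs = np.unique(np.round(design.site_positions[:, 0], 9))
    return float(np.min(np.diff(xs)))
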