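"""Synthetic STORM localization fields of DNA-origami nanorulers.

Generates molecule-list tables (``x_nm, y_nm, frame``) with the statistical
structure of single-molecule localization data acquired on surface-tethered
DNA origami: per-emitter localization clouds from dye blinking, incomplete
labeling, per-site structural jitter, optional per-site gel displacement
("post-denaturation" condition), isotropic expansion scaling, and uniform
background localizations.  A ground-truth sidecar records every designed
site so downstream estimators can be validated against known positions.

All coordinates are nanometers.  Field sizes are micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "OrigamiDesign",
    "SimulationConfig",
    "make_design",
    "design_by_name",
    "simulate_field",
    "DESIGN_PRESETS",
]

UM_TO_NM = 1000.0

Kind = Literal["linear", "rectangular"]
Condition = Literal["pre", "post"]


@dataclass(frozen=True)
class OrigamiDesign:
    """Labeling-site layout of one origami species, in its local frame.

    ``linear`` designs have all sites on one line; ``rectangular`` designs
    have two parallel rows of equally spaced sites.
    """

    name: str
    site_positions: np.ndarray  # (n_sites, 2) nm
    kind: Kind

    def __post_init__(self) -> None:
        pos = np.asarray(self.site_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("site_positions must be an (n>=2, 2) array")
        object.__setattr__(self, "site_positions", pos)

    @property
    def n_sites(self) -> int:
        return int(self.site_positions.shape[0])

    @property
    def radius(self) -> float:
        """Radius of the bounding circle about the design centroid (nm)."""
        c = self.site_positions.mean(axis=0)
        return float(np.max(np.linalg.norm(self.site_positions - c, axis=1)))


def make_design(
    kind: Kind,
    spacing: float,
    n_sites: int,
    row_spacing: float | None = None,
    name: str | None = None,
) -> OrigamiDesign:
    """Build a labeling-site design.

    Parameters
    ----------
    kind
        ``"linear"``: ``n_sites`` sites at ``(i * spacing, 0)``.
        ``"rectangular"``: two rows of ``n_sites`` each, at
        ``(i * spacing, 0)`` and ``(i * spacing, row_spacing)``.
    spacing
        Within-row site spacing (nm), > 0.
    n_sites
        Sites per row (>= 2).
    row_spacing
        Row separation (nm); required iff ``kind == "rectangular"``.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if n_sites < 2:
        raise ValueError(f"n_sites must be >= 2, got {n_sites}")
    x = np.arange(n_sites, dtype=float) * spacing
    if kind == "linear":
        if row_spacing is not None:
            raise ValueError("row_spacing only applies to rectangular designs")
        pos = np.column_stack([x, np.zeros(n_sites)])
        name = name or f"linear{spacing:g}"
    elif kind == "rectangular":
        if row_spacing is None or row_spacing <= 0:
            raise ValueError("rectangular designs require positive row_spacing")
        pos = np.vstack(
            [
                np.column_stack([x, np.zeros(n_sites)]),
                np.column_stack([x, np.full(n_sites, float(row_spacing))]),
            ]
        )
        name = name or f"rect{spacing:g}"
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    return OrigamiDesign(name=name, site_positions=pos, kind=kind)


#: Named designs used throughout: a 10-site linear ruler with 28-nm spacing,
#: a sparse 4-site variant spanning the same 252 nm at 84-nm spacing, and a
#: rectangular ruler with two rows 30 nm apart and 11-nm within-row spacing.
DESIGN_PRESETS: dict[str, OrigamiDesign] = {
    "linear28": make_design("linear", 28.0, 10, name="linear28"),
    "linear84": make_design("linear", 84.0, 4, name="linear84"),
    "rect11": make_design("rectangular", 11.0, 8, row_spacing=30.0, name="rect11"),
}


def design_by_name(name: str) -> OrigamiDesign:
    try:
        return DESIGN_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; available: {sorted(DESIGN_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated field.

    Defaults describe the no-gel reference regime: bright-Cy5 localization
    clouds a few nm wide, ~30 localizations per dye, sparse fields in a
    90 x 90 um imaging area, ~15,000 camera frames.

    Attributes
    ----------
    n_objects : number of origami placed in the field.
    field_size : (width, height) of the placement field, micrometers.
    labeling_efficiency : probability that a site carries a visible dye.
    locs_per_emitter_mean : Poisson mean of localizations per visible dye.
    min_locs_per_emitter : floor on localizations per visible dye, so that
        simulated emitters are detectable at minPts = 5.
    localization_precision : sigma (nm, per coordinate) of each localization
        about its emitter.
    intrinsic_jitter : sigma (nm, per coordinate) of per-site structural
        displacement present in all conditions.
    gel_distortion : sigma (nm, per coordinate) of per-site displacement
        applied only in the "post" (denatured-in-gel) condition.
    expansion_factor : isotropic scale (>= 1) applied to all emitter
        positions about the field origin.
    background_density : uniform background localizations per um^2 of the
        imaged (post-expansion) field.
    n_frames : camera frames; localization frames are uniform on 1..n_frames.
    seed : integer seed; identical inputs give byte-identical outputs.
    """

    n_objects: int = 100
    field_size: tuple[float, float] = (90.0, 90.0)
    labeling_efficiency: float = 0.85
    locs_per_emitter_mean: float = 30.0
    min_locs_per_emitter: int = 5
    localization_precision: float = 3.0
    intrinsic_jitter: float = 5.0
    gel_distortion: float = 0.0
    expansion_factor: float = 1.0
    background_density: float = 0.1
    n_frames: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.labeling_efficiency <= 1.0):
            raise ValueError("labeling_efficiency must be in (0, 1]")
        for name in ("localization_precision", "intrinsic_jitter", "gel_distortion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expansion_factor < 1.0:
            raise ValueError("expansion_factor must be >= 1")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field_size must be positive")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.min_locs_per_emitter < 0 or self.locs_per_emitter_mean < 0:
            raise ValueError("localization counts must be >= 0")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _place_objects(
    rng: np.random.Generator,
    n_objects: int,
    field_nm: tuple[float, float],
    radius: float,
    min_separation: float,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Rejection-sample object centers so bounding circles never overlap."""
    w, h = field_nm
    margin = min(radius, w / 2, h / 2)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_objects:
        c = rng.uniform([margin, margin], [w - margin, h - margin])
        tries += 1
        if tries > max_tries * max(1, n_objects):
            raise RuntimeError(
                "could not place objects without overlap; "
                "field too crowded for the requested n_objects"
            )
        if centers and np.min(
            np.linalg.norm(np.asarray(centers) - c, axis=1)
        ) < min_separation:
            continue
        centers.append(c)
    return np.asarray(centers).reshape(n_objects, 2)


def simulate_field(
    design: OrigamiDesign,
    config: SimulationConfig,
    condition: Condition = "pre",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one field of origami and return (localizations, ground truth).

    The generative chain per object is: uniform random placement and
    rotation in the field; per-site Bernoulli visibility; true site position
    = placed design position + intrinsic jitter + (post condition only) gel
    displacement; all emitter positions scaled by ``expansion_factor`` about
    the field origin; each visible emitter emits
    ``max(min_locs_per_emitter, Poisson(locs_per_emitter_mean))``
    localizations with iid Gaussian noise of ``localization_precision`` per
    coordinate and frames uniform on ``1..n_frames``; finally a uniform
    spatial Poisson background is added over the imaged field.

    The random stream is consumed identically for ``pre`` and ``post`` (the
    gel displacement is drawn in both and zeroed for ``pre``), so the two
    conditions of one seed share placements, visibility, jitter and blinking
    statistics and differ only by the gel displacement itself.

    Returns
    -------
    localizations : DataFrame with columns ``x_nm, y_nm, frame``.
    ground_truth : DataFrame with one row per designed site:
        ``object_id, site_index, x_true_nm, y_true_nm, visible,
        dx_gel_nm, dy_gel_nm``.  True positions are in imaged (post-
        expansion) coordinates; gel displacements are pre-expansion nm.
    """
    if condition not in ("pre", "post"):
        raise ValueError(f"condition must be 'pre' or 'post', got {condition!r}")
    rng = np.random.default_rng(config.seed)
    field_nm = (config.field_size[0] * UM_TO_NM, config.field_size[1] * UM_TO_NM)
    f = config.expansion_factor
    gel_scale = config.gel_distortion if condition == "post" else 0.0

    # Keep distinct objects far enough apart that downstream single-linkage
    # grouping (default radius 100 nm) can never bridge them.
    min_sep = 2.0 * design.radius + 500.0
    centers = _place_objects(
        rng, config.n_objects, field_nm, design.radius, min_sep
    )

    loc_xy: list[np.ndarray] = []
    loc_frames: list[np.ndarray] = []
    truth_rows: list[pd.DataFrame] = []
    n = design.n_sites
    for obj_id in range(config.n_objects):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        local = design.site_positions - design.site_positions.mean(axis=0)
        placed = local @ rot.T + centers[obj_id]
        visible = rng.random(n) < config.labeling_efficiency
        jitter = rng.standard_normal((n, 2)) * config.intrinsic_jitter
        gel_applied = rng.standard_normal((n, 2)) * gel_scale
        true_pre = placed + jitter + gel_applied
        true_img = true_pre * f
        counts = np.maximum(
            config.min_locs_per_emitter,
            rng.poisson(config.locs_per_emitter_mean, size=n),
        )
        for i in range(n):
            if not visible[i]:
                continue
            k = int(counts[i])
            noise = rng.standard_normal((k, 2)) * config.localization_precision
            loc_xy.append(true_img[i] + noise)
            loc_frames.append(rng.integers(1, config.n_frames + 1, size=k))
        truth_rows.append(
            pd.DataFrame(
                {
                    "object_id": obj_id,
                    "site_index": np.arange(n),
                    "x_true_nm": true_img[:, 0],
                    "y_true_nm": true_img[:, 1],
                    "visible": visible,
                    "dx_gel_nm": gel_applied[:, 0],
                    "dy_gel_nm": gel_applied[:, 1],
                }
            )
        )

    # Background: uniform spatial Poisson process over the imaged field.
    imaged_area_um2 = config.field_size[0] * config.field_size[1] * f * f
    n_bg = rng.poisson(config.background_density * imaged_area_um2)
    if n_bg > 0:
        bg = rng.uniform([0.0, 0.0], [field_nm[0] * f, field_nm[1] * f], size=(n_bg, 2))
        loc_xy.append(bg)
        loc_frames.append(rng.integers(1, config.n_frames + 1, size=n_bg))

    if loc_xy:
        xy = np.vstack(loc_xy)
        frames = np.concatenate(loc_frames)
    else:
        xy = np.empty((0, 2))
        frames = np.empty(0, dtype=int)
    locs = pd.DataFrame(
        {"x_nm": xy[:, 0], "y_nm": xy[:, 1], "frame": frames.astype(np.int64)}
    )
    if truth_rows:
        truth = pd.concat(truth_rows, ignore_index=True)
    else:
        truth = pd.DataFrame(
            {
                "object_id": pd.Series(dtype=np.int64),
                "site_index": pd.Series(dtype=np.int64),
                "x_true_nm": pd.Series(dtype=float),
                "y_true_nm": pd.Series(dtype=float),
                "visible": pd.Series(dtype=bool),
                "dx_gel_nm": pd.Series(dtype=float),
                "dy_gel_nm": pd.Series(dtype=float),
            }
        )
    return locs, truth
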