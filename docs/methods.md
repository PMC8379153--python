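# Methods

`nanoruler` quantifies how well a hydrogel embedding preserves nanoscale
structure, using DNA-origami nanorulers imaged by single-molecule
localization microscopy (STORM) as distance standards.  This note documents
the analysis model, the synthetic-data generator used to validate it, the
parameters that matter, and the numerical choices made where the procedure
was genuinely open.

## Analysis model

A STORM molecule list is a table of localizations (x, y, frame), many per
fluorophore because dyes blink repeatedly.  The pipeline proceeds in five
stages:

1. **Emitter clustering.**  Each dye's localization cloud is collapsed to a
   centroid.  For rulers with ≥ 28-nm site spacing this is DBSCAN
   (`eps` = 10 nm, `minPts` = 5) on the raw coordinates; cluster centroids
   estimate emitter positions with an error of roughly
   `precision / sqrt(K)` — a few nm or better for bright Cy5.  For the
   11-nm rectangular design DBSCAN merges neighboring sites, so clustering
   is instead seeded from local maxima of a Gaussian-blurred rendered image
   and refined by Lloyd's K-means on the raw coordinates.
2. **Object grouping and selection.**  Cluster centroids are grouped into
   candidate origami by single-linkage (radius `max(100 nm, 2.5 × spacing)`,
   so the gap left by one missing emitter never splits an object).  Linear
   objects are kept if ≥ 5 clusters lie on a straight line with total-least-
   squares R² > 0.9 (≥ 3 for the sparse 84-nm design, which has only 4
   sites); rectangular-origami rows are kept at ≥ 3 collinear clusters.
3. **Nearest-neighbor distances.**  Within each object, every cluster
   contributes the Euclidean distance to its nearest neighbor; mutual pairs
   are counted once.  For expanded samples, distances are divided by the
   physically measured expansion factor ("effective distances").
4. **First-peak fit.**  The pooled distances are histogrammed (2-nm bins)
   and the first peak is fitted with `A·exp(−(d−μ)²/2σ²)` by unweighted
   least squares inside a window around the design spacing `s` (default
   `[0.5, 1.5]·s`).  μ reports the recovered spacing; σ its spread.
5. **Distortion estimate.**  Gel-introduced per-emitter positional error is
   isolated by comparing σ before and after origami denaturation:

       σ_emitter = sqrt((σ_post² − σ_pre²) / 2),
       FWHM      = 2·sqrt(2·ln 2) · σ_emitter ≈ 2.355 · σ_emitter.

   The factor 2 reflects that both emitters of a distance receive
   independent displacements, whose components along the inter-emitter axis
   add in quadrature; transverse second-order terms are neglected, which is
   why the comparison uses the sparse 84-nm ruler (spacing ≫ distortion,
   and its first peak does not overlap higher-order peaks even when
   broadened).  σ_post < σ_pre (possible by sampling noise when the true
   distortion is small) yields a flagged zero, never an imaginary number.

### Known biases of the distortion estimator

Parameter recovery on synthetic data shows the estimator is slightly
conservative: feeding a true 16-nm per-coordinate displacement through the
full pipeline returns ≈ 14.5–16 nm.  Two effects, both intrinsic to the
statistic, contribute.  First, nearest-neighbor selection prefers the
smaller of the two gaps flanking an interior site, which narrows the
distance distribution relative to the plain adjacent-gap distribution
(≈ −6% on σ at 16-nm distortion).  Second, the straightness filter removes
objects with large transverse displacements.  Both are documented
properties of the published procedure rather than implementation artifacts;
the variance-additivity property test therefore checks the factor-2 law on
ground-truth adjacent-site distances, where it holds to a few percent (the
residual being the curvature of the Euclidean distance at finite
displacement/spacing ratio).

The distortion workflow averages a few replicate pre/post experiment pairs
(default 3), mirroring how bar-plot comparisons of gel chemistries report a
mean ± SD over experiments; this reduces the ±1 nm per-experiment fit noise
at ~200 distances per condition.  For the sparse design the fit window is
widened to `[0.25, 1.75]·s`: its first peak is isolated by construction,
and the wider window covers ±2.5σ of the broadened post peak.

### Two-row fitting (rectangular design)

Dense regions of interest (> 30 localizations per 2×2 μm window,
half-overlapping grid, merged when overlapping) are segmented into
connected structures (single-linkage at 150 nm) so that two origami
sharing a window are analyzed separately.  Each structure is fitted with
two parallel rows by alternating (i) a deterministic 1D 2-means split of
the perpendicular coordinates and (ii) re-estimation of the common row
direction as the principal axis of the *within-row centered* points.  The
centering step matters: with incomplete labeling the two rows have unequal
extents, and a naive pooled principal axis tilts toward the long diagonal,
biasing the recovered row spacing low by up to several nm.  Row offsets are
MAD-trimmed means, which makes the fit robust to the occasional background
localization inside the region; localization profiles perpendicular and
parallel to the rows are summarized by sums-of-Gaussians fits.

All geometric statistics (straightness, row spacing, distances) are
rotation- and translation-invariant by construction (principal-axis / TLS
formulations, not y-on-x regression, which would spuriously reject
near-vertical objects).

## Synthetic-data generator

The generator emulates the statistical structure of origami STORM fields —
it is the validation substrate for every stage, not a camera simulator.
Per object: uniform random placement (rejection-sampled so bounding circles
never overlap; sparse fields) and rotation; per site: Bernoulli visibility
(incomplete labeling), isotropic Gaussian structural jitter, and, in the
"post" condition only, an independent isotropic Gaussian gel displacement;
all positions are then scaled by the expansion factor about the field
origin.  Each visible emitter emits `max(floor, Poisson(mean))`
localizations with isotropic Gaussian noise; frames are uniform (no
photokinetic time series — nothing downstream uses temporal structure).  A
uniform spatial Poisson background is added over the imaged field.  The
"pre" and "post" conditions of one seed consume the random stream
identically, so they share placements, visibility and blinking and differ
only by the gel displacement itself.

Default parameters (nm unless noted):

| parameter | default | rationale |
|---|---|---|
| field size | 90 × 90 μm | typical sCMOS STORM field |
| n_frames | 15 000 | typical acquisition length |
| labeling_efficiency | 0.85 | hybridization efficiency of dye oligos; produces the observed peaks at distance multiples |
| locs_per_emitter_mean | 30 (floor 5) | Cy5 blinking statistics; floor keeps emitters detectable at minPts = 5 |
| localization_precision | 3.0 | per-localization σ of bright Cy5 STORM (~5 000 photons); makes 28-nm sites separable by DBSCAN at eps 10–15, consistent with few-nm emitter accuracy |
| intrinsic_jitter | 5.0 | per-site structural disorder of linear origami (in-plane warping, linker flexibility); 1.5 for the stiffer surface-tethered rectangle |
| gel_distortion | 0 (pre) / experiment-specific (post) | the quantity under study |
| expansion_factor | 1 (up to 2.2–2.5 for expanded gels) | measured physically on real gels |
| background_density | 0.1 μm⁻² | sparse nonspecific binding on a clean coverslip |

What the generator does **not** model: raw camera frames and PSF fitting,
drift, chromatic aberration, the axial dimension, spatially correlated gel
distortion, and photokinetic correlations between frames.  Passing tests
therefore demonstrate correctness of the analysis given the stated
generative assumptions (independent per-site displacements, isotropic
expansion, uncorrelated localization noise) — not robustness to drift or
correlated distortion fields in real data.

## Numerical choices

- **DBSCAN**: scikit-learn's implementation (index-order scan); border
  points reachable from two clusters go to the cluster discovered first,
  pinned for reproducibility and verified against a textbook O(n²) oracle.
- **K-means**: fixed maxima-derived initialization only, no restarts;
  Lloyd iterations stop at max centroid shift < 0.1 nm or 100 iterations;
  empty clusters keep their center and are discarded at the end if below
  `minPts` members.  The within-cluster sum of squares is recorded and
  tested to be non-increasing.
- **Rendering**: images are localization histograms convolved with a
  Gaussian kernel (σ = 8 nm for display, matching the common rendering
  convention where the quoted "radius" is the Gaussian σ; σ = 1.5 nm at
  2-nm pixels for the maxima-seeding images).  The seeding blur is chosen
  so the effective spot width `sqrt(cloud² + blur²)` stays below half the
  11-nm spacing; a 4-nm blur demonstrably merges adjacent sites.
- **Peak fits**: unweighted least squares on bin counts (robust to empty
  bins, matches the visual fit convention); initial values μ = expected
  spacing, σ = 0.3 × spacing, A = max count; fits report a `converged`
  flag plus a diagnostic message and are never silently numeric.
  Degenerate histograms (< 4 occupied bins) and fitted means escaping the
  window are flagged unconverged.
- **Determinism**: one `numpy` Generator seeded from the config drives all
  randomness in a documented draw order; identical configs give
  byte-identical CSV/JSON outputs (floats written as `%.17g` and parsed
  round-trip).

## Problem sizes

Validation runs use fields of 100 linear origami (≈ 26 000 localizations),
100 × 2 × 3 sparse-design objects for the distortion comparison, and 60
rectangular origami (≈ 29 000 localizations); these sizes give ~400
nearest-neighbor distances per field, enough that first-peak fit noise
(± ~0.3 nm on μ) is small against the 1-nm acceptance tolerances.

## Limitations

- The distortion estimator's small negative bias (above) is not corrected;
  reported distortions are mildly conservative.
- Object grouping assumes sparse fields; touching origami are not
  disentangled (the generator enforces non-overlap; crowded real fields
  would need the rectangular branch's segmentation everywhere).
- The 84-nm sparse ruler is modeled with 4 sites spanning the same 252 nm
  as the 10-site design; the rectangular ruler with 8 sites per row.  Site
  counts beyond the stated spacings are design choices.
- Expansion is a pure isotropic scalar; no field-dependent warping.
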