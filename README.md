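# nanoruler

Analysis of DNA-origami nanoruler STORM data for quantifying how accurately
hydrogel embedding — the first step of expansion microscopy (ExM) —
preserves nanoscale structure.

Expansion microscopy physically magnifies a specimen by embedding it in a
swellable hydrogel, but the embedding itself can displace labeled sites.
DNA-origami nanorulers carry fluorophores at designed spacings (a linear
ruler with 10 sites every 28 nm, a sparse variant with 84-nm spacing, and a
rectangular ruler with two rows 30 nm apart and 11-nm within-row spacing),
so the distances recovered from single-molecule localization microscopy
report directly on structural preservation.  `nanoruler` implements the
full analysis:

- cluster localizations into emitters: DBSCAN for ≥ 28-nm spacings, local
  maxima of a Gaussian-blurred image seeding K-means for 11-nm spacings;
- group clusters into origami objects and apply the published selection
  rules (≥ 5 collinear clusters with R² > 0.9; ≥ 3 for sparse rulers and
  rectangle rows; > 30 localizations per 4 μm² for rectangle ROIs);
- build deduplicated nearest-neighbor distance distributions, rescale by
  the gel expansion factor, and fit the first peak with a Gaussian;
- convert pre/post-denaturation peak widths σ_pre, σ_post into a
  per-emitter distortion

      σ_emitter = sqrt((σ_post² − σ_pre²) / 2),   FWHM = 2√(2 ln 2)·σ_emitter,

- and simulate synthetic origami fields with ground truth, so every stage
  is verifiable without raw microscope data.

See `docs/methods.md` for the model, parameter defaults, and known
limitations.

## Worked example

Simulate a no-gel reference field of one hundred 28-nm linear rulers and
run the pipeline:

```python
from nanoruler import (SimulationConfig, analyze_linear_field,
                       design_by_name, distortion_experiment, simulate_field)

locs, truth = simulate_field(design_by_name("linear28"),
                             SimulationConfig(seed=1, n_objects=100), "pre")
res = analyze_linear_field(locs)
print(f"selected {res.selection.n_selected} objects, "
      f"{len(res.nnd)} NN distances")
print(f"first peak {res.peak_fit.mean:.1f} +/- {res.peak_fit.sigma:.1f} nm")
```

```
selected 98 objects, 403 NN distances
first peak 29.4 +/- 5.8 nm
```

The fitted peak sits at the designed 28-nm spacing (slightly above it,
because occasionally two emitters merge into one cluster, inflating their
neighbors' distances — visible in `merged_cluster_diagnostic`).  The
distances also show mass near 56 nm where an emitter went unlabeled.

Measure the distortion a gel introduces, by comparing paired fields before
and after origami denaturation on the sparse 84-nm ruler:

```python
out = distortion_experiment(config=SimulationConfig(seed=1),
                            gel_distortion=16.0)   # true per-site sigma, nm
print(f"recovered distortion {out['sigma_emitter_nm']:.1f} nm "
      f"({out['fwhm_emitter_nm']:.0f} nm FWHM)")
```

```
recovered distortion 14.6 nm (34 nm FWHM)
```

A 16-nm true per-coordinate displacement is recovered at ≈ 15 nm (the
estimator is mildly conservative; see the methods note), while a well
preserved sample (true distortion ≤ 5 nm) stays below 12 nm FWHM.

The same stages are available from the shell:

```sh
nanoruler simulate --design linear28 --seed 1 --out demo
nanoruler cluster demo_locs.csv --method dbscan --out clusters.csv
nanoruler analyze-rect --seed 1 --out rect_run/
nanoruler distortion --pre pre.csv --post post.csv --expected-spacing 84 --out report.json
```

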