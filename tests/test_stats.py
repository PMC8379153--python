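"""Tests for nearest-neighbor statistics, peak fitting, and the distortion
estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoruler import (
    FWHM_FACTOR,
    NNDistanceSet,
    PeakFit,
    SimulationConfig,
    apply_expansion,
    design_by_name,
    estimate_distortion,
    fit_first_peak,
    fit_multi_gaussian_1d,
    merged_cluster_diagnostic,
    nn_distances,
    simulate_field,
)
from nanoruler.geometry import select_linear_objects
from oracles import brute_nn_dedup


def peak(mean, sigma, converged=True):
    return PeakFit(
        mean=mean, sigma=sigma, amplitude=1.0, fit_window=(0.0, 2 * mean),
        bin_width=2.0, converged=converged,
    )


class TestNnDistances:
    def test_three_collinear_clusters(self):
        pts = np.array([(0, 0), (28, 0), (56, 0)], float)
        d = np.sort(nn_distances(pts).distances)
        assert np.allclose(d, [28.0, 28.0])

    def test_two_clusters_single_distance(self):
        assert len(nn_distances(np.array([(0, 0), (50, 0)], float))) == 1

    def test_ten_clusters_give_nine_adjacent_gaps(self):
        pts = np.column_stack([np.arange(10) * 28.0, np.zeros(10)])
        d = nn_distances(pts).distances
        assert len(d) == 9 and np.allclose(d, 28.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            nn_distances(np.array([(0.0, 0.0)]))

    def test_matches_exhaustive_dedup_oracle(self, rng):
        """Set-semantics equivalence with brute-force pair enumeration for
        all random objects with up to 12 clusters."""
        for _ in range(50):
            n = int(rng.integers(2, 13))
            pts = rng.uniform(0, 300, (n, 2))
            mine = np.sort(nn_distances(pts).distances)
            oracle = brute_nn_dedup(pts)
            assert np.allclose(mine, oracle)


class TestApplyExpansion:
    def test_divides_distances(self):
        nnd = NNDistanceSet(np.array([70.0]), np.array([0]))
        out = apply_expansion(nnd, 2.5)
        assert out.distances[0] == pytest.approx(28.0)
        assert out.expansion_factor == 2.5

    def test_identity_and_validation(self):
        nnd = NNDistanceSet(np.array([10.0]), np.array([0]))
        assert apply_expansion(nnd, 1.0).distances[0] == 10.0
        with pytest.raises(ValueError):
            apply_expansion(nnd, 0.9)

    @given(factor=st.floats(1.0, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rescaling_commutes_with_fitting(self, factor):
        rng = np.random.default_rng(21)
        d = rng.normal(28.0 * factor, 8.0 * factor, 5000)
        d = d[d > 0]
        nnd = NNDistanceSet(d, np.zeros(len(d)))
        direct = fit_first_peak(apply_expansion(nnd, factor), 28.0)
        scaled = fit_first_peak(nnd, 28.0 * factor, bin_width=2.0 * factor)
        assert direct.converged and scaled.converged
        # sub-bin agreement: the two routes bin the same sample differently
        assert direct.mean == pytest.approx(scaled.mean / factor, abs=0.2)


class TestFitFirstPeak:
    def test_recovers_gaussian_parameters(self, rng):
        d = rng.normal(28.0, 8.0, 20000)
        d = d[d > 0][:10000]
        fit = fit_first_peak(d, 28.0)
        assert fit.converged
        assert fit.mean == pytest.approx(28.0, abs=0.3)
        assert fit.sigma == pytest.approx(8.0, abs=0.3)

    def test_second_peak_outside_window_ignored(self, rng):
        d = np.concatenate([rng.normal(28, 8, 8000), rng.normal(56, 8, 2000)])
        d = d[d > 0]
        fit = fit_first_peak(d, 28.0)
        assert fit.mean == pytest.approx(28.0, abs=1.0)

    def test_identical_distances_do_not_converge(self):
        fit = fit_first_peak(np.full(100, 28.0), 28.0)
        assert not fit.converged and fit.message

    def test_too_few_distances_flagged(self):
        fit = fit_first_peak(np.array([28.0, 30.0]), 28.0)
        assert not fit.converged
        assert "need" in fit.message


class TestEstimateDistortion:
    def test_equal_widths_give_zero(self):
        est = estimate_distortion(peak(84, 8.0), peak(84, 8.0))
        assert est.sigma_emitter == 0.0 and est.valid

    def test_16nm_distortion_prints_38_fwhm(self):
        sigma_pre = 7.0
        sigma_post = np.sqrt(2 * 16.0**2 + sigma_pre**2)
        est = estimate_distortion(peak(84, sigma_pre), peak(84, sigma_post))
        assert est.sigma_emitter == pytest.approx(16.0, abs=1e-9)
        assert est.fwhm_emitter == pytest.approx(37.67, abs=0.01)
        assert round(est.fwhm_emitter) == 38

    def test_inverted_order_flagged_not_imaginary(self):
        est = estimate_distortion(peak(84, 9.0), peak(84, 8.0))
        assert est.sigma_emitter == 0.0 and not est.valid

    def test_unconverged_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_distortion(peak(84, 8.0, converged=False), peak(84, 9.0))

    @given(sigma=st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fwhm_identity(self, sigma):
        est = estimate_distortion(
            peak(84, 5.0), peak(84, float(np.sqrt(2 * sigma**2 + 25.0)))
        )
        assert est.fwhm_emitter == pytest.approx(FWHM_FACTOR * est.sigma_emitter)
        assert FWHM_FACTOR == pytest.approx(2.3548, abs=1e-4)

    def test_variance_additivity_slope(self):
        """Fitted first-peak variance excess grows as twice the per-site
        displacement variance (the factor the estimator divides out),
        measured on ground-truth adjacent-site distances of the sparse
        design."""
        d84 = design_by_name("linear84")

        def fitted_sigma2(gel):
            cfg = SimulationConfig(
                seed=5, n_objects=1500, gel_distortion=gel,
                locs_per_emitter_mean=0.0, min_locs_per_emitter=0,
                background_density=0.0,
            )
            _, truth = simulate_field(d84, cfg, "post")
            t = truth[truth.visible]
            dists = []
            for _, g in t.groupby("object_id"):
                idx = g.site_index.to_numpy()
                xy = g[["x_true_nm", "y_true_nm"]].to_numpy()
                adj = np.flatnonzero(np.diff(idx) == 1)
                dists.extend(np.linalg.norm(xy[adj + 1] - xy[adj], axis=1))
            fit = fit_first_peak(np.asarray(dists), 84.0, bin_width=3.0, window=(21, 147))
            assert fit.converged
            return fit.sigma ** 2

        base = fitted_sigma2(0.0)
        x = np.array([5.0, 10.0, 16.0]) ** 2
        y = np.array([fitted_sigma2(g) - base for g in (5.0, 10.0, 16.0)])
        slope = float((x * y).sum() / (x * x).sum())
        assert slope == pytest.approx(2.0, rel=0.10)


class TestFitMultiGaussian:
    def test_two_rows_30nm_apart(self, rng):
        x = np.concatenate([rng.normal(0, 3.0, 2000), rng.normal(30, 3.0, 2000)])
        fits = fit_multi_gaussian_1d(x, 2)
        assert all(f.converged for f in fits)
        assert fits[1].mean - fits[0].mean == pytest.approx(30.0, abs=0.5)
        for f in fits:
            assert f.sigma == pytest.approx(3.0, abs=0.5)

    def test_single_peak_matches_plain_fit(self, rng):
        x = rng.normal(10.0, 2.5, 3000)
        (fit,) = fit_multi_gaussian_1d(x, 1)
        assert fit.converged
        assert fit.mean == pytest.approx(10.0, abs=0.3)

    def test_five_equal_peaks_11nm(self, rng):
        x = np.concatenate([rng.normal(11 * k, 2.5, 600) for k in range(5)])
        fits = fit_multi_gaussian_1d(x, 5)
        gaps = np.diff([f.mean for f in fits])
        assert np.all(np.abs(gaps - 11.0) < 1.0)

    def test_insufficient_maxima_flagged(self, rng):
        x = rng.normal(0, 2.0, 500)
        fits = fit_multi_gaussian_1d(x, 4)
        assert not any(f.converged for f in fits)


class TestMergedClusterDiagnostic:
    def test_clean_simulation_has_no_signatures(self):
        pts = [np.column_stack([np.arange(10) * 28.0, np.zeros(10)]) for _ in range(5)]
        objects = select_linear_objects([_clusters(p) for p in pts]).objects
        report = merged_cluster_diagnostic(objects, 28.0, 10)
        assert report.frac_objects_below_design == 0.0
        assert report.frac_distances_above_1p5 == 0.0

    def test_distortion_inflates_distances(self):
        """Gel distortion on the 28-nm design merges clusters and inflates
        the nearest-neighbor distances."""
        cfg = SimulationConfig(seed=6, n_objects=40, gel_distortion=16.0)
        from nanoruler import analyze_linear_field

        locs, _ = simulate_field(design_by_name("linear28"), cfg, "post")
        res = analyze_linear_field(locs, min_clusters=3, r2_min=0.8)
        report = merged_cluster_diagnostic(res.selection.objects, 28.0, 10)
        assert report.frac_objects_below_design > 0.5
        assert report.mean_nn_distance > 28.0

    def test_missing_emitters_distinguished_from_merging(self):
        """Incomplete labeling without distortion: long distances appear but
        most objects still resolve every labeled site."""
        cfg = SimulationConfig(seed=9, n_objects=60, labeling_efficiency=0.8)
        from nanoruler import analyze_linear_field

        locs, truth = simulate_field(design_by_name("linear28"), cfg, "pre")
        res = analyze_linear_field(locs)
        report = merged_cluster_diagnostic(res.selection.objects, 28.0, 10)
        assert report.frac_distances_above_1p5 > 0.0


def _clusters(points):
    from nanoruler import EmitterCluster

    return [
        EmitterCluster(centroid=(float(x), float(y)), member_indices=np.array([i]))
        for i, (x, y) in enumerate(points)
    ]
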