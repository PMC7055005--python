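"""RICS estimators, model, fitting, calibration and the interaction index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricstools.geometry import ImageSeries, ScanConfig, SpeciesSpec
from ricstools.rics import (ACFSurface, calibrate_beam_waist, fit_rics,
                            interaction_index, moving_average_subtract,
                            rics_model, spatial_acf)
from ricstools.synthetic import simulate_raster_series

from conftest import n_particles_for, simulate_single_species


def brute_force_acf(A, B, xi, psi):
    """Direct double-loop spatial correlation estimator (oracle)."""
    vals = []
    for f in range(A.shape[0]):
        ma, mb = A[f].mean(), B[f].mean()
        dA, dB = A[f] - ma, B[f] - mb
        total, n = 0.0, 0
        R, C = dA.shape
        for y in range(R):
            for x in range(C):
                y2, x2 = y + psi, x + xi
                if 0 <= y2 < R and 0 <= x2 < C:
                    total += dA[y, x] * dB[y2, x2]
                    n += 1
        vals.append(total / n / (ma * mb))
    return float(np.mean(vals))


class TestMovingAverageSubtract:
    def test_constant_series_unchanged(self):
        data = np.full((12, 8, 8), 7.0)
        assert np.allclose(moving_average_subtract(data, 5), data)

    def test_full_window_subtracts_global_temporal_mean(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(10, (15, 6, 6)).astype(float)
        out = moving_average_subtract(data, 15)
        expected = data - data.mean(axis=0) + data.mean(axis=0).mean()
        assert np.allclose(out, expected)

    def test_static_structure_removed_from_acf(self):
        rng = np.random.default_rng(1)
        structure = np.zeros((32, 32))
        structure[10:20, 8:25] = 30.0
        frames = rng.poisson(structure + 5.0, (20, 32, 32)).astype(float)
        det = moving_average_subtract(frames, 10)
        g = spatial_acf(det).G.copy()
        g[g.shape[0] // 2, g.shape[1] // 2] = 0.0   # ignore shot-noise peak
        raw = spatial_acf(frames).G.copy()
        raw[raw.shape[0] // 2, raw.shape[1] // 2] = 0.0
        assert np.abs(g).max() < 0.05 * np.abs(raw).max()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(m=st.integers(min_value=2, max_value=15), seed=st.integers(0, 100))
    def test_mean_intensity_preserved_exactly(self, m, seed):
        data = np.random.default_rng(seed).poisson(6, (15, 5, 5)).astype(float)
        out = moving_average_subtract(data, m)
        assert out.mean() == pytest.approx(data.mean(), abs=1e-10)

    def test_window_bounds_enforced(self):
        data = np.zeros((10, 4, 4))
        for m in (1, 11):
            with pytest.raises(ValueError):
                moving_average_subtract(data, m)


class TestSpatialACF:
    def test_matches_brute_force_estimator(self):
        rng = np.random.default_rng(3)
        A = rng.poisson(5.0, (2, 16, 16)).astype(float)
        B = rng.poisson(8.0, (2, 16, 16)).astype(float)
        acf = spatial_acf(A, B, max_lag=(6, 6))
        for xi in (-6, -3, 0, 2, 6):
            for psi in (-5, 0, 4):
                assert acf.value_at(xi, psi) == pytest.approx(
                    brute_force_acf(A, B, xi, psi), abs=1e-10)

    def test_iid_poisson_shot_noise_closed_form(self):
        rng = np.random.default_rng(4)
        lam = 5.0
        frames = rng.poisson(lam, (40, 64, 64)).astype(float)
        acf = spatial_acf(frames, max_lag=(5, 5))
        assert acf.value_at(0, 0) == pytest.approx(1.0 / lam, rel=0.05)
        off = acf.G.copy()
        off[5, 5] = 0.0
        assert np.abs(off).max() < 0.005

    def test_independent_channels_cross_correlation_vanishes(self):
        rng = np.random.default_rng(5)
        A = rng.poisson(5.0, (40, 64, 64)).astype(float)
        B = rng.poisson(5.0, (40, 64, 64)).astype(float)
        acf = spatial_acf(A, B, max_lag=(5, 5))
        assert acf.kind == "cross"
        assert np.abs(acf.G).max() < 0.005

    def test_auto_surface_is_point_symmetric(self):
        rng = np.random.default_rng(6)
        frames = rng.poisson(5.0, (3, 24, 24)).astype(float)
        acf = spatial_acf(frames, max_lag=(6, 6))
        assert np.allclose(acf.G, acf.G[::-1, ::-1], atol=1e-12)

    def test_zero_mean_frame_rejected(self):
        frames = np.zeros((2, 8, 8))
        with pytest.raises(ValueError):
            spatial_acf(frames)


class TestRICSModel:
    def test_zero_lag_equals_offset_plus_amplitude(self):
        scan = ScanConfig()
        val = rics_model(0, 0, D=2.0, G0=0.05, offset=0.01, scan=scan)
        assert val == pytest.approx(0.06)

    def test_immobile_limit_is_scanning_gaussian(self):
        scan = ScanConfig()
        xi = np.arange(-20, 21)
        g = rics_model(xi, 0, D=0.0, G0=1.0, offset=0.0, scan=scan)
        expected = np.exp(-(scan.pixel_size ** 2 * xi ** 2) / scan.w0 ** 2)
        assert np.allclose(g, expected)

    def test_fast_diffusion_washes_out_correlation(self):
        scan = ScanConfig()
        assert rics_model(1, 0, D=1e9, G0=1.0, offset=0.02,
                          scan=scan) == pytest.approx(0.02, abs=1e-4)


class TestFitRICS:
    def make_surface(self, scan, **kwargs):
        xi = np.arange(-32, 33)
        psi = np.arange(-16, 17)
        pg, xg = np.meshgrid(psi, xi, indexing="ij")
        G = rics_model(xg, pg, scan=scan, **kwargs)
        return ACFSurface(G=G, xi_lags=xi, psi_lags=psi, kind="auto")

    def test_self_consistency_on_model_surface(self):
        scan = ScanConfig(frame_shape=(64, 64))
        surf = self.make_surface(scan, D=1.0, G0=0.05, offset=0.0)
        fit = fit_rics(surf, scan)
        assert fit.converged
        assert fit.D == pytest.approx(1.0, abs=1e-6)
        assert fit.G0 == pytest.approx(0.05, abs=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)
        assert fit.N_apparent == pytest.approx(2 ** -1.5 / 0.05, rel=1e-4)

    def test_immobile_particles_without_detrending_fit_near_zero_d(self):
        # diffraction-limited immobile emitters: the raw ACF is the pure
        # scanning term, so the fit must collapse to the D=0 limit
        scan = ScanConfig(frame_shape=(48, 48), n_frames=10)
        sp = SpeciesSpec(D=0.0, brightness=3.0, n_particles=60)
        ser = simulate_raster_series(sp, scan, seed=7)[1]
        acf = spatial_acf(np.asarray(ser.counts, float), max_lag=(12, 16))
        fit = fit_rics(acf, scan, fit_range=(12, 16))
        assert fit.D < 0.01

    def test_recovered_d_monotone_in_simulated_d(self):
        scan = ScanConfig(frame_shape=(48, 48), n_frames=30)
        means = []
        for D in (0.1, 1.0, 10.0):
            fits = []
            for seed in range(3):
                ser = simulate_single_species(D, scan, seed=seed + 1)
                det = moving_average_subtract(ser, 10)
                fits.append(fit_rics(spatial_acf(det, max_lag=(16, 20)),
                                     scan).D)
            means.append(np.mean(fits))
        assert means[0] < means[1] < means[2]

    def test_amplitude_scales_inversely_with_particle_number(self):
        scan = ScanConfig(frame_shape=(48, 48), n_frames=30)
        g0 = {}
        for factor in (1.0, 2.0):
            vals = []
            for seed in range(4):
                n = int(round(factor * n_particles_for(scan, 2.0)))
                sp = SpeciesSpec(D=1.0, brightness=2.0, n_particles=n)
                ser = simulate_raster_series(sp, scan, seed=seed + 10)[1]
                det = moving_average_subtract(ser, 10)
                vals.append(fit_rics(spatial_acf(det, max_lag=(16, 20)),
                                     scan).G0)
            g0[factor] = np.mean(vals)
        assert g0[2.0] / g0[1.0] == pytest.approx(0.5, abs=0.15)


class TestCalibration:
    def test_waist_recovered_from_model_surface(self):
        scan = ScanConfig(frame_shape=(64, 64))
        xi = np.arange(-32, 33)
        psi = np.arange(-16, 17)
        pg, xg = np.meshgrid(psi, xi, indexing="ij")
        G = rics_model(xg, pg, D=40.0, G0=0.05, offset=0.0, scan=scan)
        surf = ACFSurface(G=G, xi_lags=xi, psi_lags=psi, kind="auto")
        cal = calibrate_beam_waist(surf, scan, D_known=40.0)
        assert cal.w0 == pytest.approx(scan.w0, abs=1e-4)

    def test_waist_recovered_from_simulated_dye_series(self, test_scan):
        w0s = []
        for seed in range(3):
            ser = simulate_single_species(40.0, test_scan, seed=seed + 1)
            det = moving_average_subtract(ser, 10)
            acf = spatial_acf(det, max_lag=(20, 36))
            w0s.append(calibrate_beam_waist(acf, test_scan, D_known=40.0).w0)
        assert np.mean(w0s) == pytest.approx(0.25, rel=0.1)

    def test_wrong_calibration_d_biases_waist_and_raises_chi2(self):
        # calibrating with twice the true dye coefficient cannot be fully
        # compensated by the waist: the fit is systematically worse
        scan = ScanConfig(frame_shape=(64, 64))
        xi = np.arange(-32, 33)
        psi = np.arange(-16, 17)
        pg, xg = np.meshgrid(psi, xi, indexing="ij")
        G = rics_model(xg, pg, D=40.0, G0=0.05, offset=0.0, scan=scan)
        surf = ACFSurface(G=G, xi_lags=xi, psi_lags=psi, kind="auto")
        good = calibrate_beam_waist(surf, scan, D_known=40.0)
        bad = calibrate_beam_waist(surf, scan, D_known=80.0)
        assert bad.chi2 > 100 * max(good.chi2, 1e-12)
        assert abs(bad.w0 - scan.w0) > 10 * abs(good.w0 - scan.w0)


class TestInteractionIndex:
    def test_identical_channels_give_unit_index(self, test_scan):
        scan = ScanConfig(frame_shape=(64, 64), n_frames=50)
        sp = SpeciesSpec(D=0.84, brightness=2.0,
                         n_particles=n_particles_for(scan), label="both")
        out = simulate_raster_series(sp, scan, seed=11)
        res = interaction_index(out[1], out[2], M=10, reference_channel=2)
        assert res.index == pytest.approx(1.0, abs=0.1)

    def test_mismatched_scans_rejected(self):
        a = ImageSeries(np.zeros((5, 8, 8), int), 1,
                        ScanConfig(frame_shape=(8, 8), n_frames=5))
        b = ImageSeries(np.zeros((6, 8, 8), int), 2,
                        ScanConfig(frame_shape=(8, 8), n_frames=6))
        with pytest.raises(ValueError):
            interaction_index(a, b)
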