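"""Local wave-vector estimation: peak search, maps, window-size suggestion."""

import math

import numpy as np
import pytest

import mrewave as mw
from conftest import make_plane_field

OMEGA = 2 * math.pi * 250.0


def gaussian_spectrum(center, width_sigma=0.05, dxi=10.0, m=41, amp=1.0):
    """Synthetic FBI spectrum with a Gaussian modulus about ``center``."""
    xi = dxi * (np.arange(m) - m // 2) + 300.0
    XX, YY = np.meshgrid(xi, xi, indexing="ij")
    mag = amp * np.exp(
        -(width_sigma**2) * ((XX - center[0]) ** 2 + (YY - center[1]) ** 2) / 2
    )
    return mw.FBISpectrum(
        probe=np.zeros(2), sigma=width_sigma, xi_x=xi, xi_y=xi.copy(),
        values=mag.astype(complex),
    )


class TestSpectralPeak:
    def test_on_node_gaussian_recovered_without_offset(self):
        spec = gaussian_spectrum((300.0, 310.0))
        peak = mw.spectral_peak(spec)
        np.testing.assert_allclose(peak.xi, [300.0, 310.0], atol=1e-12)

    @pytest.mark.parametrize("frac", [(0.3, -0.4), (-0.17, 0.05), (0.49, 0.49)])
    def test_between_node_center_recovered_subcell(self, frac):
        center = (300.0 + frac[0] * 10.0, 310.0 + frac[1] * 10.0)
        peak = mw.spectral_peak(gaussian_spectrum(center))
        # log-quadratic interpolation is exact for a Gaussian
        assert np.max(np.abs(peak.xi - center)) < 0.02 * 10.0

    def test_dominant_of_two_peaks_wins(self):
        # separation 90 sqrt(2) rad/m > 6/width_sigma = 120 rad/m
        s1 = gaussian_spectrum((260.0, 260.0), amp=2.0)
        s2 = gaussian_spectrum((350.0, 350.0), amp=1.0)
        spec = mw.FBISpectrum(
            probe=np.zeros(2), sigma=0.05, xi_x=s1.xi_x, xi_y=s1.xi_y,
            values=s1.values + s2.values,
        )
        peak = mw.spectral_peak(spec)
        mag = np.abs(spec.values)
        i, j = np.unravel_index(np.argmax(mag), mag.shape)  # brute force
        assert peak.node == (i, j)
        np.testing.assert_allclose(peak.xi, [260.0, 260.0], atol=0.5)

    def test_all_nodes_masked_raises(self):
        spec = gaussian_spectrum((300.0, 300.0))
        with pytest.raises(ValueError, match="mask"):
            mw.spectral_peak(spec, min_xi_norm=1e9)

    def test_tie_broken_toward_smaller_xi_norm(self):
        xi = 10.0 * (np.arange(21) - 10)
        vals = np.zeros((21, 21), dtype=complex)
        vals[13, 10] = 1.0  # |xi| = 30
        vals[18, 10] = 1.0  # |xi| = 80, equal magnitude
        spec = mw.FBISpectrum(np.zeros(2), 5e-3, xi, xi.copy(), vals)
        assert mw.spectral_peak(spec).node == (13, 10)


class TestLocalWaveVector:
    @pytest.mark.parametrize("lam_px,angle_deg", [(8, 30), (16, 75), (32, 140)])
    def test_recovery_within_one_percent(self, grid128, lam_px, angle_deg):
        lam = lam_px * grid128.h
        th = math.radians(angle_deg)
        beta = (2 * math.pi / (lam * OMEGA)) * np.array([math.cos(th), math.sin(th)])
        f, _ = make_plane_field(grid128, beta, OMEGA)
        sigma = min(lam, 0.25 * 128 * grid128.h)  # one wavelength window
        b = mw.local_wave_vector(f, grid128.position(64, 64), sigma)
        assert np.linalg.norm(b - beta) < 0.01 * np.linalg.norm(beta)

    def test_rotation_equivariance(self, grid64):
        beta = np.array([0.14, 0.05])
        f, _ = make_plane_field(grid64, beta, OMEGA)
        rot = mw.WaveField(grid64, np.rot90(f.values), 250.0)
        p = grid64.position(32, 32) - 0.5 * grid64.h  # rotation center
        sigma = 5 * grid64.h
        b0 = mw.local_wave_vector(f, p, sigma)
        b1 = mw.local_wave_vector(rot, p, sigma)
        expect = np.array([-b0[1], b0[0]])  # 90 deg counterclockwise
        assert np.linalg.norm(b1 - expect) < 0.01 * np.linalg.norm(b0)

    def test_strongest_of_two_waves_selected(self, grid128):
        b1 = np.array([0.2, 0.0])
        b2 = np.array([0.0, 0.13])
        c1 = mw.WaveComponent(2.0, (0, 0), b1)
        c2 = mw.WaveComponent(1.0, (0, 0), b2)
        f = mw.make_wave_field([c1, c2], grid128, OMEGA)
        # window wide enough that the two spectral peaks are well separated
        b = mw.local_wave_vector(f, grid128.position(64, 64), 16 * grid128.h)
        assert np.linalg.norm(b - b1) < 0.02 * np.linalg.norm(b1)

    @pytest.mark.parametrize("scale", [1e-3, 5.0, 2.0 - 3.0j])
    def test_amplitude_invariance(self, grid64, scale):
        f, _ = make_plane_field(grid64, (0.1, 0.12), OMEGA)
        g = f.copy_with(scale * f.values)
        p = grid64.position(32, 32)
        b0 = mw.local_wave_vector(f, p, 5 * grid64.h)
        b1 = mw.local_wave_vector(g, p, 5 * grid64.h)
        np.testing.assert_allclose(b1, b0, rtol=1e-9)

    def test_translation_covariance_in_homogeneous_region(self, grid128):
        beta = np.array([0.11, 0.16])
        f, _ = make_plane_field(grid128, beta, OMEGA)
        sigma = 5 * grid128.h
        probes = [grid128.position(60 + di, 60 + dj) for di, dj in
                  [(0, 0), (3, 1), (-2, 5), (7, -4)]]
        betas = [mw.local_wave_vector(f, p, sigma) for p in probes]
        ref = np.linalg.norm(betas[0])
        for b in betas[1:]:
            assert np.linalg.norm(b - betas[0]) < 0.005 * ref


class TestWaveVectorMap:
    def test_uniform_wave_gives_uniform_map(self, grid128):
        beta = np.array([0.12, 0.09])
        f, _ = make_plane_field(grid128, beta, OMEGA)
        vmap = mw.wave_vector_map(f, sample_spacing=8, sigma=5 * grid128.h)
        err = np.linalg.norm(vmap.beta - beta, axis=1) / np.linalg.norm(beta)
        assert np.max(err) < 0.01
        np.testing.assert_allclose(vmap.xi, vmap.beta * OMEGA, rtol=1e-12)

    def test_sample_spacing_is_samplewise_independent(self):
        grid = mw.Grid2D(32, 32, 1e-3)
        f, _ = make_plane_field(grid, (0.18, 0.1), OMEGA)
        sigma = 4 * grid.h
        m1 = mw.wave_vector_map(f, sample_spacing=1, sigma=sigma, margin=8 * grid.h)
        m4 = mw.wave_vector_map(f, sample_spacing=4, sigma=sigma, margin=8 * grid.h)
        common = {tuple(p): i for i, p in enumerate(map(tuple, m1.points))}
        for i4, p in enumerate(map(tuple, m4.points)):
            i1 = common[tuple(p)]
            np.testing.assert_array_equal(m4.beta[i4], m1.beta[i1])

    def test_two_region_stiffness_contrast_in_beta(self):
        regions = [
            mw.Region("left", (0.0, 0.5), 14.4e3, 0.0, (1, 0), 0.0),
            mw.Region("right", (0.5, 1.0), 3.6e3, 0.0, (1, 0), 0.0),
        ]
        cfg = mw.SimulationConfig(regions=regions, noise_to_signal=0.0)
        res = mw.simulate_experiment(cfg)
        lam = 2 * math.pi / (cfg.omega * np.linalg.norm(res.components[0].beta))
        vmap = mw.wave_vector_map(res.field, sample_spacing=8, sigma=0.75 * lam)
        x_mid = 64 * cfg.h
        far = 24 * cfg.h  # stay clear of the interface blur
        left = np.linalg.norm(vmap.beta[vmap.points[:, 0] < x_mid - far], axis=1)
        right = np.linalg.norm(vmap.beta[vmap.points[:, 0] > x_mid + far], axis=1)
        # stiffer left region -> longer wavelength -> smaller |beta|
        assert np.median(right) / np.median(left) == pytest.approx(2.0, rel=0.05)

    def test_zero_margin_keeps_but_flags_clipped_points(self):
        grid = mw.Grid2D(32, 32, 1e-3)
        f, _ = make_plane_field(grid, (0.18, 0.1), OMEGA)
        vmap = mw.wave_vector_map(f, sample_spacing=8, sigma=4 * grid.h, margin=0.0)
        assert np.any(vmap.boundary_clipped)
        assert len(vmap.points) == 16

    def test_excessive_margin_raises(self, grid64):
        f, _ = make_plane_field(grid64, (0.1, 0.1), OMEGA)
        with pytest.raises(ValueError, match="no sample points"):
            mw.wave_vector_map(f, sigma=4 * grid64.h, margin=1.0)


class TestSuggestSigma:
    def test_matches_known_wavelength(self, grid128):
        lam = 16 * grid128.h
        beta = (2 * math.pi / (lam * OMEGA)) * np.array([1.0, 0.0])
        f, _ = make_plane_field(grid128, beta, OMEGA)
        assert mw.suggest_sigma(f, factor=1.0) == pytest.approx(lam, rel=0.01)

    def test_proportional_in_factor(self, grid128):
        f, _ = make_plane_field(grid128, (0.1, 0.14), OMEGA)
        s1 = mw.suggest_sigma(f, factor=1.0)
        s05 = mw.suggest_sigma(f, factor=0.5)
        assert s05 == pytest.approx(0.5 * s1, rel=1e-12)

    def test_pure_noise_raises_degenerate(self, grid64):
        rng = np.random.default_rng(0)
        f = mw.WaveField(
            grid64,
            rng.standard_normal(grid64.shape) + 1j * rng.standard_normal(grid64.shape),
            250.0,
        )
        with pytest.raises(mw.DegenerateSpectrumError):
            mw.suggest_sigma(f)

    def test_factor_outside_recommended_range_warns(self, grid128):
        f, _ = make_plane_field(grid128, (0.1, 0.1), OMEGA)
        with pytest.warns(UserWarning, match="factor"):
            mw.suggest_sigma(f, factor=0.2)
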