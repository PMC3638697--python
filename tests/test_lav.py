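"""Local attenuation-vector estimation: phase differences, gradient fit."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mrewave as mw
from conftest import make_plane_field

OMEGA = 2 * math.pi * 250.0


class TestPhaseDifference:
    def test_identical_and_quarter_turn(self):
        w = 1.3 - 0.7j
        assert mw.phase_difference(w, w) == pytest.approx(0.0, abs=1e-15)
        assert mw.phase_difference(1j * w, w) == pytest.approx(math.pi / 2)

    def test_random_rotations_recovered_exactly(self):
        rng = np.random.default_rng(0)
        w0 = 0.8 + 0.3j
        for _ in range(100):
            d = rng.uniform(-math.pi + 1e-9, math.pi)
            assert mw.phase_difference(w0 * np.exp(1j * d), w0) == pytest.approx(
                d, abs=1e-12
            )

    @given(
        st.floats(-3.1, 3.1),
        st.floats(-3.1, 3.1),
        st.floats(0.1, 10.0),
        st.floats(0.1, 10.0),
    )
    def test_antisymmetry(self, th1, th0, r1, r0):
        w1 = r1 * np.exp(1j * th1)
        w0 = r0 * np.exp(1j * th0)
        d = mw.phase_difference(w1, w0)
        if abs(d) < math.pi - 1e-9:  # away from the wrap point
            assert mw.phase_difference(w0, w1) == pytest.approx(-d, abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mw.phase_difference(1.0 + 0j, 0.0 + 0j)


def linear_phase_spectrum(slope, m=41, dxi=10.0, center=400.0):
    xi = dxi * (np.arange(m) - m // 2) + center
    XX, YY = np.meshgrid(xi, xi, indexing="ij")
    mag = np.exp(-(((XX - center) ** 2 + (YY - center) ** 2)) / (2 * 150.0**2))
    vals = mag * np.exp(1j * (slope[0] * XX + slope[1] * YY))
    return mw.FBISpectrum(np.zeros(2), 5e-3, xi, xi.copy(), vals)


class TestPhaseGradient:
    def test_exact_on_linear_phase(self):
        slope = np.array([3.2e-3, -1.1e-3])
        spec = linear_phase_spectrum(slope)
        cfg = mw.PhaseFitConfig(stencil_radius=12)
        fit = mw.phase_gradient(spec, config=cfg, xi0=(400.0, 400.0))
        np.testing.assert_allclose(fit.gradient, slope, atol=1e-10)
        assert fit.residual < 1e-10

    def test_zero_phase_gives_zero_gradient(self):
        spec = linear_phase_spectrum((0.0, 0.0))
        cfg = mw.PhaseFitConfig(stencil_radius=12)
        fit = mw.phase_gradient(spec, config=cfg, xi0=(400.0, 400.0))
        np.testing.assert_allclose(fit.gradient, 0.0, atol=1e-12)

    def test_closed_form_spectrum_gradient_is_minus_omega_sigma2_alpha(self):
        sigma = 5e-3
        alpha = np.array([0.012, -0.02])
        beta = np.array([0.15, 0.2])
        comp = mw.WaveComponent(1.0, alpha, beta)
        off = 8.0 * (np.arange(61) - 30)
        spec = mw.closed_form_spectrum(
            comp, (0, 0), sigma, OMEGA, OMEGA * beta[0] + off, OMEGA * beta[1] + off
        )
        cfg = mw.PhaseFitConfig(stencil_radius=12)
        fit = mw.phase_gradient(spec, config=cfg, xi0=OMEGA * beta)
        expect = -OMEGA * sigma**2 * alpha
        np.testing.assert_allclose(fit.gradient, expect, rtol=1e-6)

    def test_stencil_must_fit_in_grid(self):
        spec = linear_phase_spectrum((0.0, 0.0))
        with pytest.raises(ValueError, match="stencil"):
            mw.phase_gradient(spec, config=mw.PhaseFitConfig(stencil_radius=12),
                              xi0=(spec.xi_x[0], spec.xi_y[0]))


class TestLocalAttenuationVector:
    def test_lossless_wave_gives_zero_alpha(self):
        # grid large enough that the analysis patch is not boundary-clipped
        # (an asymmetrically clipped window fakes a ~1e-5 phase tilt)
        grid = mw.Grid2D(256, 256, 1e-3)
        beta = np.array([0.14, 0.14])
        f, _ = make_plane_field(grid, beta, OMEGA)
        lam = 2 * math.pi / (OMEGA * np.linalg.norm(beta))
        a = mw.local_attenuation_vector(f, grid.position(128, 128), lam, beta_hat=beta)
        assert np.linalg.norm(a) < 1e-6 * np.linalg.norm(beta)

    def test_collinear_attenuation_recovered_within_five_percent(self, grid128):
        beta = np.array([0.15, 0.15])
        alpha = 0.1 * beta
        f, comp = make_plane_field(grid128, beta, OMEGA, alpha=alpha)
        lam = 2 * math.pi / (OMEGA * np.linalg.norm(beta))
        b = mw.local_wave_vector(f, grid128.position(64, 64), lam)
        a = mw.local_attenuation_vector(f, grid128.position(64, 64), lam, beta_hat=b)
        assert np.linalg.norm(a - alpha) < 0.05 * np.linalg.norm(alpha)

    def test_conjugated_field_negates_beta_keeps_alpha(self, grid128):
        beta = np.array([0.14, 0.1])
        alpha = np.array([0.005, 0.012])
        f, _ = make_plane_field(grid128, beta, OMEGA, alpha=alpha)
        g = f.copy_with(np.conj(f.values))
        p = grid128.position(64, 64)
        sigma = 5 * grid128.h
        b0 = mw.local_wave_vector(f, p, sigma)
        b1 = mw.local_wave_vector(g, p, sigma)
        np.testing.assert_allclose(b1, -b0, rtol=1e-6)
        a0 = mw.local_attenuation_vector(f, p, sigma, beta_hat=b0)
        a1 = mw.local_attenuation_vector(g, p, sigma, beta_hat=b1)
        np.testing.assert_allclose(a1, a0, atol=1e-4 * np.linalg.norm(b0))

    def test_amplitude_scaling_leaves_alpha_unchanged(self, grid128):
        beta = np.array([0.15, 0.15])
        alpha = 0.08 * beta
        f, _ = make_plane_field(grid128, beta, OMEGA, alpha=alpha)
        g = f.copy_with((2.5 - 1.5j) * f.values)
        p = grid128.position(64, 64)
        sigma = 5 * grid128.h
        a0 = mw.local_attenuation_vector(f, p, sigma, beta_hat=beta)
        a1 = mw.local_attenuation_vector(g, p, sigma, beta_hat=beta)
        np.testing.assert_allclose(a1, a0, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("offset_frac", [0.0, 0.4, 0.9])
    def test_exact_on_closed_form_oracle_near_peak(self, offset_frac):
        # any reference xi0 within 1/sigma of omega beta recovers alpha
        sigma = 5e-3
        alpha = np.array([-0.01, 0.018])
        beta = np.array([0.18, 0.12])
        comp = mw.WaveComponent(0.5 + 1.0j, alpha, beta)
        off = 8.0 * (np.arange(81) - 40)
        spec = mw.closed_form_spectrum(
            comp, (0, 0), sigma, OMEGA, OMEGA * beta[0] + off, OMEGA * beta[1] + off
        )
        xi0 = OMEGA * beta + offset_frac / sigma * np.array([0.6, -0.8])
        fit = mw.phase_gradient(spec, config=mw.PhaseFitConfig(stencil_radius=15),
                                xi0=xi0)
        ahat = -fit.gradient / (OMEGA * sigma**2)
        assert np.linalg.norm(ahat - alpha) < 1e-6 * np.linalg.norm(alpha)

    def test_strong_attenuation_warns(self, grid128):
        beta = np.array([0.2, 0.0])
        alpha = np.array([0.09, 0.0])  # |omega alpha| sigma > 1 at sigma = 8 px
        f, _ = make_plane_field(grid128, beta, OMEGA, alpha=alpha)
        with pytest.warns(UserWarning, match="omega alpha"):
            mw.local_attenuation_vector(
                f, grid128.position(64, 64), 8 * grid128.h, beta_hat=beta
            )


class TestAttenuationMap:
    def test_homogeneous_attenuated_wave_gives_uniform_alpha(self, grid128):
        # interior probes only: asymmetric window clipping of an attenuated
        # wave biases the phase fit near the boundary (a known weakness)
        beta = np.array([0.15, 0.15])
        alpha = 0.1 * beta
        f, _ = make_plane_field(grid128, beta, OMEGA, alpha=alpha)
        lam = 2 * math.pi / (OMEGA * np.linalg.norm(beta))
        vmap = mw.attenuation_map(f, sample_spacing=8, sigma=0.75 * lam,
                                  margin=45 * grid128.h)
        err = np.linalg.norm(vmap.alpha - alpha, axis=1) / np.linalg.norm(alpha)
        assert np.max(err) < 0.10
        # small but nonzero: window truncation bends the discrete phase
        assert np.max(vmap.fit_residual) < 5e-3

    def test_alpha_less_noise_tolerant_than_beta(self, noisy_replication):
        res = noisy_replication
        lam = 2 * math.pi / (
            res.config.omega * np.linalg.norm(res.components[0].beta)
        )
        vmap = mw.attenuation_map(res.field, sample_spacing=8, sigma=0.75 * lam)
        bt = res.components[0].beta
        at = res.components[0].alpha
        be = np.linalg.norm(vmap.beta - bt, axis=1) / np.linalg.norm(bt)
        ae = np.linalg.norm(vmap.alpha - at, axis=1) / np.linalg.norm(at)
        ae = ae[np.isfinite(ae)]
        for q in (0.5, 0.75, 0.9):
            assert np.quantile(ae, q) > np.quantile(be, q)
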