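"""Local attenuation-vector (LAV) estimation.

With the centered FBI kernel, the spectral phase of a single attenuated
plane wave is linear in xi:

    theta(p; xi) = -omega sigma^2 alpha . xi + theta_0,

so the attenuation vector follows from the phase gradient at the spectral
peak xi_0 = omega beta_hat:

    alpha = -grad_xi theta / (omega sigma^2).

The gradient is computed by Gaussian-weighted least squares over a square
stencil of xi nodes around the peak, fitting two slopes plus an intercept.
Phase differences are evaluated as ``arg(W(xi) conj(W(xi_0)))``, which is
continuous across the branch cuts of the arctangent form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .fbi import DEFAULT_PAD_FACTOR, FBISpectrum, fbi_transform
from .field import WaveField
from .lwv import DEFAULT_SAMPLE_SPACING, VectorFieldMap, _scan, spectral_peak

__all__ = [
    "PhaseFitConfig",
    "PhaseFit",
    "phase_difference",
    "phase_gradient",
    "local_attenuation_vector",
    "attenuation_map",
]


@dataclass(frozen=True)
class PhaseFitConfig:
    """Weights and stencil for the spectral phase-gradient fit.

    ``s`` is the Gaussian weight width in rad/m (default ``1/(2 sigma)``,
    half the spectral lobe width of the window); ``stencil_radius`` is in
    xi-grid cells (default ``max(2, ceil(3 s / dxi))``).  The stencil must
    contain at least 6 nodes since the fit has three unknowns.
    """

    s: Optional[float] = None
    stencil_radius: Optional[int] = None

    def resolved(self, sigma: float, dxi: float):
        s = self.s if self.s is not None else 1.0 / (2.0 * sigma)
        if s <= 0:
            raise ValueError("weight width s must be positive")
        r = (
            self.stencil_radius
            if self.stencil_radius is not None
            else max(2, int(math.ceil(3.0 * s / dxi)))
        )
        if (2 * r + 1) ** 2 < 6:
            raise ValueError("stencil must contain at least 6 nodes")
        return s, r


class PhaseFit(NamedTuple):
    gradient: np.ndarray  # (2,) meters (radians per rad/m)
    theta0: float  # radians, intercept at the reference node
    residual: float  # weighted RMS misfit, radians


def phase_difference(w1, w0):
    """Phase difference arg(w1) - arg(w0), wrapped to (-pi, pi].

    Computed as ``arg(w1 conj(w0))``: exact modulo 2 pi and free of the
    +-pi/2 discontinuities of the arctangent-of-ratio form.
    """
    w0 = np.asarray(w0, dtype=complex)
    w1 = np.asarray(w1, dtype=complex)
    if np.any(w0 == 0):
        raise ValueError("reference value w0 must be non-zero")
    out = np.angle(w1 * np.conj(w0))
    return float(out) if out.ndim == 0 else out


def phase_gradient(
    spectrum: FBISpectrum,
    config: Optional[PhaseFitConfig] = None,
    xi0=None,
) -> PhaseFit:
    """Weighted least-squares gradient of the spectral phase at xi0.

    ``xi0`` defaults to the spectral peak; it is snapped to the nearest
    xi-grid node, and phase differences of the stencil nodes relative to
    that node are fitted with two slopes and an intercept under Gaussian
    weights.  Raises if the stencil is not fully contained in the xi-grid
    or the normal equations are singular.
    """
    config = config or PhaseFitConfig()
    if xi0 is None:
        xi0 = spectral_peak(spectrum).xi
    s, r = config.resolved(spectrum.sigma, spectrum.dxi)
    i, j = spectrum.nearest_node(xi0)
    nx, ny = spectrum.values.shape
    if i - r < 0 or i + r >= nx or j - r < 0 or j + r >= ny:
        raise ValueError("phase-fit stencil extends beyond the xi-grid")

    w0 = spectrum.values[i, j]
    if w0 == 0:
        raise ValueError("zero spectrum value at the reference node")
    patch = spectrum.values[i - r : i + r + 1, j - r : j + r + 1]
    dth = np.angle(patch * np.conj(w0))

    off = spectrum.dxi * np.arange(-r, r + 1)
    M, N = np.meshgrid(off, off, indexing="ij")
    wgt = np.exp(-(M**2 + N**2) / (2.0 * s**2)).ravel()
    A = np.column_stack([M.ravel(), N.ravel(), np.ones(M.size)])
    sw = np.sqrt(wgt)
    Aw = A * sw[:, None]
    bw = dth.ravel() * sw
    sol, _, rank, _ = np.linalg.lstsq(Aw, bw, rcond=None)
    if rank < 3:
        raise ValueError("degenerate stencil: singular normal equations")
    misfit = bw - Aw @ sol
    residual = float(np.sqrt(np.sum(misfit**2) / np.sum(wgt)))
    return PhaseFit(gradient=sol[:2], theta0=float(sol[2]), residual=residual)


def _alpha_from_fit(fit: PhaseFit, omega: float, sigma: float) -> np.ndarray:
    return -fit.gradient / (omega * sigma**2)


def local_attenuation_vector(
    field: WaveField,
    p,
    sigma: float,
    beta_hat=None,
    config: Optional[PhaseFitConfig] = None,
    pad_factor: int = DEFAULT_PAD_FACTOR,
) -> np.ndarray:
    """Local attenuation vector alpha(p) from the spectral phase gradient.

    ``beta_hat`` is the LWV estimate at p (estimated afresh when omitted);
    the gradient is evaluated at ``xi_0 = omega beta_hat``.  A warning is
    issued when ``|omega alpha| sigma > 1``, where the single-Gaussian peak
    model starts to degrade.
    """
    spec = fbi_transform(field, p, sigma, pad_factor=pad_factor)
    return _attenuation_at(spec, field.omega, sigma, beta_hat, config)[0]


def _attenuation_at(spec, omega, sigma, beta_hat=None, config=None):
    spec = spec.with_centering(True)
    xi0 = omega * np.asarray(beta_hat, dtype=float) if beta_hat is not None else None
    fit = phase_gradient(spec, config=config, xi0=xi0)
    alpha = _alpha_from_fit(fit, omega, sigma)
    if omega * float(np.linalg.norm(alpha)) * sigma > 1.0:
        warnings.warn(
            "|omega alpha| sigma > 1: attenuation too strong for the "
            "Gaussian-peak model at this window size",
            stacklevel=3,
        )
    return alpha, fit.residual


def attenuation_map(
    field: WaveField,
    sample_spacing: int = DEFAULT_SAMPLE_SPACING,
    sigma: float = None,
    margin: Optional[float] = None,
    config: Optional[PhaseFitConfig] = None,
    pad_factor: int = DEFAULT_PAD_FACTOR,
    min_xi_norm: Optional[float] = None,
) -> VectorFieldMap:
    """Wave and attenuation vectors over a regular grid of probe points.

    Identical sampling to :func:`mrewave.lwv.wave_vector_map`; each probe's
    FBI spectrum is reused for both the peak search and the phase fit, and
    the weighted fit residual is attached per point.
    """
    if sigma is None:
        from .lwv import suggest_sigma

        sigma = suggest_sigma(field)
    cfg = config or PhaseFitConfig()

    def alpha_fn(spec, peak, omega):
        spec = spec.with_centering(True)
        try:
            fit = phase_gradient(spec, config=cfg, xi0=peak.xi)
        except ValueError:
            # e.g. a noise peak too close to the xi-grid edge for the
            # stencil; the point is reported with alpha unavailable.
            return np.full(2, np.nan), float("nan")
        return _alpha_from_fit(fit, omega, sigma), fit.residual

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _scan(
            field, sample_spacing, sigma, margin, pad_factor, min_xi_norm, alpha_fn
        )
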