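"""Local wave-vector (LWV) estimation.

The modulus of the FBI spectrum of a local single-wave form is a Gaussian
centered exactly at ``xi = omega beta``, so the slowness vector of the
locally strongest plane-wave component is recovered as

    beta(p) = argmax_xi |W(u; p, sigma)(xi)| / omega.

The raw argmax is quantized to the FFT xi-grid; since the predicted modulus
is Gaussian, a separable log-quadratic interpolation through the peak node
and its axis neighbours localizes the peak to a small fraction of a cell
(it is exact for an exactly Gaussian peak).  A DC exclusion keeps a constant
offset from winning the argmax.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .fbi import DEFAULT_PAD_FACTOR, FBISpectrum, fbi_transform
from .field import WaveField

__all__ = [
    "DEFAULT_SAMPLE_SPACING",
    "DEFAULT_SIGMA_FACTOR",
    "SpectralPeak",
    "VectorFieldMap",
    "spectral_peak",
    "local_wave_vector",
    "wave_vector_map",
    "suggest_sigma",
]

#: Default spacing between probe points, in pixels.
DEFAULT_SAMPLE_SPACING = 4

#: Default window size as a fraction of the dominant wavelength; the useful
#: range is half to one wavelength.
DEFAULT_SIGMA_FACTOR = 0.75

#: Peaks weaker than this fraction of the map-wide median peak magnitude are
#: flagged low-contrast.
LOW_CONTRAST_FRACTION = 0.1


class SpectralPeak(NamedTuple):
    """Sub-cell-refined location and magnitude of the dominant spectral peak."""

    xi: np.ndarray  # (2,) rad/m
    magnitude: float
    node: tuple  # (i, j) index of the peak node


def _refine_axis(lm1: float, l0: float, lp1: float):
    """Log-quadratic sub-cell offset and log-magnitude correction.

    Fits a parabola through log-magnitudes at offsets (-1, 0, +1); exact for
    a Gaussian peak.  Returns (offset in cells, correction to log-magnitude);
    degenerate (non-concave) configurations fall back to the node itself.
    """
    c2 = 0.5 * (lm1 + lp1) - l0
    if not np.isfinite(c2) or c2 >= 0.0:
        return 0.0, 0.0
    c1 = 0.5 * (lp1 - lm1)
    d = -c1 / (2.0 * c2)
    d = float(np.clip(d, -0.5, 0.5))
    return d, c1 * d + c2 * d * d


def _find_peak(
    mag: np.ndarray,
    xi_x: np.ndarray,
    xi_y: np.ndarray,
    min_xi_norm: Optional[float],
) -> SpectralPeak:
    """Dominant-peak search shared by the local and global estimators."""
    dxi = float(xi_x[1] - xi_x[0])
    if min_xi_norm is None:
        min_xi_norm = dxi
    r2 = xi_x[:, None] ** 2 + xi_y[None, :] ** 2
    allowed = r2 >= min_xi_norm**2
    if not np.any(allowed):
        raise ValueError("min_xi_norm masks every xi node")
    work = np.where(allowed, mag, -np.inf)
    peak_val = work.max()
    if not np.isfinite(peak_val):
        raise ValueError("spectrum has no finite values on the allowed nodes")
    cand = np.argwhere(work == peak_val)
    if len(cand) > 1:
        # Ties: smallest |xi| (longest wavelength), then lexicographic index.
        order = np.lexsort((cand[:, 1], cand[:, 0], r2[cand[:, 0], cand[:, 1]]))
        cand = cand[order]
    i, j = map(int, cand[0])

    with np.errstate(divide="ignore"):
        logm = np.log(np.maximum(mag, 0.0))
    di = dj = 0.0
    dlog = 0.0
    if 0 < i < mag.shape[0] - 1 and np.all(mag[i - 1 : i + 2, j] > 0):
        di, c = _refine_axis(logm[i - 1, j], logm[i, j], logm[i + 1, j])
        dlog += c
    if 0 < j < mag.shape[1] - 1 and np.all(mag[i, j - 1 : j + 2] > 0):
        dj, c = _refine_axis(logm[i, j - 1], logm[i, j], logm[i, j + 1])
        dlog += c
    xi_hat = np.array([xi_x[i] + di * dxi, xi_y[j] + dj * dxi])
    return SpectralPeak(xi=xi_hat, magnitude=float(peak_val * math.exp(dlog)), node=(i, j))


def spectral_peak(
    spectrum: FBISpectrum, min_xi_norm: Optional[float] = None
) -> SpectralPeak:
    """Location and magnitude of the dominant modulus peak of an FBI spectrum.

    Nodes with ``|xi| < min_xi_norm`` (default: one xi-grid cell, excluding
    DC) are ignored.  The peak is refined to sub-cell precision by separable
    log-quadratic interpolation; ties are broken toward the smallest |xi|,
    then lexicographic node order.
    """
    if spectrum.values.size == 0:
        raise ValueError("empty spectrum")
    return _find_peak(
        np.abs(spectrum.values), spectrum.xi_x, spectrum.xi_y, min_xi_norm
    )


def local_wave_vector(
    field: WaveField,
    p,
    sigma: float,
    pad_factor: int = DEFAULT_PAD_FACTOR,
    min_xi_norm: Optional[float] = None,
) -> np.ndarray:
    """Local wave vector beta(p) = argmax_xi |W(u; p, sigma)(xi)| / omega."""
    spec = fbi_transform(field, p, sigma, pad_factor=pad_factor)
    peak = spectral_peak(spec, min_xi_norm=min_xi_norm)
    return peak.xi / field.omega


@dataclass
class VectorFieldMap:
    """Per-sample-point estimates of the local wave/attenuation vectors.

    ``xi`` is the refined spectral-peak location; ``beta = xi / omega``
    exactly, by construction.  ``alpha`` and ``fit_residual`` are filled by
    the LAV pass and None otherwise.
    """

    points: np.ndarray  # (K, 2) meters
    xi: np.ndarray  # (K, 2) rad/m
    beta: np.ndarray  # (K, 2) s/m
    peak_mag: np.ndarray  # (K,)
    omega: float
    alpha: Optional[np.ndarray] = None  # (K, 2) s/m
    fit_residual: Optional[np.ndarray] = None  # (K,) radians
    boundary_clipped: Optional[np.ndarray] = None  # (K,) bool
    low_contrast: Optional[np.ndarray] = None  # (K,) bool

    def __post_init__(self) -> None:
        k = self.points.shape[0]
        if self.boundary_clipped is None:
            self.boundary_clipped = np.zeros(k, dtype=bool)
        if self.low_contrast is None:
            self.low_contrast = np.zeros(k, dtype=bool)

    def to_dataframe(self):
        import pandas as pd

        data = {
            "x_m": self.points[:, 0],
            "y_m": self.points[:, 1],
            "beta_x": self.beta[:, 0],
            "beta_y": self.beta[:, 1],
            "xi_x": self.xi[:, 0],
            "xi_y": self.xi[:, 1],
            "peak_mag": self.peak_mag,
        }
        if self.alpha is not None:
            data["alpha_x"] = self.alpha[:, 0]
            data["alpha_y"] = self.alpha[:, 1]
            data["fit_residual"] = self.fit_residual
        flags = []
        for c, lc in zip(self.boundary_clipped, self.low_contrast):
            f = []
            if c:
                f.append("boundary-clipped")
            if lc:
                f.append("low-contrast")
            flags.append("|".join(f))
        data["flags"] = flags
        return pd.DataFrame(data)


def _sample_indices(n: int, spacing: int, lo_px: float, hi_px: float) -> np.ndarray:
    idx = np.arange(0, n, spacing)
    return idx[(idx >= lo_px) & (idx <= hi_px)]


def _scan(
    field: WaveField,
    sample_spacing: int,
    sigma: float,
    margin: Optional[float],
    pad_factor: int,
    min_xi_norm: Optional[float],
    alpha_fn=None,
) -> VectorFieldMap:
    """Run the spectral estimators over a regular grid of probe points."""
    if sample_spacing < 1:
        raise ValueError("sample spacing must be >= 1 pixel")
    grid = field.grid
    if margin is None:
        margin = 2.0 * sigma
    m_px = margin / grid.h
    ix = _sample_indices(grid.nx, sample_spacing, m_px, grid.nx - 1 - m_px)
    iy = _sample_indices(grid.ny, sample_spacing, m_px, grid.ny - 1 - m_px)
    if len(ix) == 0 or len(iy) == 0:
        raise ValueError("margin leaves no sample points")

    omega = field.omega
    pts, xis, mags, clipped = [], [], [], []
    alphas, resids = [], []
    for i in ix:
        for j in iy:
            p = grid.position(int(i), int(j))
            spec = fbi_transform(field, p, sigma, pad_factor=pad_factor)
            peak = spectral_peak(spec, min_xi_norm=min_xi_norm)
            pts.append(p)
            xis.append(peak.xi)
            mags.append(peak.magnitude)
            clipped.append(spec.boundary_clipped)
            if alpha_fn is not None:
                a, r = alpha_fn(spec, peak, omega)
                alphas.append(a)
                resids.append(r)
    pts = np.array(pts)
    xis = np.array(xis)
    mags = np.array(mags)
    vmap = VectorFieldMap(
        points=pts,
        xi=xis,
        beta=xis / omega,
        peak_mag=mags,
        omega=omega,
        alpha=np.array(alphas) if alpha_fn is not None else None,
        fit_residual=np.array(resids) if alpha_fn is not None else None,
        boundary_clipped=np.array(clipped),
    )
    med = float(np.median(mags)) if len(mags) else 0.0
    vmap.low_contrast = mags < LOW_CONTRAST_FRACTION * med
    return vmap


def wave_vector_map(
    field: WaveField,
    sample_spacing: int = DEFAULT_SAMPLE_SPACING,
    sigma: float = None,
    margin: Optional[float] = None,
    pad_factor: int = DEFAULT_PAD_FACTOR,
    min_xi_norm: Optional[float] = None,
) -> VectorFieldMap:
    """Local wave vectors over a regular grid of probe points.

    Probes are pixel centers every ``sample_spacing`` pixels, at least
    ``margin`` meters (default 2 sigma, where boundary effects dominate)
    from the field edge; with ``margin = 0`` boundary-clipped estimates are
    kept but flagged.
    """
    if sigma is None:
        sigma = suggest_sigma(field)
    return _scan(field, sample_spacing, sigma, margin, pad_factor, min_xi_norm)


def suggest_sigma(field: WaveField, factor: float = DEFAULT_SIGMA_FACTOR) -> float:
    """Window size from the dominant wavelength: sigma = factor * 2 pi/|xi_inf|.

    ``xi_inf`` is the global spectral peak of the whole field.  Factors
    outside the practically useful half-to-one-wavelength range trigger a
    warning.  A field without a dominant spectral peak (e.g. pure noise)
    raises.
    """
    if not (0.5 <= factor <= 1.0):
        warnings.warn(
            f"sigma factor {factor:g} outside the recommended [0.5, 1] range",
            stacklevel=2,
        )
    from .denoise import global_spectrum_peak  # local import to avoid a cycle

    xi_inf = global_spectrum_peak(field)
    return factor * 2.0 * math.pi / float(np.linalg.norm(xi_inf))
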