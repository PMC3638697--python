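"""LWV denoising: strongest-peak spectral filtering of wave images.

Each tile of the field is replaced by the single plane wave corresponding
to the dominant peak of the tile's FBI spectrum (local mode), or to the
globally dominant Fourier peak ``xi_inf`` of the whole field (global mode).
With a zero spectral width the filter output on a tile centered at p is

    [W(u; p, sigma)(xi(p)) / m_p] exp(i (x - p) . xi(p)),

where ``m_p`` is the discrete Gaussian window mass of the (possibly
clipped) patch; this normalization makes the filter the exact identity on a
noiseless plane wave whose ``omega beta`` sits on a spectral node.  A
positive spectral width gamma replaces the delta selection by a normalized
Gaussian bundle of nodes around the peak.  The filtered field is assembled
tile by tile (characteristic-function superposition), which can leave
visible seams where neighbouring tiles lock onto different waves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.fft

from .fbi import DEFAULT_PAD_FACTOR, fbi_transform, windowed_projection
from .field import WaveField
from .lwv import SpectralPeak, _find_peak, spectral_peak

__all__ = [
    "DenoiseConfig",
    "DegenerateSpectrumError",
    "global_spectrum_peak",
    "denoise_local",
    "denoise_global",
    "total_variation",
    "count_spectral_peaks",
]

#: A spectrum whose masked maximum is below this multiple of the median
#: modulus has no dominant wave and is treated as degenerate.
PEAK_PROMINENCE = 10.0


class DegenerateSpectrumError(ValueError):
    """The field has no dominant spectral peak (e.g. pure noise or DC)."""


@dataclass
class DenoiseConfig:
    """Parameters of the spectral filter.

    sigma : Gaussian window size, meters.
    mode : 'local' (per-tile strongest peak) or 'global' (field-wide peak).
    gamma : spectral width of the pass band in rad/m; 0 selects the single
        peak node (delta filter).
    tile : tile size in pixels; 1 reproduces per-pixel filtering exactly,
        larger tiles reuse one spectrum per tile.
    """

    sigma: float
    mode: str = "local"
    gamma: float = 0.0
    tile: int = 4
    min_xi_norm: Optional[float] = None
    pad_factor: int = DEFAULT_PAD_FACTOR

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.tile < 1:
            raise ValueError("tile size must be >= 1 pixel")


def _global_spectrum(field: WaveField, pad_factor: int = DEFAULT_PAD_FACTOR):
    grid = field.grid
    n = scipy.fft.next_fast_len(pad_factor * max(grid.nx, grid.ny))
    F = np.fft.fftshift(scipy.fft.fft2(field.values, s=(n, n)))
    xi = np.fft.fftshift(2.0 * math.pi * np.fft.fftfreq(n, d=grid.h))
    return F, xi


def global_spectrum_peak(
    field: WaveField,
    min_xi_norm: Optional[float] = None,
    pad_factor: int = DEFAULT_PAD_FACTOR,
) -> np.ndarray:
    """Dominant wave vector xi_inf (rad/m) of the whole-field spectrum.

    The argmax of the modulus of the zero-padded discrete Fourier transform
    over ``|xi| >= min_xi_norm`` (default one cell, excluding DC), sub-cell
    refined.  Raises :class:`DegenerateSpectrumError` when the masked
    maximum is less than ``PEAK_PROMINENCE`` times the median modulus -
    the signature of a flat or noise-only spectrum.
    """
    F, xi = _global_spectrum(field, pad_factor)
    mag = np.abs(F)
    peak = _find_peak(mag, xi, xi, min_xi_norm)
    dxi = float(xi[1] - xi[0])
    lim = min_xi_norm if min_xi_norm is not None else dxi
    r2 = xi[:, None] ** 2 + xi[None, :] ** 2
    med = float(np.median(mag[r2 >= lim**2]))
    if not peak.magnitude > PEAK_PROMINENCE * med:
        raise DegenerateSpectrumError(
            "no dominant spectral peak: max/median modulus "
            f"{peak.magnitude / med if med else float('inf'):.2f} < {PEAK_PROMINENCE:g}"
        )
    return peak.xi


def _tile_slices(n: int, tile: int):
    for t0 in range(0, n, tile):
        yield t0, min(t0 + tile, n)


def _filter(field: WaveField, config: DenoiseConfig, xi_fixed=None) -> WaveField:
    grid = field.grid
    if config.tile > min(grid.nx, grid.ny):
        raise ValueError("tile larger than the field")
    X, Y = grid.positions()
    out = np.zeros(grid.shape, dtype=complex)
    for i0, i1 in _tile_slices(grid.nx, config.tile):
        for j0, j1 in _tile_slices(grid.ny, config.tile):
            xs = X[i0:i1, j0:j1]
            ys = Y[i0:i1, j0:j1]
            p = np.array([xs.mean(), ys.mean()])
            spec = fbi_transform(
                field, p, config.sigma, pad_factor=config.pad_factor
            )
            if xi_fixed is None:
                peak = spectral_peak(spec, min_xi_norm=config.min_xi_norm)
                xi_hat, node = peak.xi, peak.node
            else:
                xi_hat = np.asarray(xi_fixed, dtype=float)
                node = spec.nearest_node(xi_hat)
            if config.gamma == 0.0:
                # Direct projection at the refined peak: exact local complex
                # amplitude for a plane wave whose omega beta equals xi_hat.
                amp = windowed_projection(field, p, config.sigma, xi_hat)
                amp /= spec.window_mass
                out[i0:i1, j0:j1] = amp * np.exp(
                    1j * ((xs - p[0]) * xi_hat[0] + (ys - p[1]) * xi_hat[1])
                )
            else:
                out[i0:i1, j0:j1] = _gaussian_bundle(
                    spec, xi_hat, node, config.gamma, xs - p[0], ys - p[1]
                )
    return field.copy_with(out)


def _gaussian_bundle(spec, xi_hat, node, gamma, dx, dy):
    """Normalized Gaussian-weighted superposition of nodes around the peak."""
    reach = max(1, int(math.ceil(4.0 * gamma / spec.dxi)))
    i, j = node
    nx, ny = spec.values.shape
    i0, i1 = max(0, i - reach), min(nx, i + reach + 1)
    j0, j1 = max(0, j - reach), min(ny, j + reach + 1)
    gx = spec.xi_x[i0:i1]
    gy = spec.xi_y[j0:j1]
    DX, DY = np.meshgrid(gx - xi_hat[0], gy - xi_hat[1], indexing="ij")
    w = np.exp(-(DX**2 + DY**2) / (2.0 * gamma**2))
    w /= w.sum()
    amps = w * spec.values[i0:i1, j0:j1] / spec.window_mass
    # sum over the selected nodes of amp * e^{i (x-p).xi}
    ex = np.exp(1j * dx[..., None] * gx[None, None, :])  # (tx, ty, nxsel)
    ey = np.exp(1j * dy[..., None] * gy[None, None, :])
    return np.einsum("kl,ijk,ijl->ij", amps, ex, ey)


def denoise_local(field: WaveField, config: DenoiseConfig) -> WaveField:
    """Per-tile strongest-peak filtering (locally adaptive denoising)."""
    return _filter(field, config, xi_fixed=None)


def denoise_global(field: WaveField, config: DenoiseConfig) -> WaveField:
    """Filtering around the field-wide dominant peak xi_inf.

    Every tile keeps only the spectral content at the global peak, which
    collapses a single-dominant-wave field to a near-sinusoidal wave with a
    single peak in the Fourier domain.
    """
    xi_inf = global_spectrum_peak(
        field, min_xi_norm=config.min_xi_norm, pad_factor=config.pad_factor
    )
    return _filter(field, config, xi_fixed=xi_inf)


def total_variation(arr: np.ndarray) -> float:
    """Anisotropic total variation of a real 2-D array (smoothness measure)."""
    arr = np.asarray(arr, dtype=float)
    return float(
        np.abs(np.diff(arr, axis=0)).sum() + np.abs(np.diff(arr, axis=1)).sum()
    )


def count_spectral_peaks(
    field: WaveField,
    rel_threshold: float = 0.5,
    min_xi_norm: Optional[float] = None,
    pad_factor: int = DEFAULT_PAD_FACTOR,
) -> int:
    """Number of well-separated local maxima of the field's Fourier modulus.

    Counts local maxima (over a 5x5 neighbourhood) exceeding
    ``rel_threshold`` times the global maximum, outside the DC exclusion.
    """
    from scipy.ndimage import maximum_filter

    F, xi = _global_spectrum(field, pad_factor)
    mag = np.abs(F)
    dxi = float(xi[1] - xi[0])
    lim = min_xi_norm if min_xi_norm is not None else dxi
    r2 = xi[:, None] ** 2 + xi[None, :] ** 2
    mag = np.where(r2 >= lim**2, mag, 0.0)
    mx = maximum_filter(mag, size=5, mode="constant")
    peaks = (mag == mx) & (mag >= rel_threshold * mag.max()) & (mag > 0)
    return int(np.count_nonzero(peaks))
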