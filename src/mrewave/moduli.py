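"""Conversion between local wave/attenuation vectors and viscoelastic moduli.

For a time-harmonic shear wave written locally as ``a exp(omega (alpha + i
beta) . (x - p))``, substituting into the viscoelastic Helmholtz equation
``(rho omega^2 + (G' + i G'') Laplacian) u = 0`` yields the algebraic link

    rho + (G' + i G'') (alpha + i beta) . (alpha + i beta) = 0

between the slowness-like vectors ``alpha`` (attenuation, s/m) and ``beta``
(propagation, s/m) and the complex shear modulus ``G' + i G''`` (Pa).  This
module evaluates that link in both directions, applies it point-wise to
estimated vector fields, and computes per-ROI statistics of the resulting
modulus maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .lwv import VectorFieldMap

__all__ = [
    "DEFAULT_RHO",
    "DEFAULT_LOW_BETA_CUTOFF",
    "ROI",
    "ROIStats",
    "ModuliMap",
    "InfeasibleModuliError",
    "moduli_from_vectors",
    "storage_modulus_approx",
    "vectors_from_moduli",
    "moduli_map",
    "roi_stats",
]

#: Default mass density of soft tissue / gel phantoms, kg/m^3.
DEFAULT_RHO = 1000.0

#: Points with |beta| below this fraction of the median |beta| are masked:
#: a vanishing wave vector sends G' = rho/|beta|^2 to infinity and usually
#: marks a region where the data cannot be trusted (wave shadows, failed
#: phase unwrapping).
DEFAULT_LOW_BETA_CUTOFF = 0.1


class InfeasibleModuliError(ValueError):
    """Requested (G', G'', angle) combination admits no real (alpha, beta)."""


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region of interest, bounds in meters."""

    name: str
    x0: float
    x1: float
    y0: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"ROI {self.name!r} has empty extent")

    @classmethod
    def from_fractions(cls, name, fx0, fx1, fy0, fy1, grid) -> "ROI":
        """Build an ROI from fractional coordinates of a grid's extent."""
        (xmin, xmax), (ymin, ymax) = grid.extent()
        return cls(
            name,
            xmin + fx0 * (xmax - xmin),
            xmin + fx1 * (xmax - xmin),
            ymin + fy0 * (ymax - ymin),
            ymin + fy1 * (ymax - ymin),
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of shape (K,) for points of shape (K, 2)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (points[:, 0] >= self.x0)
            & (points[:, 0] <= self.x1)
            & (points[:, 1] >= self.y0)
            & (points[:, 1] <= self.y1)
        )


@dataclass(frozen=True)
class ROIStats:
    """Mean / population standard deviation of a modulus over an ROI."""

    name: str
    quantity: str  # "storage" or "loss"
    mean: float
    std: float
    count: int
    bounds: tuple = ()


def _pairs(alpha, beta):
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.shape != beta.shape or alpha.shape[-1] != 2:
        raise ValueError("alpha and beta must have matching (..., 2) shapes")
    return alpha, beta


def moduli_from_vectors(alpha, beta, rho: float = DEFAULT_RHO):
    """Storage and loss moduli (Pa) from attenuation/wave vectors (s/m).

    Evaluates

        (G', G'') = rho / ((|alpha|^2 - |beta|^2)^2 + 4 (alpha.beta)^2)
                    * (|beta|^2 - |alpha|^2,  2 alpha.beta)

    element-wise over trailing-axis-2 arrays.  ``G''`` may come out negative
    when the estimated ``alpha`` points against the propagation direction;
    such values are reported, not clipped.

    Raises
    ------
    ValueError
        If the denominator vanishes (|alpha| = |beta| with alpha
        perpendicular to beta), where the map is singular.
    """
    alpha, beta = _pairs(alpha, beta)
    if rho <= 0:
        raise ValueError("rho must be positive")
    a2 = np.sum(alpha**2, axis=-1)
    b2 = np.sum(beta**2, axis=-1)
    ab = np.sum(alpha * beta, axis=-1)
    denom = (a2 - b2) ** 2 + 4.0 * ab**2
    if np.any(denom == 0.0):
        raise ValueError(
            "singular (alpha, beta): |alpha| = |beta| and alpha . beta = 0"
        )
    gp = rho * (b2 - a2) / denom
    gpp = rho * 2.0 * ab / denom
    if np.ndim(a2) == 0:
        return float(gp), float(gpp)
    return gp, gpp


def storage_modulus_approx(beta, rho: float = DEFAULT_RHO):
    """Small-attenuation storage modulus G' = rho / |beta|^2 (Pa).

    The leading-order form of the exact link when |alpha| << |beta|;
    equivalently G' = rho c^2 with phase speed c = 1/|beta|.
    """
    beta = np.asarray(beta, dtype=float)
    b2 = np.sum(beta**2, axis=-1)
    if np.any(b2 == 0.0):
        raise ValueError("beta must be non-zero")
    out = rho / b2
    return float(out) if np.ndim(out) == 0 else out


def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def vectors_from_moduli(
    gp: float,
    gpp: float,
    rho: float = DEFAULT_RHO,
    beta_dir=(1.0, 0.0),
    angle_alpha_beta: float = 0.0,
):
    """Invert the moduli link: construct (alpha, beta) realizing (G', G'').

    Solves ``|alpha|^2 - |beta|^2 = -G' rho / |G*|^2`` and
    ``2 alpha.beta = G'' rho / |G*|^2`` (with ``|G*|^2 = G'^2 + G''^2``) for
    the vector lengths, placing ``beta`` along ``beta_dir`` and ``alpha`` at
    ``angle_alpha_beta`` radians counterclockwise from it.

    For ``G'' > 0`` the angle must satisfy ``cos(angle) > 0`` (and
    ``cos(angle) < 0`` for ``G'' < 0``); otherwise the length system has no
    real solution and :class:`InfeasibleModuliError` is raised.
    """
    if gp <= 0:
        raise InfeasibleModuliError("G' must be positive")
    if rho <= 0:
        raise ValueError("rho must be positive")
    bd = np.asarray(beta_dir, dtype=float)
    nb = np.linalg.norm(bd)
    if nb == 0:
        raise ValueError("beta_dir must be non-zero")
    bd = bd / nb

    g2 = gp * gp + gpp * gpp
    A = -gp * rho / g2  # |alpha|^2 - |beta|^2  (negative)
    B = gpp * rho / g2  # 2 |alpha| |beta| cos(angle)
    c = math.cos(angle_alpha_beta)
    if gpp == 0.0:
        x, y = 0.0, math.sqrt(-A)
    else:
        if abs(c) < 1e-12 or math.copysign(1.0, c) != math.copysign(1.0, B):
            feasible = "(0, 1]" if gpp > 0 else "[-1, 0)"
            raise InfeasibleModuliError(
                "infeasible alpha-beta angle: cos(angle) must lie in "
                f"{feasible} for G'' = {gpp:g} Pa"
            )
        p = B / (2.0 * c)  # |alpha| |beta| > 0
        # x^2 solves t^2 - A t - p^2 = 0; with A < 0 the direct root
        # (A + hypot)/2 cancels catastrophically for small p, so use the
        # algebraically equivalent stable form.
        x2 = 2.0 * p * p / (math.hypot(A, 2.0 * p) - A)
        x = math.sqrt(x2)
        y = p / x
    beta = y * bd
    alpha = x * _rot(bd, angle_alpha_beta)
    return alpha, beta


def eq3_residual(alpha, beta, gp, gpp, rho: float = DEFAULT_RHO):
    """|rho + (G' + iG'') (alpha + i beta).(alpha + i beta)|, for checking."""
    alpha, beta = _pairs(alpha, beta)
    z = np.sum((alpha + 1j * beta) ** 2, axis=-1)
    r = np.abs(rho + (np.asarray(gp) + 1j * np.asarray(gpp)) * z)
    return float(r) if np.ndim(r) == 0 else r


@dataclass
class ModuliMap:
    """Per-sample-point storage/loss moduli with a validity mask.

    ``reason`` holds a short code per masked point ('' when valid):
    ``low-beta`` (|beta| below the cutoff), ``boundary`` (the FBI window was
    clipped at the field edge), ``degenerate`` (singular moduli link).
    """

    points: np.ndarray  # (K, 2) meters
    gp: np.ndarray  # (K,) Pa, NaN where masked
    gpp: Optional[np.ndarray]  # (K,) Pa or None when alpha was unavailable
    rho: float
    valid: np.ndarray  # (K,) bool
    reason: np.ndarray  # (K,) str codes

    def to_dataframe(self):
        import pandas as pd

        data = {
            "x_m": self.points[:, 0],
            "y_m": self.points[:, 1],
            "Gp_Pa": self.gp,
            "Gpp_Pa": self.gpp if self.gpp is not None else np.nan,
            "mask": self.valid.astype(int),
            "reason": self.reason,
        }
        return pd.DataFrame(data)


def moduli_map(
    vmap: "VectorFieldMap",
    rho: float = DEFAULT_RHO,
    low_beta_cutoff: float = DEFAULT_LOW_BETA_CUTOFF,
) -> ModuliMap:
    """Point-wise moduli from an estimated vector-field map.

    Uses the exact link when the map carries attenuation vectors and the
    lossless approximation G' = rho/|beta|^2 otherwise.  Points whose
    |beta| falls below ``low_beta_cutoff`` times the median |beta| are
    masked (``low-beta``), as are boundary-clipped estimates (``boundary``).
    """
    if vmap.points.shape[0] == 0:
        raise ValueError("empty vector-field map")
    beta = vmap.beta
    K = beta.shape[0]
    bnorm = np.linalg.norm(beta, axis=1)
    med = float(np.median(bnorm[np.isfinite(bnorm)])) if K else 0.0

    valid = np.ones(K, dtype=bool)
    reason = np.full(K, "", dtype=object)

    low = ~np.isfinite(bnorm) | (bnorm < low_beta_cutoff * med)
    valid[low] = False
    reason[low] = "low-beta"
    clipped = np.asarray(vmap.boundary_clipped, dtype=bool)
    newly = valid & clipped
    valid[newly] = False
    reason[newly] = "boundary"

    gp = np.full(K, np.nan)
    gpp: Optional[np.ndarray] = None
    if vmap.alpha is not None:
        gpp = np.full(K, np.nan)
        a2 = np.sum(vmap.alpha**2, axis=1)
        b2 = bnorm**2
        ab = np.sum(vmap.alpha * beta, axis=1)
        denom = (a2 - b2) ** 2 + 4.0 * ab**2
        degen = valid & ((denom == 0.0) | ~np.isfinite(denom))
        valid[degen] = False
        reason[degen] = "degenerate"
        sel = valid
        gp[sel] = rho * (b2[sel] - a2[sel]) / denom[sel]
        gpp[sel] = rho * 2.0 * ab[sel] / denom[sel]
    else:
        sel = valid
        gp[sel] = rho / bnorm[sel] ** 2
    return ModuliMap(
        points=np.asarray(vmap.points, dtype=float),
        gp=gp,
        gpp=gpp,
        rho=rho,
        valid=valid,
        reason=reason,
    )


def roi_stats(mmap: ModuliMap, roi: ROI, quantity: str = "storage") -> ROIStats:
    """Mean and population std of a modulus over the unmasked ROI points."""
    if quantity not in ("storage", "loss"):
        raise ValueError("quantity must be 'storage' or 'loss'")
    vals = mmap.gp if quantity == "storage" else mmap.gpp
    if vals is None:
        raise ValueError("map carries no loss modulus (no attenuation vectors)")
    sel = mmap.valid & roi.contains(mmap.points)
    if not np.any(sel):
        raise ValueError(f"ROI {roi.name!r} contains no valid points")
    v = vals[sel]
    return ROIStats(
        name=roi.name,
        quantity=quantity,
        mean=float(np.mean(v)),
        std=float(np.std(v)),  # population (divide-by-N)
        count=int(v.size),
        bounds=(roi.x0, roi.x1, roi.y0, roi.y1),
    )
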