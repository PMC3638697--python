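"""File formats and figure generation.

Canonical field container: paired real/imaginary arrays (``<stem>_real.npy``
and ``<stem>_imag.npy``, or ``.txt`` delimited matrices) plus a JSON sidecar
``<stem>.json`` carrying the pixel spacing (meters), vibration frequency
(Hz), grid shape/origin and optional ROI definitions.  Snapshot stacks
travel as multi-page TIFF with the same sidecar.  Vector and modulus maps
export as delimited tables; figures (quiver overlays, modulus maps,
spectra) are regenerable artifacts, never inputs.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np

from .field import Grid2D, SnapshotStack, WaveField

__all__ = [
    "save_field",
    "load_field",
    "save_snapshots",
    "load_snapshots",
    "write_manifest",
    "quiver_overlay",
    "field_image",
    "spectrum_image",
    "moduli_image",
]


def _sidecar(grid: Grid2D, frequency_hz: float, extra: Optional[dict] = None) -> dict:
    meta = {
        "h_m": grid.h,
        "frequency_hz": frequency_hz,
        "nx": grid.nx,
        "ny": grid.ny,
        "origin_m": list(grid.origin),
    }
    if extra:
        meta.update(extra)
    return meta


def save_field(stem: str, field: WaveField, extra_meta: Optional[dict] = None,
               fmt: str = "npy") -> None:
    """Write a complex field as paired real/imag arrays plus a JSON sidecar."""
    if fmt not in ("npy", "txt"):
        raise ValueError("fmt must be 'npy' or 'txt'")
    if fmt == "npy":
        np.save(stem + "_real.npy", np.real(field.values))
        np.save(stem + "_imag.npy", np.imag(field.values))
    else:
        np.savetxt(stem + "_real.txt", np.real(field.values))
        np.savetxt(stem + "_imag.txt", np.imag(field.values))
    meta = _sidecar(field.grid, field.frequency_hz, extra_meta)
    meta["format"] = fmt
    with open(stem + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_field(stem: str) -> WaveField:
    """Read a field written by :func:`save_field` (sidecar is mandatory)."""
    sidecar = stem + ".json"
    if not os.path.exists(sidecar):
        raise FileNotFoundError(
            f"missing sidecar {sidecar}: pixel spacing and frequency are required"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("h_m", "frequency_hz"):
        if key not in meta:
            raise KeyError(f"sidecar {sidecar} lacks required key {key!r}")
    fmt = meta.get("format", "npy")
    if fmt == "npy":
        re = np.load(stem + "_real.npy")
        im = np.load(stem + "_imag.npy")
    else:
        re = np.loadtxt(stem + "_real.txt")
        im = np.loadtxt(stem + "_imag.txt")
    grid = Grid2D(
        meta.get("nx", re.shape[0]),
        meta.get("ny", re.shape[1]),
        meta["h_m"],
        tuple(meta.get("origin_m", (0.0, 0.0))),
    )
    return WaveField(grid, re + 1j * im, meta["frequency_hz"])


def save_snapshots(stem: str, stack: SnapshotStack) -> None:
    """Write a snapshot stack as a multi-page TIFF plus a JSON sidecar."""
    import tifffile

    tifffile.imwrite(stem + ".tiff", stack.snapshots.astype(np.float32))
    meta = _sidecar(stack.grid, stack.frequency_hz,
                    {"n_snapshots": stack.n, "advance_sign": stack.advance_sign})
    with open(stem + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_snapshots(stem: str) -> SnapshotStack:
    import tifffile

    with open(stem + ".json") as fh:
        meta = json.load(fh)
    snaps = np.asarray(tifffile.imread(stem + ".tiff"), dtype=float)
    grid = Grid2D(meta["nx"], meta["ny"], meta["h_m"],
                  tuple(meta.get("origin_m", (0.0, 0.0))))
    return SnapshotStack(grid, snaps, meta["frequency_hz"],
                         meta.get("advance_sign", 1))


def write_manifest(path: str, payload: dict) -> None:
    """Record the exact run configuration (config echo, seed, versions)."""
    import mrewave

    payload = dict(payload)
    payload["versions"] = {
        "mrewave": mrewave.__version__,
        "numpy": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Figures (lazy matplotlib import; Agg backend)
# ---------------------------------------------------------------------------


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def _imextent(grid: Grid2D):
    (x0, x1), (y0, y1) = grid.extent()
    return (x0, x1, y0, y1)


def field_image(field: WaveField, path: str, part: str = "real") -> None:
    """Grayscale image of Re u, Im u or |u|."""
    plt = _plt()
    arr = {"real": np.real, "imag": np.imag, "abs": np.abs}[part](field.values)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(arr.T, origin="lower", extent=_imextent(field.grid),
                   cmap="gray")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def quiver_overlay(field: WaveField, vmap, path: str, which: str = "beta",
                   scale: Optional[float] = None) -> None:
    """Vector arrows over the real part of the wave image."""
    plt = _plt()
    vec = getattr(vmap, which)
    if vec is None:
        raise ValueError(f"map carries no {which!r} vectors")
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.imshow(np.real(field.values).T, origin="lower",
              extent=_imextent(field.grid), cmap="gray")
    ax.quiver(vmap.points[:, 0], vmap.points[:, 1], vec[:, 0], vec[:, 1],
              color="red", scale=scale, width=0.003)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(which)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def spectrum_image(field: WaveField, path: str, pad_factor: int = 4) -> None:
    """Modulus of the field's Fourier transform."""
    from .denoise import _global_spectrum

    plt = _plt()
    F, xi = _global_spectrum(field, pad_factor)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(np.abs(F).T, origin="lower",
                   extent=(xi[0], xi[-1], xi[0], xi[-1]))
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel(r"$\xi_x$ (rad/m)")
    ax.set_ylabel(r"$\xi_y$ (rad/m)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def moduli_image(mmap, path: str, quantity: str = "storage") -> None:
    """Scatter map of a modulus over the sample points (masked points blank)."""
    plt = _plt()
    vals = mmap.gp if quantity == "storage" else mmap.gpp
    if vals is None:
        raise ValueError("map carries no loss modulus")
    sel = mmap.valid
    fig, ax = plt.subplots(figsize=(5.5, 5))
    sc = ax.scatter(mmap.points[sel, 0], mmap.points[sel, 1],
                    c=vals[sel] / 1e3, s=14, marker="s", cmap="gray")
    fig.colorbar(sc, ax=ax, shrink=0.8, label=f"{quantity} modulus (kPa)")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
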