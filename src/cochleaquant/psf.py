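"""Point-spread-function model used for rendering and deconvolution.

The confocal PSF is approximated by a separable 3D Gaussian parameterised by a
lateral width ``sigma_xy`` and an axial width ``sigma_z`` (both in micrometres),
sampled on the voxel grid of the acquisition.  This is the standard widefield /
confocal approximation; it is fully reproducible and adequate for the moderate
numerical apertures at which ribbon-synapse stacks are acquired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PointSpreadFunction", "make_psf"]


@dataclass(frozen=True)
class PointSpreadFunction:
    """A discretised PSF kernel.

    Parameters
    ----------
    kernel
        Non-negative weights on a ``(z, y, x)`` grid with odd extent along
        every axis, summing to one.
    voxel_dims
        Physical voxel dimensions ``(dx, dy, dz)`` in micrometres.
    profiles
        Optional separable factorisation ``(pz, py, px)`` with
        ``kernel = pz x py x px``; when present, convolutions run as three
        1D passes instead of a 3D FFT.
    """

    kernel: np.ndarray
    voxel_dims: tuple[float, float, float]
    profiles: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 3:
            raise ValueError("PSF kernel must be 3-dimensional (z, y, x)")
        if np.any(k < 0):
            raise ValueError("PSF kernel weights must be non-negative")
        if any(s % 2 == 0 for s in k.shape):
            raise ValueError(f"PSF kernel extent must be odd along every axis, got {k.shape}")
        if abs(float(k.sum()) - 1.0) > 1e-9:
            raise ValueError("PSF kernel must sum to 1 within 1e-9")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        object.__setattr__(self, "kernel", k)

    @property
    def is_delta(self) -> bool:
        """True when the kernel is a single-voxel identity."""
        return self.kernel.shape == (1, 1, 1)


def make_psf(
    sigma_xy: float,
    sigma_z: float,
    voxel_dims: tuple[float, float, float],
    truncate: float = 3.0,
) -> PointSpreadFunction:
    """Build a separable Gaussian PSF sampled on the voxel grid.

    Parameters
    ----------
    sigma_xy, sigma_z
        Gaussian widths in micrometres, laterally and axially.
    voxel_dims
        ``(dx, dy, dz)`` voxel dimensions in micrometres.
    truncate
        Kernel support in units of sigma per side.  As ``truncate`` approaches
        zero the kernel degenerates to a single-voxel delta.

    Returns
    -------
    PointSpreadFunction
        Normalised kernel on a ``(z, y, x)`` grid with odd extents.
    """
    if sigma_xy <= 0 or sigma_z <= 0:
        raise ValueError("PSF sigmas must be positive")
    dx, dy, dz = voxel_dims
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel dimensions must be positive")
    if truncate < 0:
        raise ValueError("truncate must be non-negative")

    def axis_profile(sigma: float, step: float) -> np.ndarray:
        half = int(np.ceil(truncate * sigma / step - 1e-12))
        x = np.arange(-half, half + 1) * step
        return np.exp(-0.5 * (x / sigma) ** 2)

    pz = axis_profile(sigma_z, dz)
    py = axis_profile(sigma_xy, dy)
    px = axis_profile(sigma_xy, dx)
    pz, py, px = pz / pz.sum(), py / py.sum(), px / px.sum()
    kernel = pz[:, None, None] * py[None, :, None] * px[None, None, :]
    kernel /= kernel.sum()
    return PointSpreadFunction(
        kernel=kernel, voxel_dims=tuple(voxel_dims), profiles=(pz, py, px)
    )
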