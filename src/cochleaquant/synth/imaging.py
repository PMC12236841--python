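"""Synthetic confocal fields of inner-hair-cell ribbon synapses.

The generator emulates the quantified content of a cochlear whole-mount
z-stack: a row of 10-20 IHCs, each bearing a ring of pre/postsynaptic puncta
pairs around its basal pole (plus optional unpaired "orphans"), imaged with a
Gaussian PSF under Poisson photon noise and Gaussian read noise.  Every
planted punctum's position, volume, channel and pairing is recorded as ground
truth so the downstream counting and volumetry stages can be scored against
a known answer.

Geometry and acquisition defaults follow the study conditions: 0.11 um
pixels, 0.2 or 0.3 um z-step, 10-20 cells per field, 0.04-5 um^3 admissible
punctum volumes, and a 0.3 um synaptic-cleft offset between paired centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..psf import PointSpreadFunction
from ..stack import ConfocalStack

__all__ = [
    "Punctum",
    "CellFootprint",
    "GroundTruth",
    "NoiseModel",
    "FieldGeometry",
    "plant_ground_truth",
    "render_stack",
    "rasterize_puncta",
    "default_field_shape",
    "lognormal_volume_dist",
    "COUNTING_VOXELS",
    "VOLUMETRIC_VOXELS",
]

#: Acquisition voxel dimensions (dx, dy, dz) in um for the two branches.
COUNTING_VOXELS = (0.11, 0.11, 0.3)
VOLUMETRIC_VOXELS = (0.11, 0.11, 0.2)


@dataclass(frozen=True)
class Punctum:
    """One planted fluorescent punctum."""

    center_um: tuple[float, float, float]  # (x, y, z)
    volume_um3: float
    channel: str  # "ribbon" or "receptor"
    pair_id: int | None = None


@dataclass(frozen=True)
class CellFootprint:
    """Elliptical IHC footprint in the projection plane."""

    cell_id: int
    center_um: tuple[float, float]  # (x, y)
    semi_axes_um: tuple[float, float]  # (ax, ay)
    region_label: str = "apex"

    def contains(self, x_um: float, y_um: float, scale: float = 1.0) -> bool:
        cx, cy = self.center_um
        ax, ay = self.semi_axes_um
        return ((x_um - cx) / (ax * scale)) ** 2 + ((y_um - cy) / (ay * scale)) ** 2 <= 1.0


@dataclass(frozen=True)
class GroundTruth:
    """Planted puncta and cell footprints; the oracle for recovery tests."""

    puncta: tuple[Punctum, ...]
    cells: tuple[CellFootprint, ...]
    seed: int
    geometry: "FieldGeometry"

    def __post_init__(self) -> None:
        per_pair: dict[int, list[str]] = {}
        for p in self.puncta:
            if p.volume_um3 <= 0:
                raise ValueError("punctum volumes must be positive")
            if p.channel not in ("ribbon", "receptor"):
                raise ValueError(f"unknown channel {p.channel!r}")
            if p.pair_id is not None:
                per_pair.setdefault(p.pair_id, []).append(p.channel)
        for pid, chans in per_pair.items():
            if sorted(chans) != ["receptor", "ribbon"]:
                raise ValueError(
                    f"pair {pid} must appear on exactly one ribbon and one receptor punctum"
                )

    @property
    def pair_ids(self) -> tuple[int, ...]:
        return tuple(sorted({p.pair_id for p in self.puncta if p.pair_id is not None}))

    def puncta_by_channel(self, channel: str) -> tuple[Punctum, ...]:
        return tuple(p for p in self.puncta if p.channel == channel)

    def counts_per_cell(self) -> dict[int, dict[str, int]]:
        """Planted per-cell counts of ribbon, receptor and paired puncta."""
        out: dict[int, dict[str, int]] = {}
        for cell in self.cells:
            out[cell.cell_id] = {"ribbon": 0, "receptor": 0, "paired": 0}
        for p in self.puncta:
            owner = min(
                self.cells,
                key=lambda c: (p.center_um[0] - c.center_um[0]) ** 2
                + (p.center_um[1] - c.center_um[1]) ** 2,
            )
            rec = out[owner.cell_id]
            rec[p.channel] += 1
            if p.pair_id is not None and p.channel == "ribbon":
                rec["paired"] += 1
        return out


@dataclass(frozen=True)
class FieldGeometry:
    """Physical layout of the synthetic organ-of-Corti field.

    Distances in micrometres.  Cells sit in a single row along x; puncta
    rings surround each basal pole at ``ring_scale`` of the footprint with
    small radial/angular/axial jitter, which keeps neighbouring puncta
    resolvable the way real basal-pole ribbons are.
    """

    cell_pitch: float = 12.0
    cell_semi_axes: tuple[float, float] = (5.0, 3.8)
    margin_x: float = 6.0
    field_height_y: float = 16.0
    field_depth_z: float = 4.0
    ring_scale: float = 0.92
    radial_jitter: float = 0.10
    angular_jitter_frac: float = 0.08
    z_band_center: float = 2.0
    z_jitter: float = 0.25
    cleft_um: float = 0.3

    def field_extent(self, n_cells: int) -> tuple[float, float, float]:
        """(x, y, z) extent in um for ``n_cells`` cells."""
        x = 2 * self.margin_x + self.cell_pitch * (n_cells - 1)
        return (x, self.field_height_y, self.field_depth_z)


def lognormal_volume_dist(
    median_um3: float = 0.35,
    sigma_log: float = 0.4,
    lo: float = 0.1,
    hi: float = 2.0,
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Log-normal punctum-volume sampler clipped to an admissible range.

    The default median of 0.35 um^3 with ~40% log-spread matches reported
    ribbon / receptor-patch volumes and sits inside the biologically
    admissible 0.04-5 um^3 window, above the sizing resolution of the
    default PSF.
    """
    if lo <= 0:
        raise ValueError("volume distribution support must lie in (0, inf)")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        v = np.exp(rng.normal(math.log(median_um3), sigma_log, size=n))
        return np.clip(v, lo, hi)

    return sample


def _ring_angles(
    ax: float, ay: float, n_slots: int, rng: np.random.Generator, jitter_frac: float
) -> np.ndarray:
    """Parameter angles of ``n_slots`` points uniform in arc length on an
    ellipse, with a random phase and +/- ``jitter_frac`` of a slot of jitter."""
    theta = np.linspace(0.0, 2 * math.pi, 2048)
    ds = np.hypot(ax * np.sin(theta), ay * np.cos(theta))
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(theta))])
    total = s[-1]
    targets = (
        rng.uniform(0, total)
        + (np.arange(n_slots) + rng.uniform(-jitter_frac, jitter_frac, n_slots))
        * total
        / n_slots
    ) % total
    return np.interp(targets, s, theta)


def plant_ground_truth(
    n_cells: int = 10,
    pairs_per_cell: int | Callable[[np.random.Generator], int] = 16,
    orphan_rate: float | tuple[float, float] = 0.0,
    volume_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    geometry: FieldGeometry = FieldGeometry(),
    region_label: str = "apex",
) -> GroundTruth:
    """Plant cells and synaptic puncta with known positions and volumes.

    Parameters
    ----------
    n_cells
        Number of IHCs in the field (the study images 10-20 per stack).
    pairs_per_cell
        Constant count or a callable drawing a count per cell.
    orphan_rate
        Expected unpaired puncta per planted pair, per channel
        (``(ribbon_rate, receptor_rate)`` or one scalar for both).
    volume_dist
        Per-channel volume sampler; default is
        :func:`lognormal_volume_dist`.
    seed
        Seed for the deterministic generator.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(orphan_rate, (int, float)):
        orphan_rate = (float(orphan_rate), float(orphan_rate))
    if not all(0.0 <= r <= 1.0 for r in orphan_rate):
        raise ValueError("orphan rates must lie in [0, 1]")
    if volume_dist is None:
        volume_dist = lognormal_volume_dist()

    rng = np.random.default_rng(seed)
    geo = geometry
    _, ey, _ = geo.field_extent(n_cells)
    cy = ey / 2.0

    cells = tuple(
        CellFootprint(
            cell_id=i + 1,
            center_um=(geo.margin_x + geo.cell_pitch * i, cy),
            semi_axes_um=geo.cell_semi_axes,
            region_label=region_label,
        )
        for i in range(n_cells)
    )

    puncta: list[Punctum] = []
    next_pair = 1
    ax, ay = geo.cell_semi_axes
    ring_ax, ring_ay = ax * geo.ring_scale, ay * geo.ring_scale
    for cell in cells:
        n_pairs = pairs_per_cell(rng) if callable(pairs_per_cell) else int(pairs_per_cell)
        if n_pairs < 0:
            raise ValueError("pairs_per_cell must be non-negative")
        n_orph = tuple(rng.binomial(n_pairs, r) if n_pairs > 0 else 0 for r in orphan_rate)
        n_slots = n_pairs + sum(n_orph)
        if n_slots == 0:
            continue
        # slots uniform in arc length (not angle), with bounded jitter, keep
        # nearest-neighbour spacing even all around the elliptical ring
        angles = _ring_angles(ring_ax, ring_ay, n_slots, rng, geo.angular_jitter_frac)
        order = rng.permutation(n_slots)
        roles = (["pair"] * n_pairs + ["orphan_ribbon"] * n_orph[0] + ["orphan_receptor"] * n_orph[1])
        vols_r = volume_dist(rng, n_slots)
        vols_g = volume_dist(rng, n_slots)
        cx0, cy0 = cell.center_um
        for slot, role_idx in enumerate(order):
            role = roles[role_idx]
            th = angles[slot]
            rj = rng.uniform(-geo.radial_jitter, geo.radial_jitter)
            x = cx0 + (ring_ax + rj) * math.cos(th)
            y = cy0 + (ring_ay + rj) * math.sin(th)
            z = geo.z_band_center + rng.uniform(-geo.z_jitter, geo.z_jitter)
            # unit outward normal of the ring ellipse, for the cleft offset
            nx, ny = math.cos(th) / ring_ax, math.sin(th) / ring_ay
            nn = math.hypot(nx, ny)
            nx, ny = nx / nn, ny / nn
            if role == "pair":
                pid = next_pair
                next_pair += 1
                puncta.append(Punctum((x, y, z), float(vols_r[slot]), "ribbon", pid))
                puncta.append(
                    Punctum(
                        (x + geo.cleft_um * nx, y + geo.cleft_um * ny, z),
                        float(vols_g[slot]),
                        "receptor",
                        pid,
                    )
                )
            elif role == "orphan_ribbon":
                puncta.append(Punctum((x, y, z), float(vols_r[slot]), "ribbon", None))
            else:
                puncta.append(Punctum((x, y, z), float(vols_g[slot]), "receptor", None))

    return GroundTruth(puncta=tuple(puncta), cells=cells, seed=seed, geometry=geo)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise plus additive Gaussian read noise.

    ``photon_scale`` multiplies rendered signal amplitudes before the Poisson
    draw; ``background`` is the mean background photon count; ``read_sigma``
    is the Gaussian read-noise standard deviation (counts).  With
    ``shot_noise=False`` and ``read_sigma=0`` the renderer is exact.
    """

    photon_scale: float = 1.0
    read_sigma: float = 2.0
    background: float = 10.0
    shot_noise: bool = True

    @classmethod
    def none(cls, background: float = 0.0) -> "NoiseModel":
        return cls(photon_scale=1.0, read_sigma=0.0, background=background, shot_noise=False)


#: Rendered signal peak amplitude (photon counts) per channel.
CHANNEL_AMPLITUDES = {"ribbon": 200.0, "receptor": 160.0, "cell": 40.0}


def default_field_shape(
    n_cells: int,
    voxel_dims: tuple[float, float, float] = VOLUMETRIC_VOXELS,
    geometry: FieldGeometry = FieldGeometry(),
) -> tuple[int, int, int]:
    """Stack shape ``(nz, ny, nx)`` covering the field of ``n_cells`` cells."""
    ex, ey, ez = geometry.field_extent(n_cells)
    dx, dy, dz = voxel_dims
    return (int(round(ez / dz)), int(round(ey / dy)), int(round(ex / dx)))


def _ellipsoid_semi_axes(volume_um3: float, elongation: float) -> tuple[float, float]:
    """Lateral and axial semi-axes (a, c) of an ellipsoid of given volume."""
    a = (3.0 * volume_um3 / (4.0 * math.pi * elongation)) ** (1.0 / 3.0)
    return a, a * elongation


def _rasterize_punctum(
    grid: np.ndarray,
    p: Punctum,
    voxel_dims: tuple[float, float, float],
    elongation: float,
    amplitude: float,
) -> int:
    """Paint a solid ellipsoid of exactly round(volume / voxel volume) voxels.

    Voxels are ranked by normalised ellipsoid distance from the punctum
    centre (ties broken by index order), making the painted voxel count, and
    hence the planted volume, exact by construction.
    """
    dx, dy, dz = voxel_dims
    voxvol = dx * dy * dz
    n_target = max(1, int(round(p.volume_um3 / voxvol)))
    a, c = _ellipsoid_semi_axes(p.volume_um3, elongation)
    x0, y0, z0 = p.center_um
    nz, ny, nx = grid.shape
    # generous candidate box around the centre
    rx = max(2, int(math.ceil(2.0 * a / dx)) + 1)
    ry = max(2, int(math.ceil(2.0 * a / dy)) + 1)
    rz = max(2, int(math.ceil(2.0 * c / dz)) + 1)
    ix0, iy0, iz0 = int(round(x0 / dx - 0.5)), int(round(y0 / dy - 0.5)), int(round(z0 / dz - 0.5))
    zz = np.arange(max(0, iz0 - rz), min(nz, iz0 + rz + 1))
    yy = np.arange(max(0, iy0 - ry), min(ny, iy0 + ry + 1))
    xx = np.arange(max(0, ix0 - rx), min(nx, ix0 + rx + 1))
    if len(zz) == 0 or len(yy) == 0 or len(xx) == 0:
        raise ValueError("punctum lies outside the rendered field")
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    # voxel centres in physical coordinates
    d2 = (
        (((X + 0.5) * dx - x0) / a) ** 2
        + (((Y + 0.5) * dy - y0) / a) ** 2
        + (((Z + 0.5) * dz - z0) / c) ** 2
    )
    flat = np.argsort(d2, axis=None, kind="stable")[:n_target]
    grid[Z.ravel()[flat], Y.ravel()[flat], X.ravel()[flat]] += amplitude
    return n_target


def rasterize_puncta(
    gt: GroundTruth,
    channel: str,
    shape: tuple[int, int, int],
    voxel_dims: tuple[float, float, float],
    elongation: float = 2.5,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Noise- and blur-free occupancy rendering of one channel."""
    grid = np.zeros(shape, dtype=float)
    for p in gt.puncta_by_channel(channel):
        _rasterize_punctum(grid, p, voxel_dims, elongation, amplitude)
    return grid


def render_stack(
    gt: GroundTruth,
    psf: PointSpreadFunction,
    noise: NoiseModel = NoiseModel(),
    voxel_dims: tuple[float, float, float] = VOLUMETRIC_VOXELS,
    shape: tuple[int, int, int] | None = None,
    seed: int = 0,
    amplitudes: dict[str, float] | None = None,
) -> ConfocalStack:
    """Render a three-channel stack from planted ground truth.

    Each punctum is painted as a solid ellipsoid of its ground-truth volume
    (axial elongation matching the PSF anisotropy), the result is convolved
    with ``psf`` and degraded with Poisson + Gaussian noise.  Intensities
    stay well below saturation under the default amplitudes.
    """
    if shape is None:
        shape = default_field_shape(len(gt.cells), voxel_dims, gt.geometry)
    dx, dy, dz = voxel_dims
    nz, ny, nx = shape
    ex, ey, ez = nx * dx, ny * dy, nz * dz
    amps = dict(CHANNEL_AMPLITUDES)
    if amplitudes:
        amps.update(amplitudes)

    offenders = [
        p
        for p in gt.puncta
        if not (0 <= p.center_um[0] < ex and 0 <= p.center_um[1] < ey and 0 <= p.center_um[2] < ez)
    ]
    if offenders:
        raise ValueError(
            f"{len(offenders)} puncta lie outside the {ex:.2f} x {ey:.2f} x {ez:.2f} um field: "
            + "; ".join(f"{p.channel}@{p.center_um}" for p in offenders[:5])
        )

    elongation = psf_elongation = _psf_elongation(psf)
    rng = np.random.default_rng(seed)
    channels: dict[str, np.ndarray] = {}
    from .._fft import ReflectConvolver

    conv = None if psf.is_delta else ReflectConvolver(shape, psf.kernel, psf.profiles)
    for ch in ("ribbon", "receptor"):
        signal = rasterize_puncta(gt, ch, shape, voxel_dims, elongation, amps[ch])
        channels[ch] = signal
    # hair-cell channel: filled elliptical cylinders through the stack depth
    cell_grid = np.zeros(shape, dtype=float)
    yy = (np.arange(ny) + 0.5) * dy
    xx = (np.arange(nx) + 0.5) * dx
    Xg, Yg = np.meshgrid(xx, yy)
    for cell in gt.cells:
        cx0, cy0 = cell.center_um
        ax, ay = cell.semi_axes_um
        mask = ((Xg - cx0) / ax) ** 2 + ((Yg - cy0) / ay) ** 2 <= 1.0
        cell_grid[:, mask] += amps["cell"]
    channels["cell"] = cell_grid

    for ch, signal in channels.items():
        blurred = conv.convolve(signal) if conv is not None else signal
        expected = noise.background + noise.photon_scale * np.clip(blurred, 0, None)
        if noise.shot_noise:
            observed = rng.poisson(expected).astype(float)
        else:
            observed = expected
        if noise.read_sigma > 0:
            observed = observed + rng.normal(0.0, noise.read_sigma, size=shape)
        channels[ch] = np.clip(observed, 0, None)

    meta = {
        "seed": seed,
        "n_cells": len(gt.cells),
        "noise": {
            "photon_scale": noise.photon_scale,
            "read_sigma": noise.read_sigma,
            "background": noise.background,
            "shot_noise": noise.shot_noise,
        },
        "psf_elongation": psf_elongation,
    }
    return ConfocalStack(channels=channels, voxel_dims=voxel_dims, metadata=meta)


def _psf_elongation(psf: PointSpreadFunction) -> float:
    """Axial/lateral width ratio of the PSF (in physical units)."""
    k = psf.kernel
    if psf.is_delta:
        return 2.5
    dx, dy, dz = psf.voxel_dims

    def width(profile: np.ndarray, step: float) -> float:
        idx = np.arange(len(profile))
        w = profile / profile.sum()
        mu = (idx * w).sum()
        return math.sqrt(max(((idx - mu) ** 2 * w).sum(), 1e-12)) * step

    wz = width(k.sum(axis=(1, 2)), dz)
    wx = width(k.sum(axis=(0, 1)), dx)
    if wx < 1e-9:
        return 2.5
    return max(1.0, wz / wx)
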