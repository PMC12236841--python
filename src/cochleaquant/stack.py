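"""The multi-channel confocal stack container and its TIFF/JSON round trip.

A :class:`ConfocalStack` holds three aligned 3D voxel grids -- the ribbon
(CtBP2), receptor (GluA2) and hair-cell (MyosinVIIa) channels -- together with
the physical voxel dimensions.  Stacks are stored as multi-channel TIFF with a
JSON metadata sidecar carrying the voxel dimensions and channel order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ConfocalStack", "CHANNELS"]

CHANNELS = ("ribbon", "receptor", "cell")


@dataclass
class ConfocalStack:
    """Aligned 3D intensity grids, one per immunolabel.

    ``channels`` maps channel name to a ``(z, y, x)`` array; ``voxel_dims``
    is ``(dx, dy, dz)`` in micrometres.
    """

    channels: dict[str, np.ndarray]
    voxel_dims: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        shapes = {ch: np.asarray(g).shape for ch, g in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError("all channels must be 3-dimensional (z, y, x)")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, g in self.channels.items():
            g = np.asarray(g, dtype=float)
            if np.any(g < 0):
                raise ValueError(f"channel {ch!r} has negative intensities")
            self.channels[ch] = g
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def save(self, path: str | Path) -> None:
        """Write a ``(channel, z, y, x)`` TIFF plus a ``.json`` sidecar."""
        path = Path(path)
        names = sorted(self.channels)
        data = np.stack([self.channels[ch] for ch in names]).astype(np.float32)
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = {
            "channels": names,
            "voxel_dims_um": list(self.voxel_dims),
            "axes": "CZYX",
            **self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ConfocalStack":
        path = Path(path)
        data = tifffile.imread(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        names = sidecar["channels"]
        if data.ndim == 3:  # single channel
            data = data[None]
        channels = {ch: data[i].astype(float) for i, ch in enumerate(names)}
        meta = {
            k: v for k, v in sidecar.items() if k not in ("channels", "voxel_dims_um", "axes")
        }
        return cls(
            channels=channels,
            voxel_dims=tuple(sidecar["voxel_dims_um"]),
            metadata=meta,
        )
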