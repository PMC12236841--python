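"""Intensity thresholding used by the 2D counting and 3D volumetric branches.

Two selectable, scale-covariant methods are provided:

``robust_background``
    ``median + k * MAD`` of the whole image (raw median absolute deviation,
    default ``k = 4``).  Sits just above the background fluctuation level, so
    it keeps faint puncta at the cost of generous footprints.
``otsu``
    Otsu's between-class variance criterion.  Lands between the background
    and puncta intensity modes.

Both methods commute with a global intensity rescaling, so particle counts
are invariant to acquisition gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["ThresholdConfig", "threshold_value"]

_METHODS = ("robust_background", "otsu")


@dataclass(frozen=True)
class ThresholdConfig:
    method: str = "robust_background"
    k: float = 4.0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(
                f"unknown threshold method {self.method!r}; supported: {_METHODS}"
            )


def threshold_value(image: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()) -> float:
    """Compute the scalar threshold for ``image`` under ``cfg``.

    Pixels strictly above the returned value are foreground.
    """
    data = np.asarray(image, dtype=float)
    if data.size == 0:
        raise ValueError("cannot threshold an empty image")
    if cfg.method == "robust_background":
        med = float(np.median(data))
        mad = float(np.median(np.abs(data - med)))
        return med + cfg.k * mad
    # otsu
    if np.ptp(data) == 0:
        # constant image: put the threshold at the constant so nothing is
        # strictly above it
        return float(data.flat[0])
    return float(threshold_otsu(data))
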