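"""Distortion-product otoacoustic emission (DPOAE) extraction.

Two primary tones f1 and f2 (f2/f1 = 1.2, L2 = L1 - 10 dB) drive the
cochlear amplifier; a healthy cochlea emits a distortion product at
2*f1 - f2 that is picked up by an ear-canal microphone sampled at 4 us
intervals.  The DP amplitude is read from the pressure spectrum, the noise
floor from adjacent analysis bins, and the DPOAE threshold is the lowest
f2 level whose signal-to-noise-floor ratio exceeds one.

Estimator design: recordings are cut into analysis segments (Hann-windowed).
The DP bin, which carries a phase-coherent tone, is *vector*-averaged across
segments; the adjacent noise-floor bins are *magnitude*-averaged.  Vector
averaging suppresses incoherent noise in the DP bin by ~sqrt(n_segments),
so on noise-only recordings the SNR sits below one instead of fluctuating
around it -- which is what makes the "SNR > 1" threshold rule usable as an
automatic criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abr import ThresholdResult

__all__ = [
    "PressureRecording",
    "PrimaryPair",
    "DpoaeMeasurement",
    "SpectrumConfig",
    "SPL_REFERENCE_AMPLITUDE",
    "db_to_amplitude",
    "amplitude_to_db",
    "design_primaries",
    "measure_dp",
    "dpoae_threshold",
]

#: Calibration convention: a pure tone of peak amplitude ``a`` corresponds to
#: ``20*log10(a / SPL_REFERENCE_AMPLITUDE)`` dB SPL.  All level arithmetic is
#: relative, so the absolute value of the reference is immaterial.
SPL_REFERENCE_AMPLITUDE = 2e-5


def db_to_amplitude(level_db: float, ref: float = SPL_REFERENCE_AMPLITUDE) -> float:
    return ref * 10.0 ** (level_db / 20.0)


def amplitude_to_db(amplitude: float, ref: float = SPL_REFERENCE_AMPLITUDE) -> float:
    return 20.0 * np.log10(max(amplitude, 1e-300) / ref)


@dataclass
class PressureRecording:
    """Sampled ear-canal pressure with stimulus metadata."""

    samples: np.ndarray
    fs: float
    metadata: dict

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("recording must be a non-empty 1D series")


@dataclass(frozen=True)
class PrimaryPair:
    """Primary-tone parameters and the implied DP frequency."""

    f1: float
    f2: float
    l1: float
    l2: float
    dp_frequency: float

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("primary frequencies must be positive")
        if abs(self.f2 / self.f1 - 1.2) > 1.2 * 1e-6:
            raise ValueError("f2/f1 must equal 1.2 within 1e-6 relative")
        if abs(self.l2 - (self.l1 - 10.0)) > 1e-9:
            raise ValueError("L2 must equal L1 - 10 dB")
        if self.dp_frequency <= 0:
            raise ValueError("DP frequency must be positive")


def design_primaries(f2: float, l1: float) -> PrimaryPair:
    """Primary parameters from the f2 frequency and the f1 level.

    f1 = f2 / 1.2, L2 = L1 - 10 and the distortion product sits at
    2*f1 - f2.
    """
    if f2 <= 0:
        raise ValueError("f2 must be positive")
    f1 = f2 / 1.2
    return PrimaryPair(f1=f1, f2=f2, l1=float(l1), l2=float(l1) - 10.0, dp_frequency=2 * f1 - f2)


@dataclass(frozen=True)
class DpoaeMeasurement:
    """DP amplitude, noise floor and their linear-amplitude ratio."""

    dp_level_db: float
    noise_floor_db: float
    snr: float  # linear amplitude ratio
    f2_level_db: float
    dp_frequency: float = 0.0


@dataclass(frozen=True)
class SpectrumConfig:
    """Windowed spectral analysis settings.

    ``n_segments`` Hann-windowed segments are averaged (vector average at
    the DP frequency, magnitude average for the floor).  The noise floor is
    the mean magnitude of ``floor_bins_per_side`` bins each side of the DP
    frequency, separated by ``guard_bins``, excluding anything within
    ``primary_exclusion_bins`` of either primary.
    """

    n_segments: int = 3
    floor_bins_per_side: int = 5
    guard_bins: int = 1
    primary_exclusion_bins: int = 3
    amplitude_floor: float = SPL_REFERENCE_AMPLITUDE * 1e-3  # -60 dB SPL numerical floor


def _windowed_amplitudes(
    x: np.ndarray, fs: float, freqs: np.ndarray, n_segments: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency (coherent, incoherent) amplitude estimates.

    Returns peak-amplitude estimates from Hann-windowed segment DFTs
    evaluated exactly at each frequency: the magnitude of the complex
    (vector) mean across segments, and the mean of per-segment magnitudes.
    """
    n = x.size // n_segments
    if n < 16:
        raise ValueError("recording too short for the configured segmentation")
    w = np.hanning(n)
    wsum = w.sum()
    coh = np.empty(len(freqs))
    inc = np.empty(len(freqs))
    t = np.arange(n) / fs
    for j, f in enumerate(freqs):
        cs = []
        for s in range(n_segments):
            seg = x[s * n : (s + 1) * n]
            tt = t + s * n / fs  # absolute time keeps tone phase coherent
            cs.append(np.sum(w * seg * np.exp(-2j * np.pi * f * tt)))
        cs = np.asarray(cs)
        coh[j] = 2.0 * np.abs(cs.mean()) / wsum
        inc[j] = 2.0 * np.mean(np.abs(cs)) / wsum
    return coh, inc


def measure_dp(
    recording: PressureRecording,
    primaries: PrimaryPair,
    cfg: SpectrumConfig = SpectrumConfig(),
) -> DpoaeMeasurement:
    """Extract the 2f1-f2 amplitude, the adjacent-bin noise floor and SNR."""
    x = recording.samples
    n = x.size // cfg.n_segments
    if n < 16:
        raise ValueError("recording too short for the configured segmentation")
    df = recording.fs / n  # bin spacing of one analysis segment
    fdp = primaries.dp_frequency
    for fprim in (primaries.f1, primaries.f2):
        if abs(fprim - fdp) < cfg.primary_exclusion_bins * df:
            raise ValueError(
                "DP bin collides with a primary at the configured resolution"
            )
    offsets = np.arange(cfg.guard_bins + 1, cfg.guard_bins + cfg.floor_bins_per_side + 1)
    floor_freqs = [
        f
        for sign in (-1.0, 1.0)
        for f in fdp + sign * offsets * df
        if f > 0
        and abs(f - primaries.f1) > cfg.primary_exclusion_bins * df
        and abs(f - primaries.f2) > cfg.primary_exclusion_bins * df
    ]
    freqs = np.array([fdp, *floor_freqs])
    coh, inc = _windowed_amplitudes(x, recording.fs, freqs, cfg.n_segments)
    dp_amp = max(float(coh[0]), cfg.amplitude_floor)
    floor_amp = max(float(inc[1:].mean()), cfg.amplitude_floor)
    return DpoaeMeasurement(
        dp_level_db=amplitude_to_db(dp_amp),
        noise_floor_db=amplitude_to_db(floor_amp),
        snr=dp_amp / floor_amp,
        f2_level_db=primaries.l2,
        dp_frequency=fdp,
    )


def dpoae_threshold(measurements: list[DpoaeMeasurement]) -> ThresholdResult:
    """Lowest f2 level with SNR > 1, sustained at all higher tested levels.

    Censored when even the highest level fails the criterion.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    levels = [m.f2_level_db for m in measurements]
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("f2 levels must be strictly ascending")
    max_level = levels[-1]
    responding = [m.snr > 1.0 for m in measurements]
    if not responding[-1]:
        return ThresholdResult.censored_at(max_level)
    idx = len(responding) - 1
    while idx > 0 and responding[idx - 1]:
        idx -= 1
    return ThresholdResult.at(levels[idx], max_level)
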