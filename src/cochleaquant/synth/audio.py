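"""Synthetic ABR waveform series and ear-canal recordings.

The ABR generator plants a wave complex with a known threshold: below the
planted threshold the averaged records contain only noise; at and above it
the complex grows linearly with level.  Averages are generated directly at
the statistically exact residual noise level (sigma/sqrt(n)) rather than by
materialising 1024 individual sweeps; polarity sub-averages carry any
stimulus artifact with opposite signs so that it cancels exactly in the
full average, mirroring alternated-polarity acquisition.

The ear-canal generator emits the two primaries, an optional distortion
product at 2f1-f2 of configurable level, and white noise calibrated so that
the expected adjacent-bin magnitude matches the requested noise floor under
the default analysis settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..abr import AbrSeries, AbrWaveform
from ..dpoae import (
    PressureRecording,
    PrimaryPair,
    db_to_amplitude,
    design_primaries,
)

__all__ = [
    "AbrTemplate",
    "simulate_abr_series",
    "simulate_ear_canal",
    "simulate_dp_ladder",
]

DEFAULT_LEVELS = tuple(range(20, 85, 5))


@dataclass(frozen=True)
class AbrTemplate:
    """Planted wave complex: Gaussian peaks at fixed latencies.

    ``components`` are (latency_ms, width_ms, relative amplitude) triples
    covering waves 1-3; the complex is normalised so that its wave-1-window
    peak-to-peak amplitude is 1, then scaled to
    ``base_amplitude_uv + growth_uv_per_db * (level - threshold)``.
    """

    components: tuple[tuple[float, float, float], ...] = (
        (1.5, 0.15, 1.0),   # P1
        (2.0, 0.20, -0.6),  # N1
        (2.7, 0.20, 0.5),   # P2
        (3.3, 0.25, -0.35),
        (4.1, 0.25, 0.3),   # P3
    )
    base_amplitude_uv: float = 0.5
    growth_uv_per_db: float = 0.1
    wave1_window_ms: tuple[float, float] = (1.0, 2.5)

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-normalised complex sampled at ``t_ms`` (zero before onset)."""
        y = np.zeros_like(t_ms)
        for lat, width, amp in self.components:
            y += amp * np.exp(-0.5 * ((t_ms - lat) / width) ** 2)
        y[t_ms < 0] = 0.0
        t0, t1 = self.wave1_window_ms
        win = y[(t_ms >= t0) & (t_ms <= t1)]
        pp = float(win.max() - win.min()) if win.size else 1.0
        return y / max(pp, 1e-12)

    def amplitude_at(self, level_db: float, threshold_db: float) -> float:
        if level_db < threshold_db:
            return 0.0
        return self.base_amplitude_uv + self.growth_uv_per_db * (level_db - threshold_db)


def simulate_abr_series(
    threshold_db: float = 45.0,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    noise_sigma_uv: float = 0.5,
    n_epochs: int = 1024,
    fs: float = 40000.0,
    pre_ms: float = 2.0,
    post_ms: float = 8.0,
    frequency_khz: float = 16.0,
    template: AbrTemplate = AbrTemplate(),
    artifact_uv: float = 0.0,
    seed: int = 0,
) -> AbrSeries:
    """Simulate an averaged level series with a planted wave-1 threshold.

    ``noise_sigma_uv`` is the per-epoch noise; each polarity sub-average
    carries residual noise sigma/sqrt(n_epochs/2).  A threshold above the
    level range yields pure-noise averages at every level.
    """
    if not levels:
        raise ValueError("level list must not be empty")
    if noise_sigma_uv < 0:
        raise ValueError("noise sigma must be non-negative")
    if n_epochs < 2 or n_epochs % 2:
        raise ValueError("n_epochs must be an even count >= 2")
    rng = np.random.default_rng(seed)
    n = int(round((pre_ms + post_ms) * fs / 1000.0))
    t_ms = -pre_ms + np.arange(n) * 1000.0 / fs
    shape = template.waveform(t_ms)
    half_n = n_epochs // 2
    half_sigma = noise_sigma_uv / math.sqrt(half_n)
    # stimulus artifact: cos^2-enveloped burst right at onset, sign tied to
    # stimulus polarity
    if artifact_uv:
        art = np.zeros(n)
        on = (t_ms >= 0) & (t_ms < 0.5)
        art[on] = artifact_uv * np.sin(2 * np.pi * 8.0 * t_ms[on]) * np.cos(
            np.pi * (t_ms[on] - 0.25) / 0.5
        ) ** 2
    else:
        art = np.zeros(n)

    waveforms = []
    for level in sorted(levels):
        signal = template.amplitude_at(level, threshold_db) * shape
        half_a = signal + art + rng.normal(0.0, half_sigma, n)
        half_b = signal - art + rng.normal(0.0, half_sigma, n)
        waveforms.append(
            AbrWaveform(
                samples=(half_a + half_b) / 2.0,
                fs=fs,
                level_db=float(level),
                frequency_khz=frequency_khz,
                n_epochs_averaged=n_epochs,
                t_start_ms=-pre_ms,
                half_a=half_a,
                half_b=half_b,
            )
        )
    return AbrSeries(waveforms=waveforms)


def simulate_ear_canal(
    f2: float,
    l1_db: float,
    dp_level_db: float | None = None,
    noise_floor_db: float | None = -10.0,
    fs: float = 250000.0,
    duration_s: float = 1.5,
    n_segments: int = 3,
    seed: int = 0,
) -> tuple[PressureRecording, PrimaryPair]:
    """Synthesize an ear-canal recording with an optional planted DP.

    ``noise_floor_db`` calibrates white noise so that the expected
    Hann-windowed adjacent-bin magnitude equals the requested floor at the
    given segmentation; ``None`` disables noise entirely.
    """
    primaries = design_primaries(f2, l1_db)
    if fs <= 2 * max(primaries.f1, primaries.f2):
        raise ValueError("sampling rate must exceed twice the highest primary")
    n = int(round(fs * duration_s))
    if duration_s * primaries.dp_frequency < 10:
        raise ValueError("duration must cover >= 10 DP periods")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = db_to_amplitude(primaries.l1) * np.sin(2 * np.pi * primaries.f1 * t)
    x += db_to_amplitude(primaries.l2) * np.sin(2 * np.pi * primaries.f2 * t)
    if dp_level_db is not None:
        phase = rng.uniform(0, 2 * np.pi)
        x += db_to_amplitude(dp_level_db) * np.sin(2 * np.pi * primaries.dp_frequency * t + phase)
    if noise_floor_db is not None:
        seg = n // n_segments
        w = np.hanning(seg)
        # expected magnitude of the windowed-DFT amplitude estimate of white
        # noise: E[A] = sigma * sqrt(pi * sum(w^2)) / sum(w)
        target = db_to_amplitude(noise_floor_db)
        sigma = target * w.sum() / math.sqrt(math.pi * float((w**2).sum()))
        x = x + rng.normal(0.0, sigma, n)
    meta = {
        "f1": primaries.f1,
        "f2": primaries.f2,
        "l1_db": primaries.l1,
        "l2_db": primaries.l2,
        "dp_frequency": primaries.dp_frequency,
        "dp_level_db": dp_level_db,
        "noise_floor_db": noise_floor_db,
        "seed": seed,
    }
    return PressureRecording(samples=x, fs=fs, metadata=meta), primaries


def simulate_dp_ladder(
    f2: float,
    emission_threshold_db: float = 50.0,
    levels_l2: tuple[float, ...] = DEFAULT_LEVELS,
    noise_floor_db: float = -10.0,
    margin_db: float = 6.0,
    growth_db_per_db: float = 1.0,
    fs: float = 250000.0,
    duration_s: float = 0.15,
    seed: int = 0,
) -> list[tuple[PressureRecording, PrimaryPair]]:
    """A level ladder with a planted emission threshold.

    At f2 levels below ``emission_threshold_db`` no DP is emitted; at and
    above it the DP level starts ``margin_db`` above the noise floor and
    grows with stimulus level.
    """
    out = []
    rng = np.random.default_rng(seed)
    for l2 in sorted(levels_l2):
        if l2 >= emission_threshold_db:
            dp = noise_floor_db + margin_db + growth_db_per_db * (l2 - emission_threshold_db)
        else:
            dp = None
        rec, prim = simulate_ear_canal(
            f2,
            l1_db=l2 + 10.0,
            dp_level_db=dp,
            noise_floor_db=noise_floor_db,
            fs=fs,
            duration_s=duration_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append((rec, prim))
    return out
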