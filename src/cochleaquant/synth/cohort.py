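"""Synthetic cohort tables with a genotype x exposure x age effect model.

Emulates the group structure of a developmental noise-exposure study: three
genotypes (WT, a9KO with absent efferent feedback, a9KI with enhanced
feedback), control and noise-exposed arms (broadband 1-16 kHz, 100 dB SPL,
1 h at P15), several test frequencies and postnatal ages.  Each metric has a
baseline mean and dispersion; planted effects shift the group mean for
selected combinations, giving a known truth for power and type-I studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetricModel", "Effect", "CohortDesign", "simulate_cohort"]

GENOTYPES = ("WT", "a9KO", "a9KI")
ARMS = ("control", "exposed")


@dataclass(frozen=True)
class MetricModel:
    """Sampling model of one measured quantity."""

    baseline: float
    sd: float
    family: str = "normal"  # or "lognormal" (sd is then the log-scale sd)
    unit: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass(frozen=True)
class Effect:
    """Additive shift of a metric's mean for matching rows.

    ``where`` may constrain genotype, arm, age and/or frequency_khz; rows
    matching every stated key receive ``delta`` on the (natural-scale) mean.
    """

    metric: str
    delta: float
    where: dict = field(default_factory=dict)

    _KEYS = ("genotype", "arm", "age", "frequency_khz")

    def matches(self, genotype: str, arm: str, age: float, frequency_khz: float) -> bool:
        row = {"genotype": genotype, "arm": arm, "age": age, "frequency_khz": frequency_khz}
        for k, v in self.where.items():
            if k not in self._KEYS:
                raise ValueError(f"unknown effect selector {k!r}")
            if row[k] != v:
                return False
        return True


@dataclass(frozen=True)
class CohortDesign:
    """Study design of the simulated cohort.

    Defaults mirror the study conditions: all three genotypes, both arms,
    histology/physiology ages P15 and P75, the noise-band test frequencies,
    and about a dozen animals per group.
    """

    genotypes: tuple[str, ...] = GENOTYPES
    arms: tuple[str, ...] = ARMS
    ages: tuple[float, ...] = (15.0, 75.0)
    frequencies_khz: tuple[float, ...] = (8.0, 16.0, 22.65)
    metrics: dict = field(
        default_factory=lambda: {
            "synapses_per_ihc": MetricModel(16.0, 2.5, unit="count/IHC"),
            "abr_threshold_db": MetricModel(35.0, 5.0, unit="dB SPL"),
            "wave1_amplitude_uv": MetricModel(4.0, 1.0, unit="uV"),
        }
    )
    effects: tuple[Effect, ...] = ()
    n_per_group: int = 12
    exposure: dict = field(
        default_factory=lambda: {
            "band_khz": (1.0, 16.0),
            "level_db_spl": 100.0,
            "duration_h": 1.0,
            "age_days": 15,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        bad = set(self.genotypes) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        bad = set(self.arms) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arms: {sorted(bad)}")
        for e in self.effects:
            if e.metric not in self.metrics:
                raise ValueError(f"effect references unknown metric {e.metric!r}")


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """One row per animal x age x frequency x metric, deterministic in seed.

    Columns: animal_id, genotype, arm, age, frequency_khz, metric, value,
    unit.  Group means follow the design's effect model exactly.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    animal = 0
    for genotype in design.genotypes:
        for arm in design.arms:
            for _ in range(design.n_per_group):
                animal += 1
                aid = f"{genotype}-{arm}-{animal:03d}"
                for age in design.ages:
                    for f in design.frequencies_khz:
                        for name, model in design.metrics.items():
                            mean = model.baseline + sum(
                                e.delta
                                for e in design.effects
                                if e.metric == name and e.matches(genotype, arm, age, f)
                            )
                            if model.family == "normal":
                                value = rng.normal(mean, model.sd)
                            else:
                                value = float(
                                    np.exp(rng.normal(np.log(max(mean, 1e-12)), model.sd))
                                )
                            rows.append(
                                {
                                    "animal_id": aid,
                                    "genotype": genotype,
                                    "arm": arm,
                                    "age": age,
                                    "frequency_khz": f,
                                    "metric": name,
                                    "value": value,
                                    "unit": model.unit,
                                }
                            )
    return pd.DataFrame(rows)
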