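"""Synthetic assay data with known ground truth.

Emulates the structure of the wet-lab endpoints so every analysis stage is
testable without experimental raw data:

* clonogenic colony counts: Poisson around seeded x PE x LQ survival at the
  2D dose of the applied activity; the target-negative line receives no
  specific dose (no radioligand binding), so its counts are flat in
  activity;
* spheroid diameters: exponential growth slowed by a saturating inhibition
  I(D) = D / (D + D50) of the 3D dose, three lognormal-noise measurements
  per spheroid — with D50 far below the lowest treated dose the treated
  curves collapse onto a plateau, the behaviour seen in targeted spheroids;
* viability luminescence: proportional to viable cell number, LQ survival
  compounded over elapsed time (so the 2D/3D fold grows with observation
  day), multiplicative lognormal noise; the 2D and 3D arms take their
  doses from the same conversion table, which is the entire mechanism
  behind the fold difference.

Doses come from a :class:`~welldose.scoring.ConversionTable`; generators
are deterministic given the RNG and emit frames matching the CSV schemas
consumed by :mod:`welldose.radiobiology`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import ConversionTable

__all__ = [
    "CellLineProfile",
    "SyntheticDesign",
    "lq_survival",
    "growth_inhibition",
    "designed_fold",
    "synth_clonogenic",
    "synth_spheroids",
    "synth_viability",
]


@dataclass(frozen=True)
class CellLineProfile:
    """One cell line: does it bind the radioligand, and how does it plate."""

    name: str
    targeted: bool
    plating_efficiency: float
    seeded: int

    def __post_init__(self) -> None:
        if not 0 < self.plating_efficiency <= 1:
            raise ValueError("plating efficiency must be in (0, 1]")
        if self.seeded <= 0:
            raise ValueError("seeded count must be positive")


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground-truth parameters of the synthetic study.

    Defaults mirror the study conditions: a target-positive line (1000
    cells seeded for clonogenics) and a target-negative line (250 cells),
    clonogenic activities 0-2 MBq, spheroid/viability activities down to
    0.01 MBq, growth read on days 0/7/14/20 and viability on days 7/15/21,
    three replicates and three independent experiments. LQ parameters
    alpha = 0.2 /Gy, beta = 0.05 /Gy^2 are typical low-dose-rate values
    for radiosensitive prostate lines; D50 = 0.005 Gy puts every treated
    spheroid dose deep into the inhibition plateau, so treated growth
    curves collapse together while remaining clearly below control.
    """

    target_pos: CellLineProfile = CellLineProfile("LNCaP", True, 0.20, 1000)
    target_neg: CellLineProfile = CellLineProfile("PC-3", False, 0.40, 250)
    alpha_per_gy: float = 0.2
    beta_per_gy2: float = 0.05
    activities_clonogenic_mbq: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    activities_spheroid_mbq: tuple[float, ...] = (0.0, 0.01, 0.05, 0.2, 0.4)
    activities_viability_mbq: tuple[float, ...] = (0.0, 0.2)
    spheroid_days: tuple[float, ...] = (0.0, 7.0, 14.0, 20.0)
    viability_days: tuple[float, ...] = (7.0, 15.0, 21.0)
    replicates: int = 3
    experiments: int = 3
    d0_um: float = 400.0
    growth_rate_per_day: float = 0.04
    d50_gy: float = 0.005
    diameter_cv: float = 0.03
    viability_cv: float = 0.10
    viability_compound_per_day: float = 0.05
    proliferation_per_day: float = 0.10
    lum_scale: dict = field(default_factory=lambda: {"2D": 1.0e6, "3D": 2.0e5})

    def __post_init__(self) -> None:
        if self.alpha_per_gy < 0 or self.beta_per_gy2 < 0:
            raise ValueError("LQ parameters must be non-negative")
        if self.diameter_cv < 0 or self.viability_cv < 0:
            raise ValueError("noise CVs must be non-negative")

    @property
    def lines(self) -> tuple[CellLineProfile, CellLineProfile]:
        return (self.target_pos, self.target_neg)


def lq_survival(alpha: float, beta: float, dose_gy: float) -> float:
    """exp(-alpha D - beta D^2)."""
    return math.exp(-alpha * dose_gy - beta * dose_gy * dose_gy)


def growth_inhibition(dose_gy: float, d50_gy: float) -> float:
    """Saturating inhibition I(D) = D / (D + D50), in [0, 1)."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    if dose_gy == 0:
        return 0.0
    return dose_gy / (dose_gy + d50_gy)


def _dose(
    conv: ConversionTable, activity: float, geometry: str, targeted: bool
) -> float:
    if activity == 0 or not targeted:
        return 0.0
    return conv.dose(activity, geometry)


def _check_coverage(conv: ConversionTable, activities: Sequence[float]) -> None:
    have = conv.table["activity_mbq"].unique()
    for a in activities:
        if a > 0 and not np.any(np.isclose(have, a)):
            raise ValueError(f"activity {a} MBq missing from the conversion table")


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def designed_fold(
    design: SyntheticDesign, conv: ConversionTable, activity_mbq: float, day: float
) -> float:
    """Ground-truth control-normalised 2D/3D viability fold at (activity, day)."""
    s2 = lq_survival(
        design.alpha_per_gy, design.beta_per_gy2, _dose(conv, activity_mbq, "2d", True)
    )
    s3 = lq_survival(
        design.alpha_per_gy, design.beta_per_gy2, _dose(conv, activity_mbq, "3d", True)
    )
    power = 1.0 + design.viability_compound_per_day * day
    return (s2 / s3) ** power


def synth_clonogenic(
    design: SyntheticDesign, conv: ConversionTable, rng: np.random.Generator
) -> pd.DataFrame:
    """Colony counts: Poisson(seeded x PE x LQ survival at the 2D dose)."""
    _check_coverage(conv, design.activities_clonogenic_mbq)
    rows = []
    for prof in design.lines:
        for act in design.activities_clonogenic_mbq:
            d = _dose(conv, act, "2d", prof.targeted)
            mean = prof.seeded * prof.plating_efficiency * lq_survival(
                design.alpha_per_gy, design.beta_per_gy2, d
            )
            counts = rng.poisson(mean, design.replicates)
            for rep, c in enumerate(counts, start=1):
                rows.append(
                    {
                        "line": prof.name,
                        "activity_mbq": act,
                        "seeded": prof.seeded,
                        "colonies": int(c),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def synth_spheroids(
    design: SyntheticDesign, conv: ConversionTable, rng: np.random.Generator
) -> pd.DataFrame:
    """Spheroid diameter trajectories with treatment-dependent inhibition."""
    _check_coverage(conv, design.activities_spheroid_mbq)
    rows = []
    for prof in design.lines:
        for act in design.activities_spheroid_mbq:
            d = _dose(conv, act, "3d", prof.targeted)
            rate = design.growth_rate_per_day * (
                1.0 - growth_inhibition(d, design.d50_gy)
            )
            for exp_i in range(1, design.experiments + 1):
                for day in design.spheroid_days:
                    true_d = design.d0_um * math.exp(rate * day)
                    meas = true_d * _lognormal(rng, design.diameter_cv, 3)
                    rows.append(
                        {
                            "line": prof.name,
                            "activity_mbq": act,
                            "day": day,
                            "d1_um": meas[0],
                            "d2_um": meas[1],
                            "d3_um": meas[2],
                            "experiment": exp_i,
                        }
                    )
    return pd.DataFrame(rows)


def synth_viability(
    design: SyntheticDesign, conv: ConversionTable, rng: np.random.Generator
) -> pd.DataFrame:
    """Luminescence viability signals for the 2D and 3D arms.

    Signal = scale x common proliferation factor x LQ survival compounded
    over elapsed days x lognormal noise. The compounding exponent
    (1 + c day) makes the 2D/3D fold increase with observation day.
    """
    _check_coverage(conv, design.activities_viability_mbq)
    rows = []
    for prof in design.lines:
        for model, geom in (("2D", "2d"), ("3D", "3d")):
            for act in design.activities_viability_mbq:
                d = _dose(conv, act, geom, prof.targeted)
                s = lq_survival(design.alpha_per_gy, design.beta_per_gy2, d)
                for day in design.viability_days:
                    mean = (
                        design.lum_scale[model]
                        * math.exp(design.proliferation_per_day * day)
                        * s ** (1.0 + design.viability_compound_per_day * day)
                    )
                    noise = _lognormal(rng, design.viability_cv, design.replicates)
                    for rep in range(1, design.replicates + 1):
                        rows.append(
                            {
                                "model": model,
                                "line": prof.name,
                                "activity_mbq": act,
                                "day": day,
                                "lum": mean * noise[rep - 1],
                                "replicate": rep,
                            }
                        )
    return pd.DataFrame(rows)
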