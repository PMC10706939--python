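"""From tallies to absorbed dose: region doses, activity->dose conversion
tables, depth profiles and the closed-form equilibrium bound.

A tally holds energy per simulated history (one history = one emitted
electron). Absorbed dose scales it to the treatment:

    D = (E_scoring / N_histories) * N_decays * yield / m_scoring

with the no-emission fraction of decays handled by ``yield`` (electrons per
decay) and keV converted to joules. Linearity in activity is exact, so a
conversion table reuses one per-history tally per geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ScoringRegion, VoxelGrid, voxel_mass
from .source import (
    SourceSpec,
    decay_count,
    lu177_emission_lines,
    mean_emitted_energy,
    total_yield,
)
from .transport import DoseTally

__all__ = [
    "KEV_TO_J",
    "RegionDose",
    "ConversionTable",
    "region_dose",
    "equilibrium_dose",
    "conversion_table",
    "depth_profile",
]

KEV_TO_J = 1.602176634e-16
WATER_DENSITY_KG_PER_MM3 = 1e-6


@dataclass(frozen=True)
class RegionDose:
    """Mean absorbed dose over a scoring region, with its MC uncertainty."""

    dose_gy: float
    rel_se: float
    histories: int
    decays: float
    geometry: str = ""

    def __post_init__(self) -> None:
        if self.dose_gy < 0 or self.rel_se < 0:
            raise ValueError("dose and relative SE must be non-negative")

    def rescaled(self, factor: float) -> "RegionDose":
        """Same tally, different decay count (linearity is exact)."""
        return RegionDose(
            self.dose_gy * factor,
            self.rel_se,
            self.histories,
            self.decays * factor,
            self.geometry,
        )


def region_dose(
    tally: DoseTally,
    scoring: ScoringRegion,
    source: SourceSpec,
    emission_yield: float | None = None,
    geometry: str = "",
) -> RegionDose:
    """Absorbed dose (Gy) averaged over the scoring region.

    ``emission_yield`` is electrons per decay (default: the Lu-177
    three-line total, 0.999).
    """
    if tally.histories < 1:
        raise ValueError("empty tally")
    if scoring.mass_kg <= 0:
        raise ValueError("scoring region has no mass")
    y = emission_yield if emission_yield is not None else total_yield(lu177_emission_lines())
    decays = decay_count(source)
    e_per_hist = tally.scoring_energy_kev / tally.histories
    dose = e_per_hist * decays * y * KEV_TO_J / scoring.mass_kg
    return RegionDose(dose, tally.relative_se(), tally.histories, decays, geometry)


def equilibrium_dose(
    source: SourceSpec,
    medium_volume_ul: float,
    lines: Sequence | None = None,
) -> float:
    """Dose (Gy) if every emitted keV were absorbed in the medium.

    Closed form: N_decays x mean emitted energy per decay / medium mass.
    Upper bound for any finite geometry (strict whenever escape is
    possible).
    """
    if medium_volume_ul <= 0:
        raise ValueError("medium volume must be positive")
    lines = list(lines) if lines is not None else lu177_emission_lines()
    mass_kg = medium_volume_ul * WATER_DENSITY_KG_PER_MM3  # 1 uL == 1 mm^3 of water
    return decay_count(source) * mean_emitted_energy(lines) * KEV_TO_J / mass_kg


@dataclass(frozen=True)
class ConversionTable:
    """Applied activity -> absorbed dose, per geometry.

    Rows: (activity_mbq, duration_h, geometry, dose_gy, rel_se). Doses are
    linear in activity at fixed duration (single well, no saturation).
    """

    table: pd.DataFrame

    COLUMNS = ("activity_mbq", "duration_h", "geometry", "dose_gy", "rel_se")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"conversion table missing columns: {sorted(missing)}")
        if (self.table["activity_mbq"] < 0).any():
            raise ValueError("negative activity")

    def dose(self, activity_mbq: float, geometry: str) -> float:
        """Dose in Gy at the given activity (exact linear rescale)."""
        sub = self.table[self.table["geometry"] == geometry]
        if sub.empty:
            raise KeyError(f"geometry {geometry!r} not in table")
        ref = sub[sub["activity_mbq"] > 0]
        if ref.empty:
            raise KeyError(f"no nonzero-activity anchor for {geometry!r}")
        row = ref.iloc[0]
        return float(row["dose_gy"] / row["activity_mbq"] * activity_mbq)

    @classmethod
    def from_dose_rates(
        cls,
        per_mbq: dict[str, float],
        activities_mbq: Sequence[float],
        duration_h: float = 3.0,
        rel_se: dict[str, float] | None = None,
    ) -> "ConversionTable":
        """Build from Gy-per-MBq factors (e.g. synthetic-design inputs)."""
        rel_se = rel_se or {}
        rows = [
            {
                "activity_mbq": a,
                "duration_h": duration_h,
                "geometry": g,
                "dose_gy": a * d,
                "rel_se": rel_se.get(g, 0.0),
            }
            for a in activities_mbq
            for g, d in per_mbq.items()
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))


def conversion_table(
    activities_mbq: Sequence[float],
    reference_doses: dict[str, RegionDose],
    reference_activity_mbq: float = 1.0,
    duration_h: float = 3.0,
) -> ConversionTable:
    """Tabulate doses for each activity from one simulated anchor per geometry.

    ``reference_doses`` maps geometry labels ("2d"/"3d") to the region dose
    simulated at ``reference_activity_mbq``; every other activity is an
    exact linear rescale of the same tally.
    """
    if len(activities_mbq) == 0:
        raise ValueError("need at least one activity")
    if any(a < 0 for a in activities_mbq):
        raise ValueError("negative activity")
    per_mbq = {g: rd.dose_gy / reference_activity_mbq for g, rd in reference_doses.items()}
    rel = {g: rd.rel_se for g, rd in reference_doses.items()}
    return ConversionTable.from_dose_rates(per_mbq, list(activities_mbq), duration_h, rel)


def depth_profile(
    tally: DoseTally,
    grid: VoxelGrid,
    axis: str = "z",
    source: SourceSpec | None = None,
    emission_yield: float | None = None,
) -> pd.DataFrame:
    """Mean dose (or energy) binned along one grid axis.

    Returns columns ``depth_mm`` (bin centre along the axis),
    ``energy_kev`` (summed tally energy per slab) and, when ``source`` is
    given, ``dose_gy`` (slab energy scaled to the treatment and divided by
    the slab mass). The slabs partition the grid, so the energy column sums
    back to the in-grid total exactly.
    """
    if tally.voxel_energy_kev is None or tally.histories < 1:
        raise ValueError("tally has no voxel data")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    other = tuple(i for i in range(3) if i != ax)
    energy = tally.voxel_energy_kev.sum(axis=other)
    centers = (
        grid.origin_mm[ax] + (np.arange(grid.shape[ax]) + 0.5) * grid.spacing_mm[ax]
    )
    out = pd.DataFrame({"depth_mm": centers, "energy_kev": energy})
    if source is not None:
        y = (
            emission_yield
            if emission_yield is not None
            else total_yield(lu177_emission_lines())
        )
        slab_voxels = grid.n_voxels / grid.shape[ax]
        slab_mass = voxel_mass(grid) * slab_voxels
        scale = decay_count(source) * y * KEV_TO_J / (tally.histories * slab_mass)
        out["dose_gy"] = out["energy_kev"] * scale
    return out
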