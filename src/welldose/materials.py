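"""Materials and electron stopping-power data for condensed-history transport.

The medium is liquid water; vessel walls are polystyrene, treated as
density-scaled water (the two are close in composition; walls matter only
through backscatter). Collision stopping powers are reference values for
liquid water embedded as interpolation nodes; the radiative component is an
approximate smooth table — it is removed from the electron but never
deposited, so its accuracy affects results at the sub-percent level.

Units: energies keV, lengths mm, mass stopping power MeV cm^2/g,
linear stopping power keV/mm, densities g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "Material",
    "WATER",
    "POLYSTYRENE",
    "StoppingPowerTable",
    "water_table",
    "stopping_power",
    "csda_range",
    "energy_from_range",
]


@dataclass(frozen=True)
class Material:
    """A transport medium.

    ``stopping_scale`` multiplies the *linear* stopping power of water:
    it folds together density and the (mild) mass-stopping-power ratio
    relative to water.
    """

    name: str
    density: float  # g/cm^3
    mean_excitation_energy: float  # eV
    stopping_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean excitation energy must be positive")


WATER = Material("water", density=1.0, mean_excitation_energy=78.0)
# Polystyrene: density 1.05, mass collision stopping power ~3% below water.
POLYSTYRENE = Material(
    "polystyrene", density=1.05, mean_excitation_energy=68.7, stopping_scale=1.05 * 0.97
)

# Reference nodes, liquid water: kinetic energy [keV], collision and
# radiative mass stopping power [MeV cm^2/g].
_E_NODES_KEV = np.array(
    [1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0,
     100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 600.0, 800.0, 1000.0,
     1250.0, 1500.0, 2000.0, 2500.0]
)
_S_COL_NODES = np.array(
    [126.3, 77.45, 42.61, 22.56, 16.47, 13.17, 9.653, 7.780, 6.603,
     5.797, 4.757, 4.115, 3.242, 2.795, 2.355, 2.148, 2.034, 1.965,
     1.886, 1.849, 1.829, 1.822, 1.824, 1.834]
)
_S_RAD_NODES = np.array(
    [0.0033, 0.0035, 0.0037, 0.0039, 0.0040, 0.0042, 0.0044, 0.0047,
     0.0049, 0.0052, 0.0056, 0.0061, 0.0073, 0.0087, 0.0112, 0.0137,
     0.0162, 0.0188, 0.0243, 0.0297, 0.0367, 0.0438, 0.0583, 0.0730]
)

# keV/mm = (MeV cm^2/g) * (g/cm^3) * 100, at unit density
_MASS_TO_LINEAR = 100.0


class StoppingPowerTable:
    """Log-log interpolated electron stopping powers and CSDA ranges.

    Built for unit-density water; other materials scale the linear
    stopping power through :attr:`Material.stopping_scale`. The table
    covers 1--2500 keV and reproduces its nodes exactly (log-log
    interpolation passes through the data).
    """

    def __init__(
        self,
        energy_kev: np.ndarray = _E_NODES_KEV,
        s_col: np.ndarray = _S_COL_NODES,
        s_rad: np.ndarray = _S_RAD_NODES,
    ) -> None:
        if np.any(energy_kev <= 0) or np.any(s_col <= 0) or np.any(s_rad <= 0):
            raise ValueError("table entries must be strictly positive")
        self.energy_kev = np.asarray(energy_kev, dtype=float)
        self.s_col = np.asarray(s_col, dtype=float)  # MeV cm^2/g
        self.s_rad = np.asarray(s_rad, dtype=float)
        self._log_e = np.log(self.energy_kev)
        self._log_col = np.log(self.s_col)
        self._log_rad = np.log(self.s_rad)
        # Dense grid for the range integral and fast runtime lookups.
        self._dense_log_e = np.linspace(self._log_e[0], self._log_e[-1], 800)
        dense_e = np.exp(self._dense_log_e)
        self._dense_col = (
            np.exp(np.interp(self._dense_log_e, self._log_e, self._log_col))
            * _MASS_TO_LINEAR
        )  # keV/mm
        self._dense_rad = (
            np.exp(np.interp(self._dense_log_e, self._log_e, self._log_rad))
            * _MASS_TO_LINEAR
        )
        total = self._dense_col + self._dense_rad
        # CSDA range measured from the 1 keV table floor; the missing
        # sub-keV tail is < 5e-5 mm in water.
        self._dense_range = np.concatenate(
            [[0.0], cumulative_trapezoid(1.0 / total, dense_e)]
        )

    @property
    def e_min(self) -> float:
        return float(self.energy_kev[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_kev[-1])

    def _check(self, energy_kev: np.ndarray) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise ValueError(
                f"energy outside table range [{self.e_min}, {self.e_max}] keV"
            )
        return e

    def collision(self, energy_kev, material: Material = WATER):
        """Linear collision stopping power, keV/mm (exact at the nodes)."""
        e = self._check(energy_kev)
        s = np.exp(np.interp(np.log(e), self._log_e, self._log_col)) * _MASS_TO_LINEAR
        return s * material.stopping_scale

    def radiative(self, energy_kev, material: Material = WATER):
        """Linear radiative stopping power, keV/mm (exact at the nodes)."""
        e = self._check(energy_kev)
        s = np.exp(np.interp(np.log(e), self._log_e, self._log_rad)) * _MASS_TO_LINEAR
        return s * material.stopping_scale

    def total(self, energy_kev, material: Material = WATER):
        e = self._check(energy_kev)
        le = np.log(e)
        s = (
            np.exp(np.interp(le, self._log_e, self._log_col))
            + np.exp(np.interp(le, self._log_e, self._log_rad))
        ) * _MASS_TO_LINEAR
        return s * material.stopping_scale

    def csda_range(self, energy_kev, material: Material = WATER):
        """CSDA range in mm (path-length integral of 1/total stopping power)."""
        e = self._check(energy_kev)
        r = np.interp(np.log(e), self._dense_log_e, self._dense_range)
        return r / material.stopping_scale

    def energy_from_range(self, range_mm, material: Material = WATER):
        """Inverse of :meth:`csda_range` (water-referenced lookup)."""
        r = np.asarray(range_mm, dtype=float) * material.stopping_scale
        le = np.interp(r, self._dense_range, self._dense_log_e)
        return np.exp(le)


_WATER_TABLE: StoppingPowerTable | None = None


def water_table() -> StoppingPowerTable:
    """The shared water stopping-power table."""
    global _WATER_TABLE
    if _WATER_TABLE is None:
        _WATER_TABLE = StoppingPowerTable()
    return _WATER_TABLE


def stopping_power(
    energy_kev, material: Material = WATER, component: str = "collision"
):
    """Linear stopping power in keV/mm at ``energy_kev``.

    ``component`` is one of ``"collision"``, ``"radiative"``, ``"total"``.
    """
    tab = water_table()
    if component == "collision":
        return tab.collision(energy_kev, material)
    if component == "radiative":
        return tab.radiative(energy_kev, material)
    if component == "total":
        return tab.total(energy_kev, material)
    raise ValueError(f"unknown component {component!r}")


def csda_range(energy_kev, material: Material = WATER):
    """CSDA range in mm for an electron of the given kinetic energy."""
    return water_table().csda_range(energy_kev, material)


def energy_from_range(range_mm, material: Material = WATER):
    return water_table().energy_from_range(range_mm, material)
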