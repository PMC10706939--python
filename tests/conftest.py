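"""Shared fixtures: seeded RNGs and session-cached small Monte Carlo runs.

The transport runs here are deliberately modest (1e5-scale histories):
large enough for the statistical assertions they feed, small enough to
keep the whole suite fast. Reproduction-quality runs live in
scripts/acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from welldose import geometry as geo
from welldose.pipeline import make_source, simulate_dose
from welldose.transport import TransportSettings, run


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def source_1mbq_3h():
    return make_source(activity_mbq=1.0, duration_h=3.0)


@pytest.fixture(scope="session")
def dose_3d(source_1mbq_3h):
    """(well, scoring, grid, tally, RegionDose) for the U-bottom well."""
    rng = np.random.default_rng(101)
    settings = TransportSettings(n_histories=120_000)
    return simulate_dose("3d", source_1mbq_3h, settings, rng)


@pytest.fixture(scope="session")
def dose_2d(source_1mbq_3h):
    """(well, scoring, grid, tally, RegionDose) for the flat-bottom well."""
    rng = np.random.default_rng(102)
    settings = TransportSettings(n_histories=120_000)
    return simulate_dose("2d", source_1mbq_3h, settings, rng)


@pytest.fixture(scope="session")
def bath_tally():
    """Uniform-source water ball, source restricted to a 2.6 mm core around
    the central scoring sphere (electrons born farther cannot reach it)."""
    well, scoring, grid = geo.build_bath()
    settings = TransportSettings(
        n_histories=300_000, source_radius_mm=2.6, source_center_mm=(0.0, 0.0, 0.0)
    )
    rng = np.random.default_rng(103)
    tally = run(well, scoring, None, settings, rng)
    return well, scoring, tally, 2.6
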