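"""High-level drivers tying geometry, source, transport and scoring together.

These are the entry points the CLI, the analysis scripts and the
reproduction script all share.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import geometry as geo
from . import transport as tp
from .scoring import RegionDose, equilibrium_dose, region_dose
from .source import SourceSpec, lu177_emission_lines, total_yield

__all__ = ["build_geometry", "make_source", "simulate_dose"]

_BUILDERS = {"2d": geo.build_2d_well, "3d": geo.build_3d_well, "bath": geo.build_bath}


def build_geometry(kind: str, overrides: dict | None = None):
    """(well, scoring, grid) for a geometry kind: '2d', '3d' or 'bath'."""
    try:
        builder = _BUILDERS[kind.lower()]
    except KeyError:
        raise ValueError(f"unknown geometry kind {kind!r}") from None
    cfg = dict(overrides or {})
    cfg.pop("kind", None)
    return builder(cfg)


def make_source(
    activity_mbq: float = 1.0,
    duration_h: float = 3.0,
    decay_correction: bool = False,
    half_life_d: float | None = None,
) -> SourceSpec:
    kwargs = {}
    if half_life_d is not None:
        kwargs["half_life_s"] = half_life_d * 86400.0
    return SourceSpec(
        activity_mbq * 1e6, duration_h * 3600.0, decay_correction=decay_correction, **kwargs
    )


def simulate_dose(
    kind: str,
    source: SourceSpec,
    settings: tp.TransportSettings,
    rng: np.random.Generator,
    geometry_overrides: dict | None = None,
    target_rel_se: float | None = None,
    with_grid: bool = True,
):
    """Simulate one well and score it.

    Returns (well, scoring, grid, tally, RegionDose). With
    ``target_rel_se`` set, the history count doubles adaptively until the
    scoring-region relative SE beats the target.
    """
    well, scoring, grid = build_geometry(kind, geometry_overrides)
    lines = lu177_emission_lines()
    g = grid if with_grid else None
    if target_rel_se is not None:
        tally = tp.run_adaptive(
            well, scoring, g, settings, rng, lines, target_rel_se=target_rel_se
        )
    else:
        tally = tp.run(well, scoring, g, settings, rng, lines)
    rd = region_dose(tally, scoring, source, total_yield(lines), geometry=kind)
    return well, scoring, grid, tally, rd
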