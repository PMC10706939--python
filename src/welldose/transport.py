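"""Condensed-history electron transport in the well geometries.

Electrons lose energy continuously at the collision stopping-power rate
(CSDA); the radiative component is removed from the particle but discarded
(no photon transport, no delta rays). Direction is perturbed each step by a
Gaussian multiple-scattering angle (Highland's formula). Steps are capped at
the voxel size (0.01 mm) inside an inflated envelope of the scoring region
and at 0.1 mm elsewhere, and by a maximum fractional energy loss per step.
A particle is killed — depositing its residual energy locally — when its
residual CSDA range falls below the range cut (0.01 mm), and discarded when
it leaves the medium into vacuum. Polystyrene walls continue transport with
density-scaled stopping power; wall deposits are tallied outside the dose
grid but inside the energy balance.

The engine transports *emitted electrons*: one history is one electron, and
no-emission decays are accounted for analytically when converting tallies
to dose (see :mod:`welldose.scoring`).

All lengths mm, energies keV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import geometry as geo
from .materials import POLYSTYRENE, WATER, StoppingPowerTable, water_table
from .source import EmissionLine, lu177_emission_lines, sample_directions, sample_energies

__all__ = [
    "TransportSettings",
    "ParticleState",
    "DoseTally",
    "step",
    "run",
    "run_adaptive",
]

_X0_WATER_MM = 360.8  # radiation length of water at unit density
_ELECTRON_MASS_KEV = 510.99895


@dataclass
class TransportSettings:
    """Knobs of the condensed-history engine.

    ``fine_step_mm`` applies inside the scoring envelope (scoring bounding
    box inflated by one coarse step), matching the 0.01 mm maximum step of
    the reference simulation; ``range_cut_mm`` is the residual-range kill
    threshold. ``range_rejection`` kills electrons that can no longer reach
    the scoring region, depositing their energy on the spot — exact for
    scoring-region dose and for the energy balance, wrong for the remote
    voxel map (switch it off for depth profiles).
    """

    n_histories: int = 200_000
    batches: int = 20
    max_step_mm: float = 0.1
    fine_step_mm: float = 0.01
    range_cut_mm: float = 0.01
    max_eloss_fraction: float = 0.05
    range_rejection: bool = True
    rejection_margin_mm: float = 0.05
    block_size: int = 250_000
    source_center_mm: tuple[float, float, float] | None = None
    source_radius_mm: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "max_step_mm",
            "fine_step_mm",
            "range_cut_mm",
            "max_eloss_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.batches < 2:
            raise ValueError("need at least two batches for the variance estimate")


@dataclass
class ParticleState:
    """A transported electron."""

    position: np.ndarray
    direction: np.ndarray
    energy_kev: float
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy_kev < 0 or not np.all(np.isfinite(self.position)):
            raise ValueError("invalid particle state")


@dataclass
class DoseTally:
    """Accumulated energy deposition statistics.

    ``region_energy_kev`` keys: scoring, medium (outside the scoring
    region), wall, escaped (left into vacuum), radiative (bremsstrahlung
    losses, discarded). ``batch_scoring_kev`` holds per-batch
    (scoring energy, histories) pairs for the variance estimate.
    """

    voxel_energy_kev: np.ndarray | None
    region_energy_kev: dict[str, float]
    batch_scoring_kev: list[tuple[float, int]]
    histories: int
    initial_energy_kev: float
    meta: dict = field(default_factory=dict)

    @property
    def scoring_energy_kev(self) -> float:
        return self.region_energy_kev["scoring"]

    @property
    def deposited_energy_kev(self) -> float:
        r = self.region_energy_kev
        return r["scoring"] + r["medium"] + r["wall"]

    def energy_balance_error(self) -> float:
        """Relative closure error of the energy balance (should be ~1e-12)."""
        r = self.region_energy_kev
        total = self.deposited_energy_kev + r["escaped"] + r["radiative"]
        return abs(total - self.initial_energy_kev) / max(self.initial_energy_kev, 1e-300)

    def relative_se(self) -> float:
        """Relative standard error of the mean scoring energy per history.

        Weighted batch-means estimator: with batch means e_i over n_i
        histories, s^2 = sum n_i (e_i - mean)^2 / (B - 1) estimates the
        per-history variance, and SE(mean) = sqrt(s^2 / sum n_i).
        """
        batches = [(e, n) for e, n in self.batch_scoring_kev if n > 0]
        if len(batches) < 2:
            return math.inf
        e = np.array([b[0] for b in batches])
        n = np.array([b[1] for b in batches], dtype=float)
        mean = e.sum() / n.sum()
        if mean == 0:
            return math.inf
        s2 = float(np.sum(n * (e / n - mean) ** 2) / (len(batches) - 1))
        return math.sqrt(s2 / n.sum()) / mean

    def merge(self, other: "DoseTally") -> "DoseTally":
        if (self.voxel_energy_kev is None) != (other.voxel_energy_kev is None):
            raise ValueError("cannot merge tallies with and without voxel grids")
        vox = None
        if self.voxel_energy_kev is not None:
            vox = self.voxel_energy_kev + other.voxel_energy_kev
        sums = {
            k: self.region_energy_kev[k] + other.region_energy_kev[k]
            for k in self.region_energy_kev
        }
        return DoseTally(
            vox,
            sums,
            self.batch_scoring_kev + other.batch_scoring_kev,
            self.histories + other.histories,
            self.initial_energy_kev + other.initial_energy_kev,
            dict(self.meta),
        )


class _Context:
    """Precomputed geometry/physics lookups shared by all steps."""

    def __init__(
        self,
        well: geo.WellModel,
        scoring: geo.ScoringRegion,
        grid: geo.VoxelGrid | None,
        settings: TransportSettings,
        table: StoppingPowerTable,
    ) -> None:
        self.well = well
        self.scoring = scoring
        self.grid = grid
        self.table = table
        self.sc_center, self.sc_radius = scoring.bounding_sphere()
        lo, hi = scoring.bbox()
        pad = settings.max_step_mm * 1.2
        self.fine_lo = lo - pad
        self.fine_hi = hi + pad
        # kill threshold: energy whose residual CSDA range equals the cut
        self.e_kill = float(table.energy_from_range(settings.range_cut_mm))
        self.e_floor = table.e_min
        self.wall_scale = POLYSTYRENE.stopping_scale
        if grid is not None and not grid.covers(scoring):
            raise ValueError("voxel grid does not cover the scoring region")


class _Accumulator:
    def __init__(self, n_voxels: int | None) -> None:
        self.voxel = np.zeros(n_voxels) if n_voxels is not None else None
        self.sums = {k: 0.0 for k in ("scoring", "medium", "wall", "escaped", "radiative")}
        self.initial = 0.0

    def deposit_by_label(
        self, labels: np.ndarray, pts: np.ndarray, de: np.ndarray, ctx: _Context
    ) -> None:
        """Attribute deposits ``de`` at points ``pts`` with region ``labels``."""
        for code, key in (
            (geo.SCORING, "scoring"),
            (geo.MEDIUM, "medium"),
            (geo.WALL, "wall"),
            (geo.OUTSIDE, "escaped"),
        ):
            m = labels == code
            if np.any(m):
                self.sums[key] += float(de[m].sum())
        if self.voxel is not None:
            in_med = (labels == geo.MEDIUM) | (labels == geo.SCORING)
            if np.any(in_med):
                p = pts[in_med]
                ing = ctx.grid.contains(p)
                if np.any(ing):
                    np.add.at(
                        self.voxel, ctx.grid.flat_index(p[ing]), de[in_med][ing]
                    )


def _advance(
    pos: np.ndarray,
    dirs: np.ndarray,
    e: np.ndarray,
    ctx: _Context,
    settings: TransportSettings,
    rng: np.random.Generator,
    acc: _Accumulator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One synchronized condensed-history step for every particle.

    Returns the surviving (pos, dirs, e) arrays (dead particles removed).
    """
    if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(e)):
        raise ValueError("NaN/Inf in particle state")
    labels = geo.locate(pos, ctx.well, ctx.scoring)

    # electrons in vacuum: discard remaining energy
    out = labels == geo.OUTSIDE
    if np.any(out):
        acc.sums["escaped"] += float(e[out].sum())

    # residual range below the cut: local deposit
    low = ~out & (e <= ctx.e_kill)
    if np.any(low):
        acc.deposit_by_label(labels[low], pos[low], e[low], ctx)

    live = ~(out | low)

    # range rejection: too far from the scoring region to ever reach it
    if settings.range_rejection and np.any(live):
        d = np.linalg.norm(pos[live] - ctx.sc_center, axis=1) - ctx.sc_radius
        resid = ctx.table.csda_range(e[live])
        rej = d > resid + settings.rejection_margin_mm
        if np.any(rej):
            idx = np.flatnonzero(live)[rej]
            acc.deposit_by_label(labels[idx], pos[idx], e[idx], ctx)
            live[idx] = False

    if not np.any(live):
        return pos[:0], dirs[:0], e[:0]

    pos, dirs, e, labels = pos[live], dirs[live], e[live], labels[live]
    in_wall = labels == geo.WALL
    scale = np.where(in_wall, ctx.wall_scale, 1.0)
    s_col = ctx.table.collision(e) * scale
    s_rad = ctx.table.radiative(e) * scale
    s_tot = s_col + s_rad

    fine = np.all((pos >= ctx.fine_lo) & (pos <= ctx.fine_hi), axis=1)
    ds = np.where(fine, settings.fine_step_mm, settings.max_step_mm)
    ds = np.minimum(ds, settings.max_eloss_fraction * e / s_tot)

    de_col = s_col * ds
    de_rad = s_rad * ds
    acc.sums["radiative"] += float(de_rad.sum())

    mid = pos + dirs * (0.5 * ds)[:, None]
    mlabels = geo.locate(mid, ctx.well, ctx.scoring)
    acc.deposit_by_label(mlabels, mid, de_col, ctx)

    pos = pos + dirs * ds[:, None]
    e = e - de_col - de_rad

    # Highland multiple-scattering deflection over the step
    x0 = np.where(in_wall, _X0_WATER_MM / POLYSTYRENE.density, _X0_WATER_MM)
    ekin = np.maximum(e, ctx.e_floor)
    beta_pc = ekin * (ekin + 2 * _ELECTRON_MASS_KEV) / (ekin + _ELECTRON_MASS_KEV)
    t = ds / x0
    # Highland's log term uses the particle's characteristic total path
    # (its residual CSDA range), not the sub-step length: applying the log
    # per step is known to underestimate the accumulated deflection.
    t_total = np.maximum(ctx.table.csda_range(ekin) / x0, t)
    theta0 = (
        13600.0 / beta_pc * np.sqrt(t) * np.maximum(1.0 + 0.038 * np.log(t_total), 0.1)
    )
    tx = rng.normal(size=len(e)) * theta0
    ty = rng.normal(size=len(e)) * theta0
    theta = np.hypot(tx, ty)
    # orthonormal frame around the current direction
    a = np.zeros_like(dirs)
    small_x = np.abs(dirs[:, 0]) < 0.9
    a[small_x, 0] = 1.0
    a[~small_x, 1] = 1.0
    e1 = np.cross(dirs, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    st = np.sinc(theta / np.pi)  # sin(theta)/theta, safe at 0
    dirs = (
        dirs * np.cos(theta)[:, None]
        + e1 * (st * tx)[:, None]
        + e2 * (st * ty)[:, None]
    )
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return pos, dirs, e


def step(
    particle: ParticleState,
    grid: geo.VoxelGrid | None,
    well: geo.WellModel,
    scoring: geo.ScoringRegion,
    settings: TransportSettings,
    rng: np.random.Generator,
) -> tuple[ParticleState, dict[str, float]]:
    """Advance a single electron by one condensed-history step.

    Returns the updated particle and the energy deposited this step by
    destination (scoring/medium/wall/escaped/radiative). Thin wrapper over
    the vectorized kernel; :func:`run` is the production path.
    """
    if not particle.alive:
        raise ValueError("particle is not alive")
    ctx = _Context(well, scoring, grid, settings, water_table())
    acc = _Accumulator(grid.n_voxels if grid is not None else None)
    pos, dirs, e = _advance(
        particle.position[None, :].copy(),
        particle.direction[None, :].copy(),
        np.array([particle.energy_kev], dtype=float),
        ctx,
        settings,
        rng,
        acc,
    )
    if len(e):
        new = ParticleState(pos[0], dirs[0], float(e[0]))
    else:
        new = ParticleState(particle.position, particle.direction, 0.0, alive=False)
    return new, dict(acc.sums)


def _run_batch(
    n: int,
    ctx: _Context,
    settings: TransportSettings,
    rng: np.random.Generator,
    lines: Sequence[EmissionLine],
    acc: _Accumulator,
) -> None:
    within = None
    if settings.source_radius_mm is not None:
        center = settings.source_center_mm or (0.0, 0.0, 0.0)
        within = (np.asarray(center, dtype=float), settings.source_radius_mm)
    done = 0
    while done < n:
        m = min(settings.block_size, n - done)
        pos = ctx.well.sample_positions(m, rng, within=within)
        dirs = sample_directions(m, rng)
        e = sample_energies(lines, m, rng, conditional=True).astype(float)
        acc.initial += float(e.sum())
        it = 0
        while len(e):
            pos, dirs, e = _advance(pos, dirs, e, ctx, settings, rng, acc)
            it += 1
            if it > 100_000:  # pragma: no cover - safety net
                raise RuntimeError("transport failed to terminate")
        done += m


def run(
    well: geo.WellModel,
    scoring: geo.ScoringRegion,
    grid: geo.VoxelGrid | None,
    settings: TransportSettings,
    rng: np.random.Generator,
    lines: Sequence[EmissionLine] | None = None,
) -> DoseTally:
    """Simulate ``settings.n_histories`` emitted electrons.

    Histories are split into ``settings.batches`` batches whose
    scoring-region energies feed the batch variance estimate. Deterministic
    for a given generator state.
    """
    if settings.n_histories <= 0:
        raise ValueError("need at least one history")
    if settings.n_histories < settings.batches:
        raise ValueError("histories must be >= batch count")
    lines = list(lines) if lines is not None else lu177_emission_lines()
    ctx = _Context(well, scoring, grid, settings, water_table())
    acc = _Accumulator(grid.n_voxels if grid is not None else None)
    per = np.full(settings.batches, settings.n_histories // settings.batches)
    per[: settings.n_histories % settings.batches] += 1
    batch_records: list[tuple[float, int]] = []
    for nb in per:
        before = acc.sums["scoring"]
        _run_batch(int(nb), ctx, settings, rng, lines, acc)
        batch_records.append((acc.sums["scoring"] - before, int(nb)))
    vox = None
    if acc.voxel is not None:
        vox = acc.voxel.reshape(grid.shape)
    return DoseTally(
        vox,
        dict(acc.sums),
        batch_records,
        int(settings.n_histories),
        acc.initial,
        {"settings": settings},
    )


def run_adaptive(
    well: geo.WellModel,
    scoring: geo.ScoringRegion,
    grid: geo.VoxelGrid | None,
    settings: TransportSettings,
    rng: np.random.Generator,
    lines: Sequence[EmissionLine] | None = None,
    target_rel_se: float = 0.015,
    max_histories: int = 1 << 26,
) -> DoseTally:
    """Double the history count until the scoring-region relative SE
    drops below ``target_rel_se`` (default 1.5%)."""
    tally = run(well, scoring, grid, settings, rng, lines)
    from dataclasses import replace

    while tally.relative_se() > target_rel_se and tally.histories < max_histories:
        more = replace(settings, n_histories=tally.histories)
        tally = tally.merge(run(well, scoring, grid, more, rng, lines))
    tally.meta["achieved_rel_se"] = tally.relative_se()
    tally.meta["target_rel_se"] = target_rel_se
    return tally
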