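"""Culture-well geometries, scoring regions and the dose-scoring voxel lattice.

Two vessels are modelled, each as a water volume inside 1 mm polystyrene
walls with vacuum above the medium surface:

* a flat-bottom cylindrical well (monolayer culture; default inner diameter
  34.8 mm, a standard 6-well format, holding 1 mL of medium), scored on a
  12 mm diameter x 0.01 mm cylinder seated on the bottom — the cell layer;
* a U-bottom well (spheroid culture; hemispherical bottom of default radius
  3.2 mm continued by a cylinder, holding 100 uL), scored on a 0.6 mm
  diameter sphere resting on the bottom apex — the spheroid.

A third, wall-less "bath" geometry (a large water ball) exists for
equilibrium-limit validation.

Coordinates: origin at the centre of the medium/wall bottom interface
(ball centre for the bath), z up, lengths in mm. 1 uL == 1 mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "OUTSIDE",
    "MEDIUM",
    "SCORING",
    "WALL",
    "REGION_NAMES",
    "WellModel",
    "ScoringRegion",
    "VoxelGrid",
    "build_2d_well",
    "build_3d_well",
    "build_bath",
    "locate",
    "locate_point",
    "voxel_index",
    "voxel_mass",
]

OUTSIDE, MEDIUM, SCORING, WALL = 0, 1, 2, 3
REGION_NAMES = {OUTSIDE: "outside", MEDIUM: "medium", SCORING: "scoring", WALL: "wall"}

WATER_DENSITY_G_CM3 = 1.0


@dataclass(frozen=True)
class WellModel:
    """A culture vessel: medium shape plus polystyrene wall.

    ``kind`` is ``"flat"`` (flat-bottom cylinder), ``"ubottom"``
    (hemispherical cap of radius ``inner_radius_mm`` continued by a
    cylinder) or ``"bath"`` (water ball of radius ``inner_radius_mm``,
    no wall). ``fill_height_mm`` is derived from the medium volume.
    """

    kind: str
    inner_radius_mm: float
    wall_thickness_mm: float
    medium_volume_ul: float
    well_depth_mm: float
    fill_height_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "ubottom", "bath"):
            raise ValueError(f"unknown well kind {self.kind!r}")
        if self.inner_radius_mm <= 0 or self.wall_thickness_mm < 0:
            raise ValueError("bad well dimensions")
        if self.kind != "bath" and self.medium_volume_ul <= 0:
            raise ValueError("medium volume must be positive")
        object.__setattr__(self, "fill_height_mm", self._solve_fill_height())
        if self.kind != "bath" and self.fill_height_mm > self.well_depth_mm + 1e-9:
            raise ValueError(
                f"medium volume {self.medium_volume_ul} uL exceeds vessel capacity "
                f"(fill height {self.fill_height_mm:.2f} mm > depth {self.well_depth_mm} mm)"
            )

    def _solve_fill_height(self) -> float:
        r = self.inner_radius_mm
        v = self.medium_volume_ul  # mm^3
        if self.kind == "flat":
            return v / (math.pi * r * r)
        if self.kind == "bath":
            return 2.0 * r
        hemi = 2.0 / 3.0 * math.pi * r**3
        if v >= hemi:
            return r + (v - hemi) / (math.pi * r * r)
        # spherical cap measured up from the apex: V(h) = pi h^2 (3r - h)/3
        cap = lambda h: math.pi * h * h * (3.0 * r - h) / 3.0 - v
        return brentq(cap, 0.0, r, xtol=1e-12 * r)

    # -- queries ---------------------------------------------------------

    def medium_mask(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points lie in the medium (scoring included)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        r2 = x * x + y * y
        rin = self.inner_radius_mm
        fill = self.fill_height_mm
        if self.kind == "flat":
            return (z >= 0.0) & (z <= fill) & (r2 <= rin * rin)
        if self.kind == "bath":
            return r2 + z * z <= rin * rin
        d2 = r2 + (z - rin) ** 2
        in_cap = (z <= np.minimum(rin, fill)) & (z >= 0.0) & (d2 <= rin * rin)
        in_cyl = (z > rin) & (z <= fill) & (r2 <= rin * rin)
        return in_cap | in_cyl

    def wall_mask(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "bath":
            return np.zeros(len(p), dtype=bool)
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        r2 = x * x + y * y
        rin = self.inner_radius_mm
        t = self.wall_thickness_mm
        fill = self.fill_height_mm
        rout2 = (rin + t) ** 2
        med = self.medium_mask(p)
        if self.kind == "flat":
            bottom = (z < 0.0) & (z >= -t) & (r2 <= rout2)
            side = (z >= 0.0) & (z <= fill) & (r2 <= rout2)
            return ~med & (bottom | side)
        d2 = r2 + (z - rin) ** 2
        shell = (z <= rin) & (d2 <= rout2) & (d2 > rin * rin)
        side = (z > rin) & (z <= fill) & (r2 <= rout2)
        return ~med & (shell | side)

    def sample_positions(
        self,
        n: int,
        rng: np.random.Generator,
        within: tuple[np.ndarray, float] | None = None,
    ) -> np.ndarray:
        """``n`` positions uniform over the medium, by rejection sampling.

        ``within=(center, radius)`` restricts to the intersection of the
        medium with a ball (importance restriction for sources far larger
        than the electron range); the caller is responsible for rescaling
        decay counts by the restricted volume.
        """
        if self.medium_volume_ul <= 0 and self.kind != "bath":
            raise ValueError("degenerate medium")
        lo, hi = self._medium_bbox()
        if within is not None:
            c = np.asarray(within[0], dtype=float)
            rad = float(within[1])
            lo = np.maximum(lo, c - rad)
            hi = np.minimum(hi, c + rad)
            if np.any(hi <= lo):
                raise ValueError("restriction ball does not intersect the medium")
        out = np.empty((n, 3))
        got = 0
        while got < n:
            m = max(int((n - got) * 2.5), 1024)
            cand = rng.uniform(lo, hi, size=(m, 3))
            ok = self.medium_mask(cand)
            if within is not None:
                ok &= np.sum((cand - c) ** 2, axis=1) <= rad * rad
            cand = cand[ok]
            take = min(len(cand), n - got)
            out[got : got + take] = cand[:take]
            got += take
        return out

    def _medium_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.inner_radius_mm
        if self.kind == "bath":
            return np.array([-r, -r, -r]), np.array([r, r, r])
        return np.array([-r, -r, 0.0]), np.array([r, r, self.fill_height_mm])


@dataclass(frozen=True)
class ScoringRegion:
    """The geometric proxy for the biological sample.

    ``"cylinder"``: axis-aligned disc of ``radius_mm`` x ``height_mm`` whose
    base sits at ``center_z_mm`` (the monolayer). ``"sphere"``: ball of
    ``radius_mm`` centred on the axis at ``center_z_mm`` (the spheroid).
    """

    shape: str
    radius_mm: float
    height_mm: float = 0.0
    center_z_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere"):
            raise ValueError(f"unknown scoring shape {self.shape!r}")
        if self.radius_mm <= 0 or (self.shape == "cylinder" and self.height_mm <= 0):
            raise ValueError("bad scoring dimensions")

    @property
    def volume_mm3(self) -> float:
        if self.shape == "cylinder":
            return math.pi * self.radius_mm**2 * self.height_mm
        return 4.0 / 3.0 * math.pi * self.radius_mm**3

    @property
    def mass_kg(self) -> float:
        """Water mass of the region (1 mm^3 of unit-density water = 1e-6 kg)."""
        return self.volume_mm3 * WATER_DENSITY_G_CM3 * 1e-6

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        if self.shape == "cylinder":
            return (
                (x * x + y * y <= self.radius_mm**2)
                & (z >= self.center_z_mm)
                & (z <= self.center_z_mm + self.height_mm)
            )
        return x * x + y * y + (z - self.center_z_mm) ** 2 <= self.radius_mm**2

    def bounding_sphere(self) -> tuple[np.ndarray, float]:
        if self.shape == "cylinder":
            c = np.array([0.0, 0.0, self.center_z_mm + self.height_mm / 2.0])
            return c, math.hypot(self.radius_mm, self.height_mm / 2.0)
        return np.array([0.0, 0.0, self.center_z_mm]), self.radius_mm

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.radius_mm
        if self.shape == "cylinder":
            z0 = self.center_z_mm
            return np.array([-r, -r, z0]), np.array([r, r, z0 + self.height_mm])
        z0 = self.center_z_mm
        return np.array([-r, -r, z0 - r]), np.array([r, r, z0 + r])


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned tally lattice with half-open voxels [lower, upper)."""

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm) or any(n <= 0 for n in self.shape):
            raise ValueError("bad grid definition")

    @property
    def upper_mm(self) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(self.spacing_mm) * np.asarray(
            self.shape
        )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.origin_mm)
        return np.all((p >= lo) & (p < self.upper_mm), axis=1)

    def index(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel indices, shape (n, 3); raises if any point is outside."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(self.contains(p)):
            raise ValueError("point outside voxel grid")
        rel = (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)
        return np.minimum(rel.astype(np.int64), np.asarray(self.shape) - 1)

    def flat_index(self, points: np.ndarray) -> np.ndarray:
        idx = self.index(points)
        nx, ny, nz = self.shape
        return (idx[:, 0] * ny + idx[:, 1]) * nz + idx[:, 2]

    def covers(self, scoring: ScoringRegion) -> bool:
        lo, hi = scoring.bbox()
        return bool(
            np.all(lo >= np.asarray(self.origin_mm) - 1e-9)
            and np.all(hi <= self.upper_mm + 1e-9)
        )


def voxel_mass(grid: VoxelGrid, density_g_cm3: float = WATER_DENSITY_G_CM3) -> float:
    """Mass of one voxel in kg (volume mm^3 x density; 1 mm^3 water = 1e-6 kg)."""
    return grid.voxel_volume_mm3 * density_g_cm3 * 1e-6


def voxel_index(point, grid: VoxelGrid):
    """Voxel index triple of a single point (half-open convention)."""
    return tuple(int(i) for i in grid.index(np.asarray(point))[0])


# -- builders ------------------------------------------------------------


def _grid_for_scoring(
    scoring: ScoringRegion, spacing: tuple[float, float, float], z_top: float | None
) -> VoxelGrid:
    lo, hi = scoring.bbox()
    if z_top is not None:
        hi = hi.copy()
        hi[2] = max(hi[2], z_top)
    sp = np.asarray(spacing)
    shape = tuple(int(math.ceil(round((h - l) / s, 9))) for l, h, s in zip(lo, hi, sp))
    return VoxelGrid(tuple(lo), tuple(spacing), shape)


def build_2d_well(config: dict | None = None):
    """The monolayer (flat-bottom) well, its scoring disc and tally grid.

    Defaults: inner diameter 34.8 mm, 1 mm walls, 1 mL of water, scoring
    cylinder 12 mm diameter x 0.01 mm seated on the bottom, voxels
    0.1 x 0.1 x 0.01 mm. ``grid_z_top_mm`` extends the grid upward (for
    depth profiles); by default the grid just covers the scoring disc.
    """
    cfg = {
        "inner_diameter_mm": 34.8,
        "wall_thickness_mm": 1.0,
        "medium_volume_ul": 1000.0,
        "well_depth_mm": 17.5,
        "scoring_diameter_mm": 12.0,
        "scoring_height_mm": 0.01,
        "voxel_xy_mm": 0.1,
        "voxel_z_mm": 0.01,
        "grid_z_top_mm": None,
    }
    _apply(cfg, config, "2D well geometry")
    well = WellModel(
        "flat",
        cfg["inner_diameter_mm"] / 2.0,
        cfg["wall_thickness_mm"],
        cfg["medium_volume_ul"],
        cfg["well_depth_mm"],
    )
    scoring = ScoringRegion(
        "cylinder", cfg["scoring_diameter_mm"] / 2.0, cfg["scoring_height_mm"], 0.0
    )
    if scoring.radius_mm > well.inner_radius_mm or (
        scoring.height_mm > well.fill_height_mm
    ):
        raise ValueError("scoring region not inside the medium")
    grid = _grid_for_scoring(
        scoring,
        (cfg["voxel_xy_mm"], cfg["voxel_xy_mm"], cfg["voxel_z_mm"]),
        cfg["grid_z_top_mm"],
    )
    return well, scoring, grid


def build_3d_well(config: dict | None = None):
    """The spheroid (U-bottom) well, its scoring sphere and tally grid.

    Defaults: hemispherical bottom radius 3.2 mm, 1 mm walls, 100 uL of
    water, scoring sphere 0.6 mm diameter resting on the bottom apex,
    isotropic 0.01 mm voxels.
    """
    cfg = {
        "inner_diameter_mm": 6.4,
        "wall_thickness_mm": 1.0,
        "medium_volume_ul": 100.0,
        "well_depth_mm": 11.0,
        "scoring_diameter_mm": 0.6,
        "voxel_mm": 0.01,
        "grid_z_top_mm": None,
    }
    _apply(cfg, config, "3D well geometry")
    well = WellModel(
        "ubottom",
        cfg["inner_diameter_mm"] / 2.0,
        cfg["wall_thickness_mm"],
        cfg["medium_volume_ul"],
        cfg["well_depth_mm"],
    )
    r = cfg["scoring_diameter_mm"] / 2.0
    scoring = ScoringRegion("sphere", r, center_z_mm=r)
    center, rad = scoring.bounding_sphere()
    if not np.all(well.medium_mask(center[None, :])) or (
        scoring.center_z_mm + r > well.fill_height_mm
    ):
        raise ValueError("scoring sphere not inside the medium")
    v = cfg["voxel_mm"]
    grid = _grid_for_scoring(scoring, (v, v, v), cfg["grid_z_top_mm"])
    return well, scoring, grid


def build_bath(config: dict | None = None):
    """A large water ball with a central scoring sphere (equilibrium check)."""
    cfg = {"radius_mm": 30.0, "scoring_diameter_mm": 0.6, "voxel_mm": 0.01}
    _apply(cfg, config, "bath geometry")
    r = cfg["radius_mm"]
    well = WellModel("bath", r, 0.0, 4.0 / 3.0 * math.pi * r**3, 2 * r)
    scoring = ScoringRegion("sphere", cfg["scoring_diameter_mm"] / 2.0, center_z_mm=0.0)
    v = cfg["voxel_mm"]
    grid = _grid_for_scoring(scoring, (v, v, v), None)
    return well, scoring, grid


def _apply(defaults: dict, overrides: dict | None, what: str) -> None:
    if not overrides:
        return
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    defaults.update(overrides)


def locate(points: np.ndarray, well: WellModel, scoring: ScoringRegion) -> np.ndarray:
    """Label points as OUTSIDE / MEDIUM / SCORING / WALL (mutually exclusive).

    Scoring points are medium points carrying the more specific label.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(p), dtype=np.uint8)
    med = well.medium_mask(p)
    out[med] = MEDIUM
    sc = med & scoring.contains(p)
    out[sc] = SCORING
    wall = well.wall_mask(p)
    out[wall] = WALL
    return out


def locate_point(point, well: WellModel, scoring: ScoringRegion) -> str:
    """Region name of a single point."""
    return REGION_NAMES[int(locate(np.asarray(point)[None, :], well, scoring)[0])]
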