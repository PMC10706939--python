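"""File formats: TOML run configuration, commented CSV tables, and the
raw + sidecar voxel-grid format.

Every writer stamps the RNG seed (and any extra metadata) into
comment-prefixed header lines, so outputs are reproducible by
construction. Voxel grids are stored as a raw little-endian float32 array
(C order) next to a JSON sidecar holding shape, spacing, origin and units;
write/read round-trips are byte-identical.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import VoxelGrid

__all__ = [
    "default_config",
    "read_config",
    "write_config",
    "read_csv",
    "write_csv",
    "write_voxel_grid",
    "read_voxel_grid",
]

_CONFIG_BLOCKS = {
    "seed": None,
    "geometry": {
        "kind",
        "inner_diameter_mm",
        "wall_thickness_mm",
        "medium_volume_ul",
        "well_depth_mm",
        "scoring_diameter_mm",
        "scoring_height_mm",
        "voxel_xy_mm",
        "voxel_z_mm",
        "voxel_mm",
        "grid_z_top_mm",
        "radius_mm",
    },
    "source": {"activity_mbq", "duration_h", "decay_correction", "half_life_d"},
    "transport": {
        "n_histories",
        "batches",
        "max_step_mm",
        "fine_step_mm",
        "range_cut_mm",
        "max_eloss_fraction",
        "range_rejection",
        "target_rel_se",
    },
    "output": {"directory"},
}


def default_config(kind: str = "3d") -> dict:
    """A complete run configuration with the study defaults."""
    return {
        "seed": 1,
        "geometry": {"kind": kind},
        "source": {"activity_mbq": 1.0, "duration_h": 3.0, "decay_correction": False},
        "transport": {"n_histories": 200_000, "batches": 20},
        "output": {"directory": "results"},
    }


def _validate(cfg: dict, path: str) -> dict:
    unknown = set(cfg) - set(_CONFIG_BLOCKS)
    if unknown:
        raise ValueError(f"unknown configuration keys in {path}: {sorted(unknown)}")
    for block, allowed in _CONFIG_BLOCKS.items():
        if allowed is None or block not in cfg:
            continue
        if not isinstance(cfg[block], dict):
            raise ValueError(f"configuration block [{block}] must be a table")
        bad = set(cfg[block]) - allowed
        if bad:
            raise ValueError(f"unknown keys in [{block}] of {path}: {sorted(bad)}")
    return cfg


def read_config(path: str | Path) -> dict:
    """Read and validate a TOML run configuration; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"configuration file not found: {p}")
    with open(p, "rb") as fh:
        cfg = tomllib.load(fh)
    return _validate(cfg, str(p))


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def write_config(cfg: dict, path: str | Path) -> None:
    """Write a (validated) flat configuration dict as TOML."""
    _validate(cfg, str(path))
    lines: list[str] = []
    for key, val in cfg.items():
        if not isinstance(val, dict):
            lines.append(f"{key} = {_toml_scalar(val)}")
    for key, val in cfg.items():
        if isinstance(val, dict):
            lines.append(f"\n[{key}]")
            lines.extend(f"{k} = {_toml_scalar(v)}" for k, v in val.items() if v is not None)
    Path(path).write_text("\n".join(lines) + "\n")


def write_csv(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, **meta
) -> None:
    """Write a table with comment-prefixed metadata header lines."""
    header = []
    if seed is not None:
        header.append(f"# seed: {seed}")
    header.extend(f"# {k}: {v}" for k, v in meta.items())
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (header comments skipped).

    Column order is irrelevant — tables are header-keyed.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return pd.read_csv(p, comment="#")


def write_voxel_grid(
    path: str | Path, grid: VoxelGrid, energy_kev: np.ndarray, seed: int | None = None
) -> tuple[Path, Path]:
    """Write the tally as ``<path>.raw`` (little-endian float32, C order)
    plus ``<path>.json`` sidecar. Returns the two paths."""
    if tuple(energy_kev.shape) != tuple(grid.shape):
        raise ValueError("tally shape does not match the grid")
    base = Path(path)
    raw = base.with_suffix(".raw")
    sidecar = base.with_suffix(".json")
    np.ascontiguousarray(energy_kev, dtype="<f4").tofile(raw)
    meta = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing_mm),
        "origin_mm": list(grid.origin_mm),
        "dtype": "<f4",
        "order": "C",
        "units": "keV",
    }
    if seed is not None:
        meta["seed"] = seed
    sidecar.write_text(json.dumps(meta, indent=1))
    return raw, sidecar


def read_voxel_grid(path: str | Path) -> tuple[VoxelGrid, np.ndarray]:
    """Read a raw + sidecar voxel grid; dimension mismatches are errors."""
    base = Path(path)
    sidecar = base.with_suffix(".json")
    raw = base.with_suffix(".raw")
    for p in (sidecar, raw):
        if not p.exists():
            raise FileNotFoundError(f"voxel grid file not found: {p}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(int(n) for n in meta["shape"])
    data = np.fromfile(raw, dtype=meta.get("dtype", "<f4"))
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"sidecar dimensions {shape} do not match payload length {data.size}"
        )
    grid = VoxelGrid(
        tuple(meta["origin_mm"]), tuple(meta["spacing_mm"]), shape
    )
    return grid, data.reshape(shape)
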