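#!/usr/bin/env python
"""Generate the synthetic assay datasets from the simulated dose table.

Uses the conversion table written by 02_conversion_table.py (required) so
that the synthetic biology is driven by this package's own dosimetry:
clonogenic colony counts (2D doses), spheroid growth trajectories (3D
doses) and 2D/3D viability luminescence. Writes
results/synthetic/{clonogenic,spheroids,viability}.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from welldose import io
from welldose.scoring import ConversionTable
from welldose.synthetic import (
    SyntheticDesign,
    synth_clonogenic,
    synth_spheroids,
    synth_viability,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    conv_path = ROOT / "results" / "conversion_table.csv"
    if not conv_path.exists():
        raise SystemExit(f"run analysis/02_conversion_table.py first ({conv_path} missing)")
    conv = ConversionTable(io.read_csv(conv_path))
    design = SyntheticDesign()
    outdir = ROOT / "results" / "synthetic"
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([args.seed, 30])
    io.write_csv(synth_clonogenic(design, conv, rng), outdir / "clonogenic.csv",
                 seed=args.seed)
    io.write_csv(synth_spheroids(design, conv, rng), outdir / "spheroids.csv",
                 seed=args.seed)
    io.write_csv(synth_viability(design, conv, rng), outdir / "viability.csv",
                 seed=args.seed)
    print(
        f"ground truth: alpha = {design.alpha_per_gy}/Gy, beta = "
        f"{design.beta_per_gy2}/Gy^2, growth {design.growth_rate_per_day}/day, "
        f"D50 = {design.d50_gy} Gy"
    )
    print(f"wrote three assay CSVs to {outdir}")


if __name__ == "__main__":
    main()
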