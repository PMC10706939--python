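"""Assay arithmetic: clonogenic survival, spheroid growth, 2D/3D viability
folds, the study's significance test, and the linear-quadratic linkage
between simulated dose and survival.

Input tables use the CSV schemas documented in :mod:`welldose.io`:

* clonogenic: line, activity_mbq, seeded, colonies, replicate
* spheroids:  line, activity_mbq, day, d1_um, d2_um, d3_um, experiment
* viability:  model, line, activity_mbq, day, lum, replicate
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "plating_efficiency",
    "surviving_fraction",
    "sf_table",
    "spheroid_diameter",
    "growth_curve",
    "viability_fold",
    "fold_table",
    "compare_to_control",
    "stats_table",
    "lq_fit",
    "lq_fit_with_se",
    "viability_fold_with_se",
]

SIGNIFICANCE_LEVEL = 0.01


def plating_efficiency(control_colonies: Sequence[float], seeded: float) -> float:
    """Fraction of seeded untreated cells forming colonies.

    Mean colony count of the control plates divided by the number of
    seeded cells. A value above 1 indicates a counting anomaly and is
    flagged with a warning, not an error.
    """
    if seeded <= 0:
        raise ValueError("seeded cell count must be positive")
    counts = np.asarray(list(control_colonies), dtype=float)
    if counts.size == 0:
        raise ValueError("no control colony counts")
    if np.any(counts < 0):
        raise ValueError("negative colony count")
    pe = float(counts.mean() / seeded)
    if pe > 1:
        warnings.warn(
            f"plating efficiency {pe:.3f} > 1: more colonies than seeded cells",
            stacklevel=2,
        )
    return pe


def surviving_fraction(
    treated_colonies: Sequence[float],
    seeded: float,
    pe: float,
    literal: bool = False,
) -> float:
    """Clonogenic surviving fraction.

    Standard normalisation: mean treated colonies / (seeded x PE), which
    makes the control condition exactly 1. ``literal=True`` instead
    multiplies PE by the mean colony count (the non-normalised reading of
    the assay protocol as printed), kept for audit only.
    """
    if seeded <= 0:
        raise ValueError("seeded cell count must be positive")
    if not 0 < pe <= 1:
        raise ValueError("plating efficiency must be in (0, 1]")
    counts = np.asarray(list(treated_colonies), dtype=float)
    if counts.size == 0:
        raise ValueError("no treated colony counts")
    if literal:
        return float(pe * counts.mean())
    return float(counts.mean() / (seeded * pe))


def sf_table(clonogenic: pd.DataFrame, literal: bool = False) -> pd.DataFrame:
    """Per (line, activity) surviving fractions from a clonogenic table.

    The 0-activity rows of each line define its plating efficiency.
    Returns columns line, activity_mbq, seeded, pe, sf, n_replicates.
    """
    _require(clonogenic, ["line", "activity_mbq", "seeded", "colonies"], "clonogenic")
    rows = []
    for line, sub in clonogenic.groupby("line", sort=True):
        ctrl = sub[sub["activity_mbq"] == 0]
        if ctrl.empty:
            raise ValueError(f"no control (0 MBq) rows for line {line!r}")
        seeded = float(ctrl["seeded"].iloc[0])
        pe = plating_efficiency(ctrl["colonies"], seeded)
        for act, grp in sub.groupby("activity_mbq", sort=True):
            rows.append(
                {
                    "line": line,
                    "activity_mbq": float(act),
                    "seeded": float(grp["seeded"].iloc[0]),
                    "pe": pe,
                    "sf": surviving_fraction(
                        grp["colonies"], float(grp["seeded"].iloc[0]), pe, literal
                    ),
                    "n_replicates": len(grp),
                }
            )
    return pd.DataFrame(rows)


def spheroid_diameter(measurements_um: Sequence[float]) -> float:
    """Mean of the three diameter measurements of one spheroid (um)."""
    m = np.asarray(list(measurements_um), dtype=float)
    if m.size != 3:
        raise ValueError("expected exactly three diameter measurements")
    if np.any(m <= 0):
        raise ValueError("diameters must be positive")
    return float(m.mean())


def growth_curve(spheroids: pd.DataFrame) -> pd.DataFrame:
    """Growth curves: mean +/- sd of spheroid diameter across experiments.

    One diameter per (experiment, activity, day) record = the mean of its
    three measurements. Returns columns line, activity_mbq, day,
    diameter_um, sd_um, n.
    """
    _require(
        spheroids,
        ["line", "activity_mbq", "day", "d1_um", "d2_um", "d3_um"],
        "spheroids",
    )
    df = spheroids.copy()
    df["diameter"] = df[["d1_um", "d2_um", "d3_um"]].mean(axis=1)
    out = (
        df.groupby(["line", "activity_mbq", "day"], sort=True)["diameter"]
        .agg(diameter_um="mean", sd_um=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    return out


def viability_fold(
    viability: pd.DataFrame,
    activity_mbq: float,
    day: float,
    normalize: bool = True,
) -> float:
    """Fold difference in viability between the 2D and 3D models.

    With ``normalize=True`` (default) each arm's mean luminescence is first
    divided by its own 0-activity control at the same day, making the fold
    comparable across models seeded with different cell numbers; with
    ``normalize=False`` raw means are divided.
    """
    _require(viability, ["model", "activity_mbq", "day", "lum"], "viability")

    def arm_mean(model: str, act: float) -> float:
        sel = viability[
            (viability["model"] == model)
            & (np.isclose(viability["activity_mbq"], act))
            & (np.isclose(viability["day"], day))
        ]
        if sel.empty:
            raise ValueError(f"no {model} rows at {act} MBq, day {day}")
        return float(sel["lum"].mean())

    v2, v3 = arm_mean("2D", activity_mbq), arm_mean("3D", activity_mbq)
    if normalize:
        v2 /= arm_mean("2D", 0.0)
        v3 /= arm_mean("3D", 0.0)
    if v3 == 0:
        raise ZeroDivisionError("3D viability signal is zero")
    return v2 / v3


def fold_table(viability: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """2D/3D folds for every (line, activity>0, day) present in both arms."""
    _require(viability, ["model", "line", "activity_mbq", "day", "lum"], "viability")
    rows = []
    for (line, act, day), _ in viability[viability["activity_mbq"] > 0].groupby(
        ["line", "activity_mbq", "day"], sort=True
    ):
        sub = viability[viability["line"] == line]
        try:
            f = viability_fold(sub, float(act), float(day), normalize)
        except ValueError:
            continue
        rows.append(
            {"line": line, "activity_mbq": float(act), "day": float(day), "fold_2d_3d": f}
        )
    return pd.DataFrame(rows)


def compare_to_control(
    values: Sequence[float], control: Sequence[float]
) -> tuple[float, float, bool]:
    """Welch's unpaired two-sample t-test against the control group.

    Returns (t statistic, two-sided p, significant at p < 0.01). Degenerate
    zero-variance pairs: p = 1 when the means agree, p = 0 when they do not
    (the limit of vanishing spread), both flagged non-parametrically.
    """
    a = np.asarray(list(values), dtype=float)
    b = np.asarray(list(control), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return math_inf_sign(a.mean() - b.mean()), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < SIGNIFICANCE_LEVEL)


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


def stats_table(
    df: pd.DataFrame, value: str, group_keys: Sequence[str], condition: str = "activity_mbq"
) -> pd.DataFrame:
    """Welch t-tests of every nonzero condition against its 0-condition control.

    ``group_keys`` define strata (e.g. ["line", "day"]); within each, every
    ``condition`` level > 0 is tested against level 0.
    """
    rows = []
    for keys, sub in df.groupby(list(group_keys), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ctrl = sub[sub[condition] == 0][value]
        if len(ctrl) < 2:
            continue
        for lvl, grp in sub[sub[condition] > 0].groupby(condition, sort=True):
            if len(grp) < 2:
                continue
            t, p, sig = compare_to_control(grp[value], ctrl)
            rows.append(
                dict(
                    zip(group_keys, keys),
                    **{condition: float(lvl), "t": t, "p": p, "significant": sig},
                )
            )
    return pd.DataFrame(rows)


def lq_fit(doses_gy: Sequence[float], sf: Sequence[float]) -> tuple[float, float]:
    """Fit the linear-quadratic survival model SF = exp(-aD - bD^2).

    Least squares on -ln SF = aD + bD^2 with b constrained non-negative;
    the model passes through SF(0) = 1 by construction. Returns (alpha
    [1/Gy], beta [1/Gy^2]).
    """
    alpha, beta, _ = lq_fit_with_se(doses_gy, sf)
    return alpha, beta


def lq_fit_with_se(
    doses_gy: Sequence[float], sf: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """LQ fit plus standard errors of (alpha, beta).

    SEs come from the residual-based least-squares covariance
    s^2 (A^T A)^-1 on the -ln SF scale (computed at the unconstrained
    solution; with fewer residual degrees of freedom than 1 they are
    reported as inf).
    """
    d = np.asarray(list(doses_gy), dtype=float)
    s = np.asarray(list(sf), dtype=float)
    if d.size != s.size or d.size < 3:
        raise ValueError("need at least three (dose, SF) pairs")
    if np.any((s <= 0) | (s > 1 + 1e-12)):
        raise ValueError("surviving fractions must lie in (0, 1]")
    if np.allclose(d, d[0]):
        raise ValueError("doses are all identical")
    y = -np.log(s)
    a_mat = np.column_stack([d, d * d])
    res = optimize.lsq_linear(a_mat, y, bounds=([-np.inf, 0.0], [np.inf, np.inf]))
    resid = y - a_mat @ res.x
    dof = d.size - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(a_mat.T @ a_mat)
        se = (math_sqrt(cov[0, 0]), math_sqrt(cov[1, 1]))
    else:
        se = (np.inf, np.inf)
    return float(res.x[0]), float(res.x[1]), se


def math_sqrt(x: float) -> float:
    return float(np.sqrt(max(x, 0.0)))


def viability_fold_with_se(
    viability: pd.DataFrame, activity_mbq: float, day: float
) -> tuple[float, float]:
    """Control-normalised 2D/3D fold and its delta-method standard error.

    The fold is a ratio of four arm means; its relative variance is the
    sum of the four relative variances of those means.
    """
    _require(viability, ["model", "activity_mbq", "day", "lum"], "viability")
    fold = viability_fold(viability, activity_mbq, day, normalize=True)
    rel_var = 0.0
    for model in ("2D", "3D"):
        for act in (activity_mbq, 0.0):
            sel = viability[
                (viability["model"] == model)
                & (np.isclose(viability["activity_mbq"], act))
                & (np.isclose(viability["day"], day))
            ]["lum"]
            if len(sel) < 2:
                return fold, np.inf
            rel_var += sel.var(ddof=1) / len(sel) / sel.mean() ** 2
    return fold, fold * float(np.sqrt(rel_var))


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")
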