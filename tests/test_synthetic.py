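"""Synthetic-assay generator: determinism, schema compatibility, designed
ground truth recovered by the analysis stages."""

import math
from dataclasses import replace

import numpy as np
import pytest

from welldose import radiobiology as rb
from welldose.scoring import ConversionTable
from welldose.synthetic import (
    SyntheticDesign,
    designed_fold,
    growth_inhibition,
    lq_survival,
    synth_clonogenic,
    synth_spheroids,
    synth_viability,
)

DESIGN = SyntheticDesign()
CONV = ConversionTable.from_dose_rates(
    {"2d": 0.3, "3d": 4.5},
    sorted(
        set(DESIGN.activities_clonogenic_mbq)
        | set(DESIGN.activities_spheroid_mbq)
        | set(DESIGN.activities_viability_mbq)
    ),
)


def test_deterministic_given_seed():
    for gen in (synth_clonogenic, synth_spheroids, synth_viability):
        a = gen(DESIGN, CONV, np.random.default_rng(5))
        b = gen(DESIGN, CONV, np.random.default_rng(5))
        assert a.equals(b)


def test_missing_activity_rejected():
    small = ConversionTable.from_dose_rates({"2d": 0.3, "3d": 4.5}, [0.5])
    with pytest.raises(ValueError):
        synth_clonogenic(DESIGN, small, np.random.default_rng(0))


class TestClonogenic:
    def test_schema_consumed_directly(self, rng):
        df = synth_clonogenic(DESIGN, CONV, rng)
        out = rb.sf_table(df)
        ctrl = out[out["activity_mbq"] == 0]
        assert np.allclose(ctrl["sf"], 1.0)

    def test_zero_lq_parameters_flatten_survival(self, rng):
        flat = replace(DESIGN, alpha_per_gy=0.0, beta_per_gy2=0.0, replicates=400)
        df = synth_clonogenic(flat, CONV, rng)
        pos = df[df["line"] == flat.target_pos.name]
        means = pos.groupby("activity_mbq")["colonies"].mean()
        mu = flat.target_pos.seeded * flat.target_pos.plating_efficiency
        se = math.sqrt(mu / 400)
        assert np.all(np.abs(means - mu) < 4 * se)

    def test_target_negative_line_flat_in_activity(self, rng):
        df = synth_clonogenic(replace(DESIGN, replicates=400), CONV, rng)
        neg = df[df["line"] == DESIGN.target_neg.name]
        means = neg.groupby("activity_mbq")["colonies"].mean()
        mu = DESIGN.target_neg.seeded * DESIGN.target_neg.plating_efficiency
        se = math.sqrt(mu / 400)
        assert np.all(np.abs(means - mu) < 4 * se)

    def test_large_n_means_match_lq_expectation(self, rng):
        big = replace(DESIGN, replicates=600)
        df = synth_clonogenic(big, CONV, rng)
        pos = df[(df["line"] == big.target_pos.name) & (df["activity_mbq"] == 2.0)]
        d = CONV.dose(2.0, "2d")
        mu = big.target_pos.seeded * big.target_pos.plating_efficiency * lq_survival(
            big.alpha_per_gy, big.beta_per_gy2, d
        )
        assert abs(pos["colonies"].mean() - mu) < 3 * math.sqrt(mu / 600)


class TestSpheroids:
    def test_inhibition_limits(self):
        assert growth_inhibition(0.0, 0.005) == 0.0
        assert growth_inhibition(1e9, 0.005) == pytest.approx(1.0, abs=1e-9)

    def test_control_growth_exact_without_noise(self, rng):
        clean = replace(DESIGN, diameter_cv=0.0, experiments=1)
        df = synth_spheroids(clean, CONV, rng)
        ctrl = df[(df["line"] == clean.target_pos.name) & (df["activity_mbq"] == 0)]
        curve = rb.growth_curve(ctrl)
        for _, row in curve.iterrows():
            expected = clean.d0_um * math.exp(clean.growth_rate_per_day * row["day"])
            assert row["diameter_um"] == pytest.approx(expected, rel=1e-12)

    def test_plateau_between_treated_activities(self, rng):
        """Doses far above D50: day-20 diameters at 0.05 and 0.4 MBq are
        statistically indistinguishable (the inhibition plateau), while the
        control is clearly separated from both."""
        design = replace(DESIGN, experiments=5)
        df = synth_spheroids(design, CONV, rng)
        pos = df[df["line"] == design.target_pos.name]
        pos = pos[pos["day"] == 20.0].copy()
        pos["diameter"] = pos[["d1_um", "d2_um", "d3_um"]].mean(axis=1)
        by_act = {a: g["diameter"] for a, g in pos.groupby("activity_mbq")}
        _, _, sig_plateau = rb.compare_to_control(by_act[0.4], by_act[0.05])
        assert not sig_plateau
        _, _, sig_ctrl = rb.compare_to_control(by_act[0.05], by_act[0.0])
        assert sig_ctrl

    def test_target_negative_untouched(self, rng):
        clean = replace(DESIGN, diameter_cv=0.0, experiments=1)
        df = synth_spheroids(clean, CONV, rng)
        neg = df[df["line"] == clean.target_neg.name]
        curve = rb.growth_curve(neg).set_index(["activity_mbq", "day"])
        for act in clean.activities_spheroid_mbq:
            assert curve.loc[(act, 20.0), "diameter_um"] == pytest.approx(
                curve.loc[(0.0, 20.0), "diameter_um"], rel=1e-12
            )


class TestViability:
    def test_equal_doses_fold_one(self, rng):
        same = ConversionTable.from_dose_rates(
            {"2d": 1.0, "3d": 1.0}, list(DESIGN.activities_viability_mbq)
        )
        assert designed_fold(DESIGN, same, 0.2, 7.0) == pytest.approx(1.0)
        df = synth_viability(replace(DESIGN, replicates=60), same, rng)
        pos = df[df["line"] == DESIGN.target_pos.name]
        f, se = rb.viability_fold_with_se(pos, 0.2, 7.0)
        assert abs(f - 1.0) < 3 * se

    def test_designed_fold_recovered(self, rng):
        design = replace(DESIGN, replicates=40)
        df = synth_viability(design, CONV, rng)
        pos = df[df["line"] == design.target_pos.name]
        truth = designed_fold(design, CONV, 0.2, 7.0)
        f, se = rb.viability_fold_with_se(pos, 0.2, 7.0)
        assert abs(f - truth) < 3 * se

    def test_fold_increases_over_days(self, rng):
        folds = [designed_fold(DESIGN, CONV, 0.2, d) for d in (7.0, 15.0, 21.0)]
        assert folds == sorted(folds)
        assert folds[0] > 1.0
        df = synth_viability(replace(DESIGN, replicates=60), CONV, rng)
        pos = df[df["line"] == DESIGN.target_pos.name]
        est = [rb.viability_fold(pos, 0.2, d) for d in (7.0, 15.0, 21.0)]
        assert est[2] > est[0]


class TestEndToEnd:
    def test_sf_to_lq_fit_recovers_design(self, rng):
        """synth -> SF table -> LQ fit returns the designed (alpha, beta)."""
        design = replace(DESIGN, replicates=12)
        df = synth_clonogenic(design, CONV, rng)
        sf = rb.sf_table(df)
        pos = sf[(sf["line"] == design.target_pos.name) & (sf["activity_mbq"] > 0)]
        doses = [CONV.dose(a, "2d") for a in pos["activity_mbq"]]
        a, b, (se_a, se_b) = rb.lq_fit_with_se(doses, pos["sf"])
        assert abs(a - design.alpha_per_gy) < 3 * max(se_a, 1e-3)
        assert abs(b - design.beta_per_gy2) < 3 * max(se_b, 1e-3)
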