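"""Assay arithmetic: PE/SF, growth metrics, folds, Welch test, LQ fit."""

import math

import numpy as np
import pandas as pd
import pytest

from welldose import radiobiology as rb


class TestPlatingEfficiency:
    def test_mean_over_seeded(self):
        assert rb.plating_efficiency([100, 110, 90], 250) == pytest.approx(0.4)
        assert rb.plating_efficiency([1000], 1000) == 1.0

    def test_zero_seeded_errors(self):
        with pytest.raises(ValueError):
            rb.plating_efficiency([10], 0)

    def test_pe_above_one_warns(self):
        with pytest.warns(UserWarning):
            rb.plating_efficiency([300], 250)


class TestSurvivingFraction:
    def test_control_normalises_to_one(self):
        pe = rb.plating_efficiency([100, 110, 90], 250)
        assert rb.surviving_fraction([100, 110, 90], 250, pe) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert rb.surviving_fraction([200], 1000, 0.4) == pytest.approx(0.5)

    def test_literal_variant_kept_for_audit(self):
        # the non-normalised reading: PE x mean colonies
        assert rb.surviving_fraction([200], 1000, 0.4, literal=True) == pytest.approx(80.0)

    def test_zero_pe_errors(self):
        with pytest.raises(ValueError):
            rb.surviving_fraction([10], 100, 0.0)

    def test_scale_invariance_in_colony_units(self):
        a = rb.surviving_fraction([20, 30], 100, 0.25)
        b = rb.surviving_fraction([200, 300], 1000, 0.25)
        assert a == pytest.approx(b)

    def test_poisson_lq_data_recovers_closed_form(self, rng):
        """Large-n Poisson colonies under LQ survival: SF -> exp(-aD-bD^2)."""
        alpha, beta, dose, seeded, pe, n = 0.2, 0.05, 2.0, 1000, 0.4, 4000
        target = math.exp(-(alpha * dose + beta * dose**2))
        ctrl = rng.poisson(seeded * pe, n)
        treat = rng.poisson(seeded * pe * target, n)
        sf = rb.surviving_fraction(treat, seeded, rb.plating_efficiency(ctrl, seeded))
        se = target * math.sqrt(2.0 / (n * seeded * pe * target))
        assert abs(sf - target) < 3 * se
        assert sf == pytest.approx(math.exp(-0.6), rel=0.02)


class TestSfTable:
    def test_control_rows_define_pe(self):
        df = pd.DataFrame(
            {
                "line": ["L"] * 4,
                "activity_mbq": [0.0, 0.0, 1.0, 1.0],
                "seeded": [1000] * 4,
                "colonies": [200, 200, 100, 100],
                "replicate": [1, 2, 1, 2],
            }
        )
        out = rb.sf_table(df)
        assert out[out["activity_mbq"] == 0]["sf"].iloc[0] == pytest.approx(1.0)
        assert out[out["activity_mbq"] == 1]["sf"].iloc[0] == pytest.approx(0.5)
        assert out["pe"].iloc[0] == pytest.approx(0.2)

    def test_missing_control_errors(self):
        df = pd.DataFrame(
            {"line": ["L"], "activity_mbq": [1.0], "seeded": [100], "colonies": [10]}
        )
        with pytest.raises(ValueError):
            rb.sf_table(df)


class TestSpheroids:
    def test_mean_of_three(self):
        assert rb.spheroid_diameter([590, 600, 610]) == 600.0
        with pytest.raises(ValueError):
            rb.spheroid_diameter([600, 610])

    def test_equal_replicates_zero_sd(self):
        df = pd.DataFrame(
            {
                "line": ["L"] * 2,
                "activity_mbq": [0.0] * 2,
                "day": [7.0] * 2,
                "d1_um": [600.0] * 2,
                "d2_um": [600.0] * 2,
                "d3_um": [600.0] * 2,
                "experiment": [1, 2],
            }
        )
        out = rb.growth_curve(df)
        assert out["sd_um"].iloc[0] == 0.0
        assert out["diameter_um"].iloc[0] == 600.0

    def test_noiseless_exponential_roundtrip(self):
        d0, r = 400.0, 0.05
        rows = []
        for day in (0, 7, 14, 20):
            d = d0 * math.exp(r * day)
            rows.append(
                {"line": "L", "activity_mbq": 0.0, "day": day, "d1_um": d,
                 "d2_um": d, "d3_um": d, "experiment": 1}
            )
        out = rb.growth_curve(pd.DataFrame(rows))
        for _, row in out.iterrows():
            assert row["diameter_um"] == pytest.approx(d0 * math.exp(r * row["day"]), rel=1e-12)

    def test_permutation_invariance(self, rng):
        rows = []
        for e in range(1, 4):
            for day in (0, 7):
                m = rng.uniform(500, 700, 3)
                rows.append(
                    {"line": "L", "activity_mbq": 0.2, "day": day, "d1_um": m[0],
                     "d2_um": m[1], "d3_um": m[2], "experiment": e}
                )
        df = pd.DataFrame(rows)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = rb.growth_curve(df)
        b = rb.growth_curve(shuffled)
        pd.testing.assert_frame_equal(a, b)


def viability_frame(v2, v3, c2=1.0, c3=1.0, day=7.0, act=0.2):
    rows = []
    for model, treated, ctrl in (("2D", v2, c2), ("3D", v3, c3)):
        for rep, val in enumerate([treated * 0.98, treated, treated * 1.02], 1):
            rows.append({"model": model, "line": "L", "activity_mbq": act,
                         "day": day, "lum": val, "replicate": rep})
        for rep, val in enumerate([ctrl * 0.99, ctrl, ctrl * 1.01], 1):
            rows.append({"model": model, "line": "L", "activity_mbq": 0.0,
                         "day": day, "lum": val, "replicate": rep})
    return pd.DataFrame(rows)


class TestViabilityFold:
    def test_identical_normalised_viabilities_give_one(self):
        df = viability_frame(0.5, 0.5)
        assert rb.viability_fold(df, 0.2, 7.0) == pytest.approx(1.0)

    def test_example_division(self):
        df = viability_frame(0.72, 0.30)
        assert rb.viability_fold(df, 0.2, 7.0) == pytest.approx(2.4)

    def test_reciprocal_invariance(self):
        df = viability_frame(0.72, 0.30)
        f = rb.viability_fold(df, 0.2, 7.0)
        swapped = df.copy()
        swapped["model"] = swapped["model"].map({"2D": "3D", "3D": "2D"})
        assert f * rb.viability_fold(swapped, 0.2, 7.0) == pytest.approx(1.0)

    def test_raw_mode_differs_when_controls_differ(self):
        df = viability_frame(0.72, 0.30, c2=2.0, c3=1.0)
        norm = rb.viability_fold(df, 0.2, 7.0, normalize=True)
        raw = rb.viability_fold(df, 0.2, 7.0, normalize=False)
        assert norm == pytest.approx(raw / 2.0, rel=1e-9)

    def test_missing_arm_errors(self):
        df = viability_frame(0.72, 0.30)
        with pytest.raises(ValueError):
            rb.viability_fold(df[df["model"] == "2D"], 0.2, 7.0)


class TestWelch:
    def test_identical_groups(self):
        t, p, sig = rb.compare_to_control([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_huge_separation_significant(self):
        _, p, sig = rb.compare_to_control([101, 102, 103], [1, 2, 3])
        assert sig and p < 1e-4

    def test_textbook_pair_matches_reference_implementation(self):
        """Frozen from R 4.3.3 t.test((10..13),(14..17))."""
        t, p, sig = rb.compare_to_control([10, 11, 12, 13], [14, 15, 16, 17])
        assert t == pytest.approx(-4.3817804600, abs=1e-6)
        assert p == pytest.approx(0.0046592149, abs=1e-6)
        assert sig

    def test_small_groups_error(self):
        with pytest.raises(ValueError):
            rb.compare_to_control([1.0], [1.0, 2.0])

    def test_stats_table(self):
        df = viability_frame(0.1, 0.1)
        out = rb.stats_table(df, "lum", ["model", "line", "day"])
        assert set(out["model"]) == {"2D", "3D"}
        assert out["significant"].all()


class TestLqFit:
    def test_noiseless_recovery(self):
        alpha, beta = 0.2, 0.05
        d = np.array([0.5, 1.0, 2.0, 4.0])
        sf = np.exp(-alpha * d - beta * d * d)
        a, b = rb.lq_fit(d, sf)
        assert a == pytest.approx(alpha, abs=1e-6)
        assert b == pytest.approx(beta, abs=1e-6)

    def test_forced_through_origin(self):
        d = np.array([0.0, 1.0, 2.0])
        sf = np.array([1.0, 0.8, 0.6])
        a, b = rb.lq_fit(d, sf)
        # SF(0)=1 contributes a zero row; the model has no intercept
        assert math.exp(-a * 0 - b * 0) == 1.0

    def test_beta_constrained_nonnegative(self):
        d = np.array([1.0, 2.0, 3.0])
        sf = np.exp(-0.5 * d + 0.05 * d * d)  # upward curvature
        _, b = rb.lq_fit(d, np.clip(sf, None, 1.0))
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rb.lq_fit([1.0, 2.0], [0.9, 0.8])
        with pytest.raises(ValueError):
            rb.lq_fit([1.0, 1.0, 1.0], [0.9, 0.8, 0.7])
        with pytest.raises(ValueError):
            rb.lq_fit([1.0, 2.0, 3.0], [0.9, 0.8, 0.0])
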