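"""Transport engine: conservation, determinism, kill rules, convergence."""

import numpy as np
import pytest

from welldose import geometry as geo
from welldose.materials import water_table
from welldose.transport import (
    DoseTally,
    ParticleState,
    TransportSettings,
    run,
    run_adaptive,
    step,
)


def small_settings(**kw):
    kw.setdefault("n_histories", 20_000)
    return TransportSettings(**kw)


class TestStep:
    def setup_method(self):
        self.well, self.scoring, self.grid = geo.build_3d_well()

    def test_residual_range_below_cut_kills_with_local_deposit(self, rng):
        # 20 keV has a residual CSDA range < 0.01 mm
        assert water_table().csda_range(20.0) < 0.01
        p = ParticleState(np.array([0.0, 0.0, 0.3]), np.array([0.0, 0.0, 1.0]), 20.0)
        new, deposits = step(p, self.grid, self.well, self.scoring, small_settings(), rng)
        assert not new.alive
        assert deposits["scoring"] == pytest.approx(20.0)
        assert sum(deposits.values()) == pytest.approx(20.0)

    def test_downward_electron_from_bottom_deposits_in_wall(self, rng):
        well, scoring, grid = geo.build_2d_well()
        st = small_settings(range_rejection=False)
        p = ParticleState(np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0]), 497.0)
        totals = {k: 0.0 for k in ("scoring", "medium", "wall", "escaped", "radiative")}
        while p.alive:
            p, dep = step(p, grid, well, scoring, st, rng)
            for k, v in dep.items():
                totals[k] += v
        assert sum(totals.values()) == pytest.approx(497.0, rel=1e-9)
        assert totals["wall"] > 0.8 * 497.0
        assert totals["scoring"] + totals["medium"] < 0.2 * 497.0

    def test_nan_state_rejected(self):
        with pytest.raises(ValueError):
            ParticleState(np.array([np.nan, 0, 0]), np.array([0.0, 0.0, 1.0]), 100.0)
        with pytest.raises(ValueError):
            ParticleState(np.zeros(3), np.array([0.0, 0.0, 2.0]), 100.0)  # not unit


class TestRun:
    def test_zero_histories_errors(self, rng):
        well, scoring, grid = geo.build_3d_well()
        with pytest.raises(ValueError):
            run(well, scoring, grid, TransportSettings(n_histories=0), rng)

    def test_same_seed_identical_tallies(self):
        well, scoring, grid = geo.build_3d_well()
        st = small_settings(n_histories=5_000)
        t1 = run(well, scoring, grid, st, np.random.default_rng(42))
        t2 = run(well, scoring, grid, st, np.random.default_rng(42))
        assert t1.region_energy_kev == t2.region_energy_kev
        np.testing.assert_array_equal(t1.voxel_energy_kev, t2.voxel_energy_kev)
        assert t1.batch_scoring_kev == t2.batch_scoring_kev

    @pytest.mark.parametrize("rejection", [True, False])
    def test_energy_conservation(self, rejection):
        """Deposits + escaped + radiative account for all emitted energy."""
        well, scoring, grid = geo.build_3d_well()
        st = small_settings(n_histories=8_000, range_rejection=rejection)
        tally = run(well, scoring, grid, st, np.random.default_rng(7))
        assert tally.energy_balance_error() < 1e-9

    def test_single_history_bounded_by_initial_energy(self):
        well, scoring, grid = geo.build_3d_well()
        st = TransportSettings(n_histories=2, batches=2, range_rejection=False)
        tally = run(well, scoring, grid, st, np.random.default_rng(3))
        assert tally.deposited_energy_kev <= tally.initial_energy_kev + 1e-9

    def test_voxel_tally_consistent_with_scoring_sum(self, dose_3d):
        """In-grid voxel energy is at least the scoring-region energy (the
        grid box circumscribes the scoring sphere) and not wildly more."""
        well, scoring, grid, tally, rd = dose_3d
        vox = float(tally.voxel_energy_kev.sum())
        assert vox >= tally.scoring_energy_kev * 0.999
        assert vox <= tally.scoring_energy_kev * 2.5


class TestStatistics:
    def test_relative_se_decreases_with_histories(self):
        well, scoring, _ = geo.build_3d_well()
        t_small = run(well, scoring, None, small_settings(n_histories=6_000),
                      np.random.default_rng(5))
        t_big = run(well, scoring, None, small_settings(n_histories=60_000),
                    np.random.default_rng(5))
        assert 0 < t_big.relative_se() < t_small.relative_se()

    def test_adaptive_mode_hits_target(self):
        well, scoring, _ = geo.build_3d_well()
        st = small_settings(n_histories=10_000)
        tally = run_adaptive(well, scoring, None, st, np.random.default_rng(9),
                             target_rel_se=0.05)
        assert tally.relative_se() < 0.05
        assert tally.meta["achieved_rel_se"] == tally.relative_se()
        assert tally.histories >= 10_000

    def test_merge_accumulates(self):
        well, scoring, _ = geo.build_3d_well()
        a = run(well, scoring, None, small_settings(n_histories=4_000),
                np.random.default_rng(1))
        b = run(well, scoring, None, small_settings(n_histories=4_000),
                np.random.default_rng(2))
        m = a.merge(b)
        assert m.histories == 8_000
        assert m.scoring_energy_kev == pytest.approx(
            a.scoring_energy_kev + b.scoring_energy_kev
        )
        assert len(m.batch_scoring_kev) == len(a.batch_scoring_kev) * 2


class TestConvergence:
    def test_step_size_halving_within_statistics(self):
        """Halving both step caps moves the scored energy by less than the
        combined 3 SE statistical resolution."""
        well, scoring, _ = geo.build_3d_well()
        n = 40_000
        coarse = run(well, scoring, None, small_settings(n_histories=n),
                     np.random.default_rng(11))
        fine = run(
            well, scoring, None,
            small_settings(n_histories=n, max_step_mm=0.05, fine_step_mm=0.005),
            np.random.default_rng(12),
        )
        ec = coarse.scoring_energy_kev / coarse.histories
        ef = fine.scoring_energy_kev / fine.histories
        se = np.hypot(ec * coarse.relative_se(), ef * fine.relative_se())
        assert abs(ec - ef) < 3 * se

    def test_range_rejection_unbiased_for_scoring_dose(self):
        """Range rejection must not change the scoring-region energy beyond
        statistics (it only redirects doomed histories)."""
        well, scoring, _ = geo.build_3d_well()
        n = 40_000
        on = run(well, scoring, None, small_settings(n_histories=n),
                 np.random.default_rng(21))
        off = run(well, scoring, None,
                  small_settings(n_histories=n, range_rejection=False),
                  np.random.default_rng(22))
        e_on = on.scoring_energy_kev / n
        e_off = off.scoring_energy_kev / n
        se = np.hypot(e_on * on.relative_se(), e_off * off.relative_se())
        assert abs(e_on - e_off) < 3 * se
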