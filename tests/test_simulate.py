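import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pusim.locus import BinGrid, Origin, Barrier, LocusConfig, SimulationParams
from pusim.simulate import (CANONICAL, RESTARTED, SimulationError,
                            TransitionNotFoundError, simulate_cell,
                            simulate_cell_fixed_step, simulate_ensemble,
                            termination_midpoint)
from tests.conftest import make_random_small_config


def _cell(config, seed=0, params=None):
    return simulate_cell(config, params or SimulationParams(),
                         np.random.default_rng(seed))


class TestSingleFork:
    def test_replication_time_is_distance_over_velocity(self):
        # one origin at 10 kb firing at t=0, v=1.8 kb/min: the bin at 19 kb
        # is reached rightward after 9 kb / 1.8 kb/min = 5 min
        grid = BinGrid(0, 20_000, 100)
        cfg = LocusConfig(grid=grid, origins=[Origin(10_000.0)])
        cell = _cell(cfg)
        k = 19_000 // 100
        assert cell.direction[k] == 1
        assert cell.replication_time[k] == pytest.approx(5.0)
        k_left = 1_000 // 100
        assert cell.direction[k_left] == -1
        assert cell.replication_time[k_left] == pytest.approx(5.0)

    def test_every_bin_replicated_exactly_once(self):
        grid = BinGrid(0, 20_000, 100)
        cfg = LocusConfig(grid=grid, origins=[Origin(10_000.0)])
        cell = _cell(cfg)
        assert np.all(np.isfinite(cell.replication_time))
        assert set(np.unique(cell.direction)) <= {-1, 1}


class TestBarrierKinematics:
    def test_closed_form_meeting_point(self, two_origin_barrier_config):
        # right fork waits 11 min at 3 kb, restarts at t=12.667; converging
        # fork from 30 kb meets it at x=5.1 kb, t=13.833
        cell = _cell(two_origin_barrier_config)
        xs = two_origin_barrier_config.grid.bin_starts()
        right = cell.direction > 0
        boundary = xs[right][-1]  # last rightward-replicated bin
        assert abs(boundary - 5_100) <= 300
        k = np.searchsorted(xs, 4_800)
        assert cell.replication_time[k] == pytest.approx(13.6667, abs=1e-3)
        k2 = np.searchsorted(xs, 5_400)
        assert cell.replication_time[k2] == pytest.approx(13.6667, abs=1e-3)
        # bins downstream of the barrier were synthesised by the restarted fork
        assert cell.fork_type[np.searchsorted(xs, 3_600)] == RESTARTED
        assert cell.fork_type[np.searchsorted(xs, 2_400)] == CANONICAL

    def test_null_probability_reproduces_barrier_free_run(self, two_origin_barrier_config):
        cfg = two_origin_barrier_config.copy()
        cfg.barriers[0].arrest_probability = 0.0
        free = LocusConfig(grid=cfg.grid, origins=cfg.origins, barriers=[])
        a = _cell(cfg, seed=5)
        b = _cell(free, seed=5)
        # direction/type are bit-equal; times agree to float rounding only,
        # because the trajectory is bookkept in different segments
        np.testing.assert_allclose(a.replication_time, b.replication_time,
                                   rtol=0, atol=1e-9)
        assert np.array_equal(a.direction, b.direction)
        assert np.array_equal(a.fork_type, b.fork_type)

    def test_zero_delay_pause_is_invisible(self, two_origin_barrier_config):
        cfg = two_origin_barrier_config.copy()
        cfg.barriers[0] = Barrier(3_000.0, "rightward", kind="pause",
                                  arrest_probability=1.0, delay=0.0)
        free = LocusConfig(grid=cfg.grid, origins=cfg.origins, barriers=[])
        a = _cell(cfg, seed=5)
        b = _cell(free, seed=5)
        np.testing.assert_allclose(a.replication_time, b.replication_time,
                                   rtol=0, atol=1e-9)
        assert np.array_equal(a.direction, b.direction)

    def test_zero_delay_restart_changes_only_fork_type(self, two_origin_barrier_config):
        cfg = two_origin_barrier_config.copy()
        cfg.barriers[0].delay = 0.0
        free = LocusConfig(grid=cfg.grid, origins=cfg.origins, barriers=[])
        a = _cell(cfg, seed=5)
        b = _cell(free, seed=5)
        np.testing.assert_allclose(a.replication_time, b.replication_time,
                                   rtol=0, atol=1e-9)
        assert np.array_equal(a.direction, b.direction)
        assert np.any(a.fork_type == RESTARTED)  # HR identity still switches

    def test_restart_offset_rereplicates_upstream_bins(self):
        # restart 600 bp behind the barrier: bins in between are overwritten
        # by the (later) restarted fork
        grid = BinGrid(0, 12_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0)],
                          barriers=[Barrier(3_000.0, "rightward", kind="restart",
                                            arrest_probability=1.0, delay=2.0,
                                            restart_offset=-600.0)])
        cell = _cell(cfg)
        xs = grid.bin_starts()
        k = np.searchsorted(xs, 2_400)
        assert cell.fork_type[k] == RESTARTED
        # re-replicated at t = arrival (1.667) + delay (2) + 0 travel
        assert cell.replication_time[k] == pytest.approx(3.6667, abs=1e-3)
        assert cell.fork_type[np.searchsorted(xs, 2_100)] == CANONICAL

    def test_restarted_fork_transits_downstream_barrier_without_delay(self):
        # canonical_only second barrier: transit time is exactly distance/v
        grid = BinGrid(0, 12_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0)],
                          barriers=[
                              Barrier(3_000.0, "rightward", kind="restart",
                                      arrest_probability=1.0, delay=5.0),
                              Barrier(9_000.0, "rightward", kind="restart",
                                      arrest_probability=1.0, delay=7.0),
                          ])
        cell = _cell(cfg)
        xs = grid.bin_starts()
        t_before = cell.replication_time[np.searchsorted(xs, 8_700)]
        t_after = cell.replication_time[np.searchsorted(xs, 9_300)]
        assert t_after - t_before == pytest.approx(600 / 1800, abs=1e-9)
        # absolute: 3000/1800 + 5 + 7800/1800
        assert t_after == pytest.approx(3000 / 1800 + 5.0 + 6300 / 1800, abs=1e-9)

    def test_restarted_fork_delayed_when_transit_delay_set(self):
        grid = BinGrid(0, 12_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0)],
                          barriers=[
                              Barrier(3_000.0, "rightward", kind="restart",
                                      arrest_probability=1.0, delay=5.0),
                              Barrier(9_000.0, "rightward", kind="restart",
                                      arrest_probability=1.0, delay=7.0,
                                      restarted_fork_delay=4.0),
                          ])
        cell = _cell(cfg)
        xs = grid.bin_starts()
        t_before = cell.replication_time[np.searchsorted(xs, 8_700)]
        t_after = cell.replication_time[np.searchsorted(xs, 9_300)]
        assert t_after - t_before == pytest.approx(4.0 + 600 / 1800, abs=1e-9)


class TestFixedStepOracle:
    def test_meeting_point_converges_to_closed_form(self, two_origin_barrier_config):
        cell = simulate_cell_fixed_step(two_origin_barrier_config,
                                        SimulationParams(), 0.001,
                                        np.random.default_rng(0))
        xs = two_origin_barrier_config.grid.bin_starts()
        boundary = xs[cell.direction > 0][-1]
        assert abs(boundary - 5_100) <= 300

    def test_symmetric_two_origin_termination(self):
        grid = BinGrid(0, 30_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0), Origin(30_000.0)])
        cell = simulate_cell_fixed_step(cfg, SimulationParams(), 0.001,
                                        np.random.default_rng(0))
        xs = grid.bin_starts()
        boundary = xs[cell.direction > 0][-1]
        assert abs(boundary - 15_000) <= 300

    def test_giant_timestep_still_completes_replication(self):
        grid = BinGrid(0, 6_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(3_000.0)])
        cell = simulate_cell_fixed_step(cfg, SimulationParams(), 1e4,
                                        np.random.default_rng(0))
        assert np.all(np.isfinite(cell.replication_time))

    def test_nonpositive_dt_rejected(self):
        grid = BinGrid(0, 6_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(3_000.0)])
        with pytest.raises(ValueError):
            simulate_cell_fixed_step(cfg, SimulationParams(), 0.0,
                                     np.random.default_rng(0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_engines_agree_on_random_loci(self, trial_seed):
        rng = np.random.default_rng(trial_seed)
        cfg = make_random_small_config(rng)
        cell_seed = int(rng.integers(2 ** 31))
        a = simulate_cell(cfg, SimulationParams(),
                          np.random.default_rng(cell_seed))
        b = simulate_cell_fixed_step(cfg, SimulationParams(), 0.001,
                                     np.random.default_rng(cell_seed))
        assert np.array_equal(a.direction, b.direction)
        assert np.array_equal(a.fork_type, b.fork_type)
        assert np.max(np.abs(a.replication_time - b.replication_time)) <= 0.001 + 1e-9


class TestEnsemble:
    def test_usage_mapping_canonical_rightward(self):
        grid = BinGrid(0, 6_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0)])
        params = SimulationParams(n_cells=10, master_seed=1, alpha_fraction=0.1)
        prof = simulate_ensemble(cfg, params)
        k = 5  # interior rightward bin
        assert prof.usage[("watson", "epsilon")][k] == 1.0
        assert prof.usage[("crick", "delta")][k] == pytest.approx(0.9)
        assert prof.usage[("crick", "alpha")][k] == pytest.approx(0.1)

    def test_restarted_bins_are_delta_delta(self):
        grid = BinGrid(0, 6_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0)],
                          barriers=[Barrier(1_500.0, "rightward", kind="restart",
                                            arrest_probability=1.0, delay=1.0)])
        prof = simulate_ensemble(cfg, SimulationParams(n_cells=10, master_seed=1))
        k = 10  # 3000 bp, downstream of the barrier
        assert prof.frac_restarted[k] == 1.0
        assert prof.usage[("watson", "delta")][k] == 1.0
        assert prof.usage[("crick", "delta")][k] == 1.0
        assert prof.usage[("watson", "alpha")][k] == 0.0

    def test_same_master_seed_is_bit_identical(self):
        grid = BinGrid(0, 9_000, 300)
        cfg = LocusConfig(grid=grid, origins=[
            Origin(0.0, efficiency=0.8, mean_firing_time=2, firing_time_sd=1),
            Origin(9_000.0, efficiency=0.8, mean_firing_time=2, firing_time_sd=1)])
        p = SimulationParams(n_cells=40, master_seed=11)
        a = simulate_ensemble(cfg, p)
        b = simulate_ensemble(cfg, p)
        for key in a.usage:
            assert np.array_equal(a.usage[key], b.usage[key])
        assert np.array_equal(a.frac_rightward, b.frac_rightward)
        assert np.array_equal(a.mean_replication_time, b.mean_replication_time)

    def test_direction_and_usage_fractions_close(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            cfg = make_random_small_config(rng)
            prof = simulate_ensemble(cfg, SimulationParams(n_cells=20, master_seed=2))
            for strand in ("watson", "crick"):
                total = sum(prof.usage[(strand, p)] for p in ("epsilon", "delta", "alpha"))
                np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_strand_symmetry_without_barriers_or_alpha(self):
        grid = BinGrid(0, 15_000, 300)
        cfg = LocusConfig(grid=grid, origins=[
            Origin(0.0, efficiency=0.9, mean_firing_time=2, firing_time_sd=1),
            Origin(9_000.0, efficiency=0.7, mean_firing_time=4, firing_time_sd=2),
            Origin(15_000.0, efficiency=0.9, mean_firing_time=2, firing_time_sd=1)])
        prof = simulate_ensemble(cfg, SimulationParams(n_cells=50, master_seed=7,
                                                       alpha_fraction=0.0))
        # same-cell bookkeeping: epsilon on Watson == delta on Crick, exactly
        assert np.array_equal(prof.usage[("watson", "epsilon")],
                              prof.usage[("crick", "delta")])


class TestTerminationMidpoint:
    def test_symmetric_origins_terminate_centrally(self):
        grid = BinGrid(0, 30_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0), Origin(30_000.0)])
        prof = simulate_ensemble(cfg, SimulationParams(n_cells=5, master_seed=0))
        mid = termination_midpoint(prof, (6_000, 24_000))
        assert abs(mid - 15_000) <= 300

    def test_delayed_fork_terminates_at_closed_form_position(self, two_origin_barrier_config):
        prof = simulate_ensemble(two_origin_barrier_config,
                                 SimulationParams(n_cells=5, master_seed=0))
        mid = termination_midpoint(prof, (0, 30_000))
        assert abs(mid - 5_100) <= 300

    def test_monotone_profile_raises(self):
        grid = BinGrid(0, 6_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(0.0)])
        prof = simulate_ensemble(cfg, SimulationParams(n_cells=5, master_seed=0))
        with pytest.raises(TransitionNotFoundError):
            termination_midpoint(prof, (0, 6_000))


class TestDegenerateInputs:
    def test_no_competent_origin_resamples(self):
        grid = BinGrid(0, 6_000, 300)
        cfg = LocusConfig(grid=grid, origins=[Origin(3_000.0, efficiency=0.05)])
        cell = _cell(cfg, seed=1)
        assert np.all(np.isfinite(cell.replication_time))
        # with 5% efficiency most cells need redraws
        counts = [simulate_cell(cfg, SimulationParams(),
                                np.random.default_rng(s)).n_resampled
                  for s in range(20)]
        assert max(counts) > 0
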