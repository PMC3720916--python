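import numpy as np
import pytest

from colonykit._kernels import PROLIF, RCD
from colonykit.branching import P1Schedule, pmf_constant
from colonykit.errors import DomainError
from colonykit.lattice import (
    LatticeConfig,
    LatticeState,
    run_batch,
    simulate_colony,
    simulate_growth_curve,
    step,
)

ZERO = P1Schedule.constant(0.0, 16)


class TestConfig:
    def test_defaults_give_sixteen_steps(self):
        assert LatticeConfig().n_steps == 16

    @pytest.mark.parametrize("kwargs", [
        {"grid_side": 200},              # even: no center site
        {"p_move": 1.5},
        {"horizon_hours": 400.0},        # exceeds (g_max + 1) doublings
        {"g_max": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(DomainError):
            LatticeConfig(**kwargs)


class TestStep:
    def test_forced_division_yields_two_generation_one_cells(self, rng):
        state = LatticeState.single(11)
        step(state, ZERO, rng, p_move=0.0)
        assert state.n_cells == 2
        assert sorted(state.generations()) == [1, 1]
        assert state.n_proliferative == 2

    def test_certain_death_flips_status_permanently(self, rng):
        state = LatticeState.single(11)
        sched = P1Schedule.constant(1.0, 16)
        step(state, sched, rng, p_move=0.0)
        assert state.n_cells == 1 and state.n_rcd == 1
        step(state, sched, rng, p_move=0.0)  # RCD is absorbing
        assert state.n_rcd == 1

    def test_contact_inhibition_defers_fate(self, rng):
        state = LatticeState.empty(5)
        for x in range(1, 4):
            for y in range(1, 4):
                state.add_cell(x, y, status=RCD if (x, y) != (2, 2) else PROLIF)
        before = state.status.copy()
        step(state, P1Schedule.constant(1.0, 16), rng, p_move=0.0)
        # the center cell is fully surrounded: no fate drawn even at P1=1
        assert state.status[2, 2] == PROLIF
        np.testing.assert_array_equal(state.status, before)

    def test_generation_beyond_schedule_rejected(self, rng):
        state = LatticeState.empty(5)
        state.add_cell(2, 2, gen=4)
        with pytest.raises(DomainError):
            step(state, P1Schedule.constant(0.5, 3), rng)

    def test_cell_count_never_decreases_and_occupancy_unique(self, rng):
        state = LatticeState.single(41)
        sched = P1Schedule.constant(0.3, 16)
        prev = 1
        for _ in range(10):
            step(state, sched, rng, p_move=0.25)
            assert state.n_cells >= prev
            prev = state.n_cells
            coords = set(zip(state.xs[:state.n_cells].tolist(),
                             state.ys[:state.n_cells].tolist()))
            assert len(coords) == state.n_cells
            assert np.count_nonzero(state.status) == state.n_cells

    def test_colony_connected_without_movement(self, rng):
        state = LatticeState.single(41)
        sched = P1Schedule.constant(0.2, 16)
        for _ in range(8):
            step(state, sched, rng, p_move=0.0)
        coords = set(zip(state.xs[:state.n_cells].tolist(),
                         state.ys[:state.n_cells].tolist()))
        seen = {next(iter(coords))}
        frontier = list(seen)
        while frontier:
            x, y = frontier.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    nb = (x + dx, y + dy)
                    if nb in coords and nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
        assert seen == coords


class TestSimulateColony:
    def test_unconstrained_doubling(self):
        cfg = LatticeConfig(g_max=2, horizon_hours=40.0, seed=0)
        out = simulate_colony(P1Schedule.constant(0.0, 2), cfg)
        assert out.size == 4 and out.n_proliferative == 4

    def test_certain_death_single_cell(self):
        out = simulate_colony(P1Schedule.constant(1.0, 16), LatticeConfig(seed=0))
        assert out.size == 1 and out.n_rcd == 1


class TestRunBatch:
    def test_shapes_and_bit_exact_reproducibility(self, half_schedule):
        cfg = LatticeConfig()
        a = run_batch(half_schedule, cfg, n_inocula=100, n_sets=2, seed=5)
        b = run_batch(half_schedule, cfg, n_inocula=100, n_sets=2, seed=5)
        assert a.final_sizes.size == 200
        np.testing.assert_array_equal(a.final_sizes, b.final_sizes)
        np.testing.assert_array_equal(a.colony_seeds, b.colony_seeds)
        assert not np.array_equal(
            a.final_sizes,
            run_batch(half_schedule, cfg, n_inocula=100, n_sets=2, seed=6).final_sizes)

    def test_all_dying_schedule_gives_unit_sizes(self):
        res = run_batch(P1Schedule.constant(1.0, 16), LatticeConfig(),
                        n_inocula=50, n_sets=1, seed=0)
        assert np.all(res.final_sizes == 1)
        assert res.clonogenic_counts().sum() == 0

    def test_small_colony_sizes_match_analytic_pmf(self, half_schedule):
        # contact inhibition cannot bind below 9 cells, so sizes 1..6 follow
        # the branching pmf exactly; 3 binomial SEs at n=4000
        res = run_batch(half_schedule, LatticeConfig(), n_inocula=4000,
                        n_sets=1, seed=3)
        ana = pmf_constant(0.5, 6)
        for n in range(1, 7):
            emp = np.mean(res.final_sizes == n)
            se = np.sqrt(ana[n - 1] * (1 - ana[n - 1]) / 4000)
            assert abs(emp - ana[n - 1]) < 3 * se

    def test_uniform_p1_increase_does_not_grow_colonies(self):
        cfg = LatticeConfig()
        base = np.full(17, 0.35)
        lo = run_batch(P1Schedule(base), cfg, n_inocula=1000, n_sets=1, seed=9)
        hi = run_batch(P1Schedule(np.clip(base + 0.1, 0, 1)), cfg,
                       n_inocula=1000, n_sets=1, seed=9)
        assert hi.final_sizes.mean() <= lo.final_sizes.mean()


class TestGrowthCurve:
    def test_confluent_start_is_flat(self):
        series = simulate_growth_curve(LatticeConfig(grid_side=21, seed=0),
                                       1.0, days=5)
        assert series.nunique() == 1

    def test_doubles_early_then_saturates(self):
        cfg = LatticeConfig(grid_side=51, seed=4, p_move=0.25)
        series = simulate_growth_curve(cfg, 0.02, days=11)
        # day-to-day growth never exceeds the doubling budget between samples
        steps = np.minimum(np.round(np.arange(12) * 24 / 20).astype(int), 16)
        max_ratio = 2.0 ** np.diff(steps)
        ratio = series.values[1:] / series.values[:-1]
        assert np.all(ratio <= max_ratio + 1e-9)
        # saturation: by day 11 the lattice is nearly full and growth stalls
        assert series.iloc[-1] <= 51 * 51
        assert series.iloc[-1] / series.iloc[-2] < 1.05
        assert series.iloc[-1] > 0.9 * 51 * 51

    def test_density_above_one_rejected(self):
        with pytest.raises(DomainError):
            simulate_growth_curve(LatticeConfig(), 1.2, days=2)
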