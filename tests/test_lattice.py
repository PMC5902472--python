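"""Unit and property tests for the stochastic lattice simulator."""

import numpy as np
import pytest
from scipy import stats

from dlgrowth import lattice
from dlgrowth.lattice import LatticeConfig, initialize, run_until_density, step


class TestInitialize:
    def test_uniform_single_packet_count_and_seed(self):
        cfg = LatticeConfig(L_x=200, L_y=200, c0=1.0, scenario="uniform_single")
        state = initialize(cfg)
        assert state.free_packets == 40_000
        assert state.nu == 1
        assert state.cells[99, 99]  # 1-based centre (100, 100)
        assert state.nutrient.sum() == 40_000

    def test_two_seed_positions_quarter_width_apart(self):
        cfg = LatticeConfig(L_x=200, L_y=200, scenario="uniform_two_seeds")
        assert cfg.seed_positions() == [(75, 100), (125, 100)]
        state = initialize(cfg)
        assert state.nu == 2
        assert state.cells[74, 99] and state.cells[124, 99]

    def test_nutrient_column_confined_to_rightmost_column(self):
        cfg = LatticeConfig(L_x=50, L_y=40, c0=2.0, scenario="nutrient_column")
        state = initialize(cfg)
        grid = state.nutrient
        assert grid.sum() == round(2.0 * 50 * 40)
        assert grid[:-1, :].sum() == 0  # everything in column x = L_x

    def test_zero_concentration_gives_empty_field(self):
        state = initialize(LatticeConfig(L_x=20, L_y=20, c0=0.0))
        assert state.free_packets == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(L_x=0, L_y=5),
            dict(L_x=5, L_y=5, c0=-1.0),
            dict(L_x=5, L_y=5, s=0),
            dict(L_x=5, L_y=5, p_m=1.5),
            dict(L_x=5, L_y=5, stop_density=0.0),
            dict(L_x=5, L_y=5, scenario="bogus"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LatticeConfig(**kwargs)

    def test_two_seed_scenario_rejects_narrow_lattice(self):
        cfg = LatticeConfig(L_x=4, L_y=9, scenario="uniform_two_seeds")
        with pytest.raises(ValueError):
            cfg.seed_positions()


class TestStep:
    def test_no_cells_conserves_packets_and_grows_nothing(self):
        cfg = LatticeConfig(L_x=30, L_y=30, c0=1.0, rng_seed=3)
        state = initialize(cfg)
        state._cells[:] = 0  # remove the seed: nothing can absorb or divide
        state._nu = 0
        new = step(state, cfg)
        assert new.nu == 0
        assert new.free_packets == state.free_packets

    def test_packet_moves_uniform_over_cardinal_directions(self):
        # 10^4 packets on one interior site move independently; with p_m = 1
        # and s = 1 the destination counts must be uniform over the four
        # cardinal neighbours (chi-square test).
        cfg = LatticeConfig(L_x=5, L_y=5, c0=0.0, p_m=1.0, s=1, rng_seed=9)
        state = initialize(cfg)
        n = 10_000
        state._packx = np.full(n, 2, dtype=np.int32)
        state._packy = np.full(n, 2, dtype=np.int32)
        state._n_pack = n
        state._cells[:] = 0
        state._nu = 0
        new = step(state, cfg)
        grid = new.nutrient
        counts = [grid[3, 2], grid[1, 2], grid[2, 3], grid[2, 1]]
        assert sum(counts) == n
        assert stats.chisquare(counts).pvalue > 1e-4

    def test_fully_surrounded_cell_never_reproduces(self):
        cfg = LatticeConfig(L_x=3, L_y=3, c0=0.0, rng_seed=1)
        state = initialize(cfg)
        state._cells[:] = 0
        # plus-shaped colony: centre fully enclosed, all with full stores,
        # but the arms sit on the walls with no vacant cardinal neighbour
        coords = [(1, 1), (0, 1), (2, 1), (1, 0), (1, 2)]
        for i, (x, y) in enumerate(coords):
            state._cells[x, y] = 1
            state._cellx[i], state._celly[i] = x, y
            state._stores[x, y] = 4
        state._nu = len(coords)
        corner_free = {(0, 0), (2, 0), (0, 2), (2, 2)}
        new = step(state, cfg)
        grown = set(zip(*np.nonzero(new._cells))) - set(coords)
        assert grown <= corner_free
        # centre cell specifically cannot have reproduced into a corner
        # (corners are not its cardinal neighbours), so its store can only
        # be spent if an arm grew -- arms are the only eligible parents
        assert new._stores[1, 1] == 4

    def test_reflecting_walls_keep_packets_inside(self):
        cfg = LatticeConfig(L_x=4, L_y=4, c0=3.0, p_m=1.0, s=7, rng_seed=2)
        state = initialize(cfg)
        for _ in range(10):
            state = step(state, cfg)
        assert state._packx[: state._n_pack].min() >= 0
        assert state._packx[: state._n_pack].max() < 4
        assert state._packy[: state._n_pack].min() >= 0
        assert state._packy[: state._n_pack].max() < 4


class TestRunUntilDensity:
    def test_reaches_requested_density(self, small_run):
        res = small_run
        assert res.terminator == "density"
        assert res.state.nu >= 0.2 * 60 * 60
        res.check_conservation()

    def test_stop_density_below_initial_returns_immediately(self):
        cfg = LatticeConfig(L_x=10, L_y=10, stop_density=0.01, rng_seed=0)
        res = run_until_density(cfg)
        assert res.state.t_step == 0
        assert res.terminator == "density"

    def test_zero_nutrient_flagged_as_exhausted(self):
        cfg = LatticeConfig(L_x=20, L_y=20, c0=0.0, stop_density=0.5, rng_seed=0)
        res = run_until_density(cfg)
        assert res.terminator == "exhausted"
        assert res.state.nu == 1

    def test_max_steps_flagged_as_non_convergence(self):
        cfg = LatticeConfig(
            L_x=40, L_y=40, c0=1.0, stop_density=0.9, max_steps=5, rng_seed=0
        )
        res = run_until_density(cfg)
        assert res.terminator == "max_steps"
        assert res.state.t_step == 5

    def test_new_cells_bounded_by_total_packets(self):
        cfg = LatticeConfig(L_x=40, L_y=40, c0=0.05, stop_density=1.0,
                            max_steps=20_000, rng_seed=4)
        res = run_until_density(cfg)
        assert res.state.nu - res.nu_initial <= res.packets_initial

    def test_nu_monotone_and_conservation_along_trajectory(self, small_run):
        traj = small_run.trajectory
        assert (np.diff(traj[:, 1]) >= 0).all()
        assert traj[-1, 1] == small_run.state.nu

    def test_identical_seed_bit_identical_result(self):
        cfg = LatticeConfig(L_x=50, L_y=50, stop_density=0.15, rng_seed=77)
        a = run_until_density(cfg)
        b = run_until_density(cfg)
        assert np.array_equal(a.trajectory, b.trajectory)
        assert np.array_equal(a.state.cells, b.state.cells)
        assert np.array_equal(a.state.nutrient, b.state.nutrient)

    def test_stepwise_equals_single_invocation(self):
        # the counter-based stream makes chunked advancement exact
        cfg = LatticeConfig(L_x=30, L_y=30, stop_density=0.9, max_steps=25,
                            rng_seed=13)
        res = run_until_density(cfg)
        state = initialize(cfg)
        for _ in range(25):
            state = step(state, cfg)
        assert np.array_equal(state.cells, res.state.cells)
        assert np.array_equal(state.stores, res.state.stores)
        assert np.array_equal(state.nutrient, res.state.nutrient)

    def test_conservation_with_nonunit_cost(self):
        cfg = LatticeConfig(L_x=40, L_y=40, c0=2.0, reproduction_cost=2,
                            stop_density=0.3, rng_seed=8)
        res = run_until_density(cfg)
        res.check_conservation()  # free + stored + 2*(nu - nu0) == initial
        assert res.terminator == "density"
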