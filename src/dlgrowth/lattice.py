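"""Stochastic lattice model of a microbial colony feeding on a diffusing nutrient.

Cells occupy lattice sites (at most one cell per site) and absorb discrete
nutrient packets that perform random walks on the same lattice.  A cell holding
at least one stored packet may place a daughter in a vacant cardinal neighbour.
The three classic seeding scenarios that diagnose diffusion-limited growth are
supported:

* ``uniform_single`` -- one central seed in a uniformly seeded nutrient field
  (branch screening),
* ``uniform_two_seeds`` -- two seeds a quarter of the domain width apart
  (colony repulsion),
* ``nutrient_column`` -- one central seed with all nutrient initially in the
  rightmost column (directed growth).

Each time step applies three sub-phases in a fixed order: packet moves (each
free packet makes ``s`` unit moves with probability ``p_m``, moves into the
solid walls are blocked), absorption (a packet co-located with a cell whose
store is below ``storage_cap`` is absorbed with probability ``p_a``), and
reproduction (each cell with a sufficient store and a vacant cardinal
neighbour places a daughter with probability ``p_r``; cells are processed in
uniformly random order so later reproductions see earlier daughters).
Reproduction consumes ``reproduction_cost`` stored packets and daughters start
with an empty store, so total nutrient is conserved as
``free + stored + reproduction_cost * (nu - nu_initial)``.

Coordinates are 1-based ``(column, row)`` with the origin at the bottom-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels

SCENARIOS = ("uniform_single", "uniform_two_seeds", "nutrient_column")

#: human-readable terminator names, indexed by kernel code
TERMINATORS = {
    _kernels.TERM_DENSITY: "density",
    _kernels.TERM_MAX_STEPS: "max_steps",
    _kernels.TERM_EXHAUSTED: "exhausted",
}


@dataclass(frozen=True)
class LatticeConfig:
    """Parameters of a lattice simulation.

    ``s`` is the number of unit moves a nutrient packet makes per time step,
    ``c0`` the mean initial number of packets per site.  Defaults follow the
    standard rule set: ``p_m = 0.8``, ``p_r = 0.5``, certain absorption, a
    storage cap of 4 packets per cell and one packet consumed per daughter.
    """

    L_x: int
    L_y: int
    s: int = 3
    c0: float = 1.0
    p_m: float = 0.8
    p_r: float = 0.5
    p_a: float = 1.0
    storage_cap: int = 4
    reproduction_cost: int = 1
    scenario: str = "uniform_single"
    stop_density: float = 0.2
    max_steps: int = 1_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.L_x < 1 or self.L_y < 1:
            raise ValueError("lattice dimensions must be >= 1")
        for name in ("p_m", "p_r", "p_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if not 0.0 < self.stop_density <= 1.0:
            raise ValueError("stop_density must lie in (0, 1]")
        if self.storage_cap < 1 or self.reproduction_cost < 1:
            raise ValueError("storage_cap and reproduction_cost must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def n_sites(self) -> int:
        return self.L_x * self.L_y

    @property
    def total_packets(self) -> int:
        return int(round(self.c0 * self.n_sites))

    def seed_positions(self) -> list[tuple[int, int]]:
        """1-based seed cell positions for this scenario."""
        cx = -(-self.L_x // 2)  # ceil(L/2)
        cy = -(-self.L_y // 2)
        if self.scenario == "uniform_two_seeds":
            off = int(round(self.L_x / 8))
            left, right = cx - off, cx + off
            if left < 1 or right > self.L_x or left == right:
                raise ValueError(
                    "lattice too narrow for the two-seed scenario (L_x < 8)"
                )
            return [(left, cy), (right, cy)]
        return [(cx, cy)]


class LatticeState:
    """Mutable simulation state: occupancy, per-cell stores and free packets.

    ``cells`` is a boolean occupancy grid, ``stores`` the per-cell packet
    store (zero off the colony) and ``nutrient`` the grid of free packet
    counts; all are indexed ``[x-1, y-1]``.
    """

    def __init__(self, cells, stores, packx, packy, n_pack, cellx, celly, nu, t_step):
        self._cells = cells
        self._stores = stores
        self._packx = packx
        self._packy = packy
        self._n_pack = n_pack
        self._cellx = cellx
        self._celly = celly
        self._nu = nu
        self.t_step = t_step

    @property
    def cells(self) -> np.ndarray:
        return self._cells.astype(bool)

    @property
    def stores(self) -> np.ndarray:
        return self._stores.astype(np.int64)

    @property
    def nutrient(self) -> np.ndarray:
        Lx, Ly = self._cells.shape
        grid = np.zeros((Lx, Ly), dtype=np.int64)
        np.add.at(grid, (self._packx[: self._n_pack], self._packy[: self._n_pack]), 1)
        return grid

    @property
    def nu(self) -> int:
        return int(self._nu)

    @property
    def free_packets(self) -> int:
        return int(self._n_pack)

    @property
    def stored_packets(self) -> int:
        return int(self._stores.sum())

    @property
    def density(self) -> float:
        Lx, Ly = self._cells.shape
        return self._nu / (Lx * Ly)

    def cell_positions(self) -> np.ndarray:
        """1-based (x, y) coordinates of all cells, shape (nu, 2)."""
        out = np.empty((self._nu, 2), dtype=np.int64)
        out[:, 0] = self._cellx[: self._nu] + 1
        out[:, 1] = self._celly[: self._nu] + 1
        return out

    def copy(self) -> "LatticeState":
        return LatticeState(
            self._cells.copy(),
            self._stores.copy(),
            self._packx.copy(),
            self._packy.copy(),
            self._n_pack,
            self._cellx.copy(),
            self._celly.copy(),
            self._nu,
            self.t_step,
        )


@dataclass
class SimulationResult:
    """Outcome of :func:`run_until_density`."""

    state: LatticeState
    trajectory: np.ndarray  # columns (t_step, nu, free_packets)
    seeds: list[tuple[int, int]]
    config: LatticeConfig
    terminator: str
    nu_initial: int
    packets_initial: int

    @property
    def converged(self) -> bool:
        return self.terminator == "density"

    @property
    def area_series(self) -> np.ndarray:
        """(t_step, area) in lattice units; one occupied site = unit area."""
        return self.trajectory[:, :2].astype(float)

    def check_conservation(self) -> None:
        """Raise if nutrient bookkeeping has been violated."""
        cost = self.config.reproduction_cost
        total = (
            self.state.free_packets
            + self.state.stored_packets
            + cost * (self.state.nu - self.nu_initial)
        )
        if total != self.packets_initial:
            raise AssertionError(
                f"nutrient not conserved: {total} != {self.packets_initial}"
            )


def initialize(config: LatticeConfig) -> LatticeState:
    """Seed cells per the scenario and scatter nutrient packets at random.

    ``round(c0 * L_x * L_y)`` packets are placed uniformly at random over all
    sites (or over the rightmost column only for ``nutrient_column``).
    """
    Lx, Ly = config.L_x, config.L_y
    rng = np.random.default_rng(config.rng_seed)

    cells = np.zeros((Lx, Ly), dtype=np.uint8)
    stores = np.zeros((Lx, Ly), dtype=np.int16)
    cap = Lx * Ly
    cellx = np.zeros(cap, dtype=np.int32)
    celly = np.zeros(cap, dtype=np.int32)
    seeds = config.seed_positions()
    for i, (sx, sy) in enumerate(seeds):
        cells[sx - 1, sy - 1] = 1
        cellx[i] = sx - 1
        celly[i] = sy - 1

    total = config.total_packets
    if config.scenario == "nutrient_column":
        packx = np.full(total, Lx - 1, dtype=np.int32)
        packy = rng.integers(0, Ly, size=total).astype(np.int32)
    else:
        site = rng.integers(0, Lx * Ly, size=total)
        packx = (site // Ly).astype(np.int32)
        packy = (site % Ly).astype(np.int32)

    return LatticeState(cells, stores, packx, packy, total, cellx, celly, len(seeds), 0)


def step(state: LatticeState, config: LatticeConfig) -> LatticeState:
    """Apply one time step (move, absorb, reproduce) and return the new state.

    The random stream is keyed on ``(config.rng_seed, t_step)``, so stepping a
    state one step at a time reproduces :func:`run_until_density` exactly.
    """
    new = state.copy()
    order_buf = np.empty(new._cellx.shape[0], dtype=np.int32)
    traj = np.empty(1, dtype=np.int64)
    n_pack, nu, t, _, _ = _kernels.advance(
        new._cells,
        new._stores,
        new._packx,
        new._packy,
        new._n_pack,
        new._cellx,
        new._celly,
        new._nu,
        new.t_step,
        1,
        config.rng_seed,
        config.s,
        config.p_m,
        config.p_r,
        config.p_a,
        config.storage_cap,
        config.reproduction_cost,
        np.iinfo(np.int64).max,
        order_buf,
        traj.copy(),
        traj.copy(),
        traj.copy(),
    )
    new._n_pack, new._nu, new.t_step = n_pack, nu, t
    return new


def run_until_density(config: LatticeConfig) -> SimulationResult:
    """Run until the cell density reaches ``stop_density``.

    Terminates with terminator ``"density"`` on success, ``"max_steps"`` when
    the step cap is hit first, or ``"exhausted"`` when growth has become
    impossible (no free packets and no cell holding enough store to divide).
    A fixed ``rng_seed`` gives a bit-identical trajectory.
    """
    state = initialize(config)
    nu0 = state.nu
    packets0 = state.free_packets
    stop_nu = int(np.ceil(config.stop_density * config.n_sites))

    order_buf = np.empty(state._cellx.shape[0], dtype=np.int32)
    traj_t = np.empty(config.max_steps, dtype=np.int64)
    traj_nu = np.empty(config.max_steps, dtype=np.int64)
    traj_free = np.empty(config.max_steps, dtype=np.int64)

    n_pack, nu, t, term, n_rec = _kernels.advance(
        state._cells,
        state._stores,
        state._packx,
        state._packy,
        state._n_pack,
        state._cellx,
        state._celly,
        state._nu,
        state.t_step,
        config.max_steps,
        config.rng_seed,
        config.s,
        config.p_m,
        config.p_r,
        config.p_a,
        config.storage_cap,
        config.reproduction_cost,
        stop_nu,
        order_buf,
        traj_t,
        traj_nu,
        traj_free,
    )
    state._n_pack, state._nu, state.t_step = n_pack, nu, t

    trajectory = np.empty((n_rec + 1, 3), dtype=np.int64)
    trajectory[0] = (0, nu0, packets0)
    trajectory[1:, 0] = traj_t[:n_rec]
    trajectory[1:, 1] = traj_nu[:n_rec]
    trajectory[1:, 2] = traj_free[:n_rec]

    result = SimulationResult(
        state=state,
        trajectory=trajectory,
        seeds=config.seed_positions(),
        config=config,
        terminator=TERMINATORS[term],
        nu_initial=nu0,
        packets_initial=packets0,
    )
    result.check_conservation()
    return result


def with_seed(config: LatticeConfig, seed: int) -> LatticeConfig:
    """Copy of ``config`` with a different RNG seed."""
    return replace(config, rng_seed=int(seed))
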