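"""Two-dimensional on-lattice Monte Carlo simulation of colony expansion.

Each lattice site holds at most one cell on a square grid with 31.6 µm
pitch (a cell footprint of 1,000 µm², matching a flat fibroblast
monolayer).  Time advances in doubling-time steps of 20 h; at each step a
proliferative cell of generation ``g`` with at least one free site among
its 8 neighbors either undergoes RCD with probability ``P1(g)`` or divides,
while fully surrounded cells are contact-inhibited and draw no fate.  A
13-day assay window corresponds to 16 steps (at most 16 divisions).

The heavy per-colony loops live in :mod:`colonykit._kernels` (numba);
this module provides the configuration/state/result types, a stepwise API
for inspection and testing, and batch drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import EMPTY, PROLIF, RCD
from .branching import P1Schedule
from .errors import DomainError

__all__ = [
    "LatticeConfig",
    "LatticeState",
    "ColonyOutcome",
    "SimulationResult",
    "step",
    "simulate_colony",
    "run_batch",
    "simulate_growth_curve",
]

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


@dataclass(frozen=True)
class LatticeConfig:
    """Simulator configuration.

    pitch_um
        Site spacing in µm (31.6 µm ~ 1,000 µm² cell area); bookkeeping
        only, the dynamics are scale-free.
    grid_side
        Sites per grid edge; must be odd so a single inoculum sits at the
        exact center.
    g_max
        Division horizon; cells of generation g_max no longer divide.
    dt_hours / horizon_hours
        One step per doubling time (20 h); a 312 h (13 day) window gives
        ceil(15.6) = 16 steps, capped at g_max.
    p_move
        Per-step probability that a cell with a free neighbor relocates to
        one (applied after the fate phase).
    blocked_can_die
        If true, contact-inhibited cells may still draw the RCD fate.
    """

    pitch_um: float = 31.6
    grid_side: int = 201
    g_max: int = 16
    dt_hours: float = 20.0
    horizon_hours: float = 312.0
    p_move: float = 0.25
    blocked_can_die: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.grid_side < 3 or self.grid_side % 2 == 0:
            raise DomainError("grid_side must be an odd integer >= 3")
        if not 0.0 <= self.p_move <= 1.0:
            raise DomainError("p_move must lie in [0, 1]")
        if self.g_max < 1:
            raise DomainError("g_max must be >= 1")
        if self.dt_hours <= 0 or self.horizon_hours <= 0:
            raise DomainError("dt_hours and horizon_hours must be positive")
        if self.horizon_hours / self.dt_hours > self.g_max + 1:
            raise DomainError("horizon/dt must not exceed g_max + 1")

    @property
    def n_steps(self) -> int:
        return min(math.ceil(self.horizon_hours / self.dt_hours), self.g_max)


@dataclass
class LatticeState:
    """Mutable occupancy state: status/generation grids plus a cell list."""

    status: np.ndarray
    gen: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    n_cells: int
    step_count: int = 0

    @classmethod
    def empty(cls, side: int) -> "LatticeState":
        cap = side * side
        return cls(status=np.zeros((side, side), np.int8),
                   gen=np.zeros((side, side), np.int16),
                   xs=np.empty(cap, np.int64), ys=np.empty(cap, np.int64),
                   n_cells=0)

    @classmethod
    def single(cls, side: int) -> "LatticeState":
        state = cls.empty(side)
        c = side // 2
        state.add_cell(c, c)
        return state

    def add_cell(self, x: int, y: int, status: int = PROLIF, gen: int = 0):
        if self.status[x, y] != EMPTY:
            raise DomainError(f"site ({x}, {y}) already occupied")
        self.status[x, y] = status
        self.gen[x, y] = gen
        self.xs[self.n_cells] = x
        self.ys[self.n_cells] = y
        self.n_cells += 1

    @property
    def n_proliferative(self) -> int:
        return int(np.count_nonzero(self.status == PROLIF))

    @property
    def n_rcd(self) -> int:
        return int(np.count_nonzero(self.status == RCD))

    def generations(self) -> np.ndarray:
        idx = (self.xs[: self.n_cells], self.ys[: self.n_cells])
        return np.asarray(self.gen[idx])


@dataclass(frozen=True)
class ColonyOutcome:
    size: int
    n_proliferative: int
    n_rcd: int
    boundary_contact: bool


@dataclass
class SimulationResult:
    """Final colony sizes of a batch of independent single-cell inocula."""

    final_sizes: np.ndarray
    n_proliferative: np.ndarray
    n_rcd: np.ndarray
    boundary: np.ndarray
    set_ids: np.ndarray
    colony_seeds: np.ndarray
    set_seeds: np.ndarray
    n_inocula: int
    n_sets: int
    schedule: P1Schedule
    config: LatticeConfig
    master_seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "set_id": self.set_ids,
            "seed": self.colony_seeds,
            "final_size": self.final_sizes,
            "n_proliferative": self.n_proliferative,
            "n_rcd": self.n_rcd,
            "boundary_flag": self.boundary.astype(int),
        })

    def clonogenic_counts(self, threshold: int = 50) -> np.ndarray:
        """Clonogenic (>= threshold cells) colony count per simulation set."""
        out = np.zeros(self.n_sets, dtype=int)
        clono = self.final_sizes >= threshold
        for s in range(self.n_sets):
            out[s] = int(np.count_nonzero(clono & (self.set_ids == s)))
        return out


def _check_schedule(state: LatticeState, schedule: P1Schedule):
    if state.n_cells and int(state.generations().max()) > schedule.g_max:
        raise DomainError("a cell's generation exceeds the schedule horizon")


def step(state: LatticeState, schedule: P1Schedule, rng: np.random.Generator,
         p_move: float = 0.25, blocked_can_die: bool = False) -> LatticeState:
    """Advance the state by one doubling-time step, in place.

    The fate phase visits cells in uniformly random order; see
    :func:`colonykit._kernels.step_kernel` for the exact update rule.
    """
    _check_schedule(state, schedule)
    _kernels.seed_kernel(int(rng.integers(_SEED_MASK)))
    state.n_cells = int(_kernels.step_kernel(
        state.status, state.gen, state.xs, state.ys, state.n_cells,
        schedule.probs, schedule.g_max, float(p_move), bool(blocked_can_die)))
    state.step_count += 1
    return state


def _working_side(config: LatticeConfig) -> int:
    # a colony grown from the center for n_steps has Chebyshev radius
    # <= n_steps (division) + n_steps (movement); clip the working grid
    # accordingly -- the boundary of the configured grid is unreachable
    # whenever the working grid is smaller, so the flag semantics survive.
    reach = 2 * config.n_steps + 3
    return min(config.grid_side, 2 * reach + 1)


def simulate_colony(schedule: P1Schedule, config: LatticeConfig,
                    rng: np.random.Generator | int | None = None) -> ColonyOutcome:
    """Grow one colony from a single cell at the grid center."""
    if schedule.g_max < config.g_max:
        raise DomainError("schedule must cover generations up to config.g_max")
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    seed = int(rng.integers(_SEED_MASK))
    size, n_prolif, n_rcd, boundary = _run_one(seed, schedule, config)
    return ColonyOutcome(int(size), int(n_prolif), int(n_rcd), bool(boundary))


def _run_one(seed: int, schedule: P1Schedule, config: LatticeConfig):
    _kernels.seed_kernel(seed)
    return _kernels.run_colony_kernel(
        _working_side(config), config.n_steps, schedule.probs, config.g_max,
        config.p_move, config.blocked_can_die)


def run_batch(schedule: P1Schedule, config: LatticeConfig,
              n_inocula: int = 10_000, n_sets: int = 5,
              seed: int | None = None) -> SimulationResult:
    """Simulate ``n_sets`` independent sets of ``n_inocula`` single cells.

    All randomness derives from one master seed (argument, falling back to
    ``config.seed``); per-colony seeds are spawned via
    :class:`numpy.random.SeedSequence`, so results are bit-reproducible and
    independent of execution order.
    """
    if n_inocula < 1 or n_sets < 1:
        raise DomainError("n_inocula and n_sets must be >= 1")
    if schedule.g_max < config.g_max:
        raise DomainError("schedule must cover generations up to config.g_max")
    master = seed if seed is not None else config.seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(n_sets)
    total = n_inocula * n_sets
    sizes = np.empty(total, np.int64)
    prolif = np.empty(total, np.int64)
    rcd = np.empty(total, np.int64)
    flags = np.empty(total, np.bool_)
    set_ids = np.repeat(np.arange(n_sets), n_inocula)
    colony_seeds = np.empty(total, np.int64)
    set_seeds = np.empty(n_sets, np.int64)
    side = _working_side(config)
    for s, child in enumerate(children):
        seeds = (child.generate_state(n_inocula, np.uint32).astype(np.int64)
                 & _SEED_MASK)
        set_seeds[s] = seeds[0]
        sl = slice(s * n_inocula, (s + 1) * n_inocula)
        colony_seeds[sl] = seeds
        _kernels.run_set_kernel(seeds, side, config.n_steps, schedule.probs,
                                config.g_max, config.p_move,
                                config.blocked_can_die, sizes[sl], prolif[sl],
                                rcd[sl], flags[sl])
    return SimulationResult(
        final_sizes=sizes, n_proliferative=prolif, n_rcd=rcd, boundary=flags,
        set_ids=set_ids, colony_seeds=colony_seeds, set_seeds=set_seeds,
        n_inocula=n_inocula, n_sets=n_sets, schedule=schedule, config=config,
        master_seed=master)


def simulate_growth_curve(config: LatticeConfig, initial_density: float,
                          days: int, schedule: P1Schedule | None = None,
                          seed: int | None = None) -> pd.Series:
    """Daily total cell counts for a random uniform inoculation at a density.

    Cells are seeded Bernoulli(``initial_density``) per site; with no RCD
    (the default all-zero schedule) growth doubles early and saturates as
    contact inhibition exhausts free sites.  The day-``d`` value is the
    count after ``round(24 d / dt)`` steps (capped at the step horizon).
    """
    if not 0.0 <= initial_density <= 1.0:
        raise DomainError("initial_density must lie in [0, 1]")
    if days < 0:
        raise DomainError("days must be >= 0")
    if schedule is None:
        schedule = P1Schedule(np.zeros(config.g_max + 1))
    n_steps = min(int(math.ceil(days * 24.0 / config.dt_hours)), config.g_max)
    master = seed if seed is not None else (config.seed or 0)
    counts = _kernels.run_growth_kernel(
        int(master) & _SEED_MASK, config.grid_side, n_steps, schedule.probs,
        config.g_max, config.p_move, config.blocked_can_die,
        float(initial_density))
    day_idx = np.arange(days + 1)
    step_idx = np.minimum(np.round(day_idx * 24.0 / config.dt_hours).astype(int),
                          n_steps)
    return pd.Series(counts[step_idx], index=day_idx, name="cells")
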