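"""Numba kernels for the lattice colony simulator.

State layout shared by all kernels: two square grids (``status`` int8 with
0 = empty, 1 = proliferative, 2 = RCD; ``gen`` int16 generation counters)
plus flat coordinate arrays ``xs``/``ys`` listing occupied sites and a live
cell count.  All randomness goes through numba's global per-thread RNG,
reseeded explicitly at every python-visible entry point.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EMPTY = 0
PROLIF = 1
RCD = 2


@njit(cache=True)
def _free_neighbors(status, x, y, out_x, out_y):
    """Collect free sites among the 8 neighbors; off-grid counts as occupied."""
    side = status.shape[0]
    k = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            if dx == 0 and dy == 0:
                continue
            nx = x + dx
            ny = y + dy
            if 0 <= nx < side and 0 <= ny < side and status[nx, ny] == EMPTY:
                out_x[k] = nx
                out_y[k] = ny
                k += 1
    return k


@njit(cache=True)
def step_kernel(status, gen, xs, ys, n_cells, p1, g_max, p_move,
                blocked_can_die):
    """One doubling-time step: fate phase then movement phase.

    Fate phase visits the cells present at step entry in uniformly random
    order; a proliferative cell with at least one free neighbor dies with
    probability p1[g] (permanently) or divides, replacing itself by two
    generation g+1 daughters (one in place, one on a random free neighbor).
    Blocked cells draw no fate unless ``blocked_can_die``.  The movement
    phase then lets every cell with a free neighbor relocate to a random
    free neighbor with probability ``p_move``.  Returns the new cell count.
    """
    nbx = np.empty(8, np.int64)
    nby = np.empty(8, np.int64)
    n0 = n_cells
    order = np.random.permutation(n0)
    for oi in range(n0):
        idx = order[oi]
        x = xs[idx]
        y = ys[idx]
        if status[x, y] != PROLIF:
            continue
        g = gen[x, y]
        if g >= g_max:
            continue  # assay horizon: no further divisions tracked
        k = _free_neighbors(status, x, y, nbx, nby)
        if k == 0:
            if blocked_can_die and np.random.random() < p1[g]:
                status[x, y] = RCD
            continue
        if np.random.random() < p1[g]:
            status[x, y] = RCD
        else:
            j = np.random.randint(0, k)
            nx = nbx[j]
            ny = nby[j]
            status[nx, ny] = PROLIF
            gen[nx, ny] = g + 1
            gen[x, y] = g + 1
            xs[n_cells] = nx
            ys[n_cells] = ny
            n_cells += 1
    if p_move > 0.0:
        order = np.random.permutation(n_cells)
        for oi in range(n_cells):
            idx = order[oi]
            if np.random.random() >= p_move:
                continue
            x = xs[idx]
            y = ys[idx]
            k = _free_neighbors(status, x, y, nbx, nby)
            if k == 0:
                continue
            j = np.random.randint(0, k)
            nx = nbx[j]
            ny = nby[j]
            status[nx, ny] = status[x, y]
            gen[nx, ny] = gen[x, y]
            status[x, y] = EMPTY
            gen[x, y] = 0
            xs[idx] = nx
            ys[idx] = ny
    return n_cells


@njit(cache=True)
def run_colony_kernel(side, n_steps, p1, g_max, p_move, blocked_can_die):
    """Grow one colony from a single center cell; RNG must be seeded upstream.

    Returns (final_size, n_proliferative, n_rcd, boundary_contact).
    """
    status = np.zeros((side, side), np.int8)
    gen = np.zeros((side, side), np.int16)
    cap = side * side
    xs = np.empty(cap, np.int64)
    ys = np.empty(cap, np.int64)
    c = side // 2
    status[c, c] = PROLIF
    xs[0] = c
    ys[0] = c
    n_cells = 1
    for _ in range(n_steps):
        alive = False
        for i in range(n_cells):
            if status[xs[i], ys[i]] == PROLIF and gen[xs[i], ys[i]] < g_max:
                alive = True
                break
        if not alive:
            break
        n_cells = step_kernel(status, gen, xs, ys, n_cells, p1, g_max,
                              p_move, blocked_can_die)
    n_prolif = 0
    n_rcd = 0
    boundary = False
    for i in range(n_cells):
        x = xs[i]
        y = ys[i]
        if status[x, y] == PROLIF:
            n_prolif += 1
        else:
            n_rcd += 1
        if x == 0 or y == 0 or x == side - 1 or y == side - 1:
            boundary = True
    return n_cells, n_prolif, n_rcd, boundary


@njit(cache=True)
def run_set_kernel(seeds, side, n_steps, p1, g_max, p_move, blocked_can_die,
                   sizes, prolif, rcd, flags):
    """One simulation set: independent colonies, one explicit seed each."""
    for i in range(seeds.shape[0]):
        np.random.seed(seeds[i])
        s, npf, nr, b = run_colony_kernel(side, n_steps, p1, g_max, p_move,
                                          blocked_can_die)
        sizes[i] = s
        prolif[i] = npf
        rcd[i] = nr
        flags[i] = b


@njit(cache=True)
def run_growth_kernel(seed, side, n_steps, p1, g_max, p_move,
                      blocked_can_die, density):
    """Confluence test: seed cells Bernoulli(density) per site, track counts.

    Returns the total cell count after each step (index 0 = initial state).
    """
    np.random.seed(seed)
    status = np.zeros((side, side), np.int8)
    gen = np.zeros((side, side), np.int16)
    cap = side * side
    xs = np.empty(cap, np.int64)
    ys = np.empty(cap, np.int64)
    n_cells = 0
    for x in range(side):
        for y in range(side):
            if np.random.random() < density:
                status[x, y] = PROLIF
                xs[n_cells] = x
                ys[n_cells] = y
                n_cells += 1
    counts = np.empty(n_steps + 1, np.int64)
    counts[0] = n_cells
    for s in range(n_steps):
        n_cells = step_kernel(status, gen, xs, ys, n_cells, p1, g_max,
                              p_move, blocked_can_die)
        counts[s + 1] = n_cells
    return counts


@njit(cache=True)
def seed_kernel(seed):
    """Seed numba's internal RNG (distinct from NumPy's python-level state)."""
    np.random.seed(seed)
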