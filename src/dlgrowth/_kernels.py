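"""Numba kernels for the lattice cell-nutrient simulator.

The random number stream is counter-based (splitmix64 keyed on the run seed
and the time-step index), so a trajectory is bit-identical whether the run is
advanced one step at a time or in a single kernel invocation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_GOLD = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_INV53 = 1.1102230246251565e-16  # 2**-53

# terminator codes
TERM_RUNNING = 0
TERM_DENSITY = 1
TERM_MAX_STEPS = 2
TERM_EXHAUSTED = 3


@njit(inline="always", cache=True)
def _mix(z):
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    return z ^ (z >> U64(31))


@njit(inline="always", cache=True)
def _next(st):
    st = st + _GOLD
    return st, _mix(st)


@njit(inline="always", cache=True)
def _uniform(st):
    st, z = _next(st)
    return st, (z >> U64(11)) * _INV53


@njit(inline="always", cache=True)
def _randint(st, n):
    # Lemire multiply-shift; bias is O(n / 2**32), negligible for small n.
    st, z = _next(st)
    return st, int(((z >> U64(32)) * U64(n)) >> U64(32))


@njit(cache=True)
def advance(
    cells,
    stores,
    packx,
    packy,
    n_pack,
    cellx,
    celly,
    nu,
    t0,
    n_steps,
    seed,
    s,
    p_m,
    p_r,
    p_a,
    cap,
    cost,
    stop_nu,
    order_buf,
    traj_t,
    traj_nu,
    traj_free,
):
    """Advance the lattice state by up to ``n_steps`` time steps in place.

    Returns (n_pack, nu, t, terminator, n_recorded).  Trajectory rows are
    appended to the ``traj_*`` buffers starting at index 0.
    """
    Lx, Ly = cells.shape
    t = t0
    n_rec = 0
    term = TERM_RUNNING
    if nu >= stop_nu:
        return n_pack, nu, t, TERM_DENSITY, n_rec

    for _ in range(n_steps):
        # per-step counter-based stream
        st = _mix(U64(seed) ^ (U64(t + 1) * _GOLD))

        # --- phase 1: nutrient packet moves -------------------------------
        for i in range(n_pack):
            st, u = _uniform(st)
            if u < p_m:
                x = packx[i]
                y = packy[i]
                for _k in range(s):
                    st, z = _next(st)
                    d = int(z & U64(3))
                    if d == 0:
                        if x + 1 < Lx:
                            x += 1
                    elif d == 1:
                        if x > 0:
                            x -= 1
                    elif d == 2:
                        if y + 1 < Ly:
                            y += 1
                    else:
                        if y > 0:
                            y -= 1
                packx[i] = x
                packy[i] = y

        # --- phase 2: absorption ------------------------------------------
        i = 0
        while i < n_pack:
            x = packx[i]
            y = packy[i]
            if cells[x, y] != 0 and stores[x, y] < cap:
                take = True
                if p_a < 1.0:
                    st, u = _uniform(st)
                    take = u < p_a
                if take:
                    stores[x, y] += 1
                    n_pack -= 1
                    packx[i] = packx[n_pack]
                    packy[i] = packy[n_pack]
                    continue  # re-examine swapped-in packet
            i += 1

        # --- phase 3: reproduction (cells in uniformly random order) ------
        nu_start = nu
        for j in range(nu_start):
            order_buf[j] = j
        for j in range(nu_start - 1, 0, -1):
            st, k = _randint(st, j + 1)
            tmp = order_buf[j]
            order_buf[j] = order_buf[k]
            order_buf[k] = tmp
        for j in range(nu_start):
            c = order_buf[j]
            x = cellx[c]
            y = celly[c]
            if stores[x, y] < cost:
                continue
            # vacant cardinal neighbours
            nvac = 0
            vx0 = vy0 = vx1 = vy1 = vx2 = vy2 = vx3 = vy3 = -1
            if x + 1 < Lx and cells[x + 1, y] == 0:
                vx0, vy0 = x + 1, y
                nvac += 1
            if x > 0 and cells[x - 1, y] == 0:
                if nvac == 0:
                    vx0, vy0 = x - 1, y
                else:
                    vx1, vy1 = x - 1, y
                nvac += 1
            if y + 1 < Ly and cells[x, y + 1] == 0:
                if nvac == 0:
                    vx0, vy0 = x, y + 1
                elif nvac == 1:
                    vx1, vy1 = x, y + 1
                else:
                    vx2, vy2 = x, y + 1
                nvac += 1
            if y > 0 and cells[x, y - 1] == 0:
                if nvac == 0:
                    vx0, vy0 = x, y - 1
                elif nvac == 1:
                    vx1, vy1 = x, y - 1
                elif nvac == 2:
                    vx2, vy2 = x, y - 1
                else:
                    vx3, vy3 = x, y - 1
                nvac += 1
            if nvac == 0:
                continue
            st, u = _uniform(st)
            if u >= p_r:
                continue
            st, pick = _randint(st, nvac)
            if pick == 0:
                dx, dy = vx0, vy0
            elif pick == 1:
                dx, dy = vx1, vy1
            elif pick == 2:
                dx, dy = vx2, vy2
            else:
                dx, dy = vx3, vy3
            cells[dx, dy] = 1
            stores[x, y] -= cost
            cellx[nu] = dx
            celly[nu] = dy
            nu += 1

        t += 1
        traj_t[n_rec] = t
        traj_nu[n_rec] = nu
        traj_free[n_rec] = n_pack
        n_rec += 1

        if nu >= stop_nu:
            term = TERM_DENSITY
            break
        if n_pack == 0:
            can_grow = False
            for j in range(nu):
                if stores[cellx[j], celly[j]] >= cost:
                    can_grow = True
                    break
            if not can_grow:
                term = TERM_EXHAUSTED
                break

    if term == TERM_RUNNING and t - t0 >= n_steps:
        term = TERM_MAX_STEPS
    return n_pack, nu, t, term, n_rec
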