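"""Numba inner loop of the lattice simulation.

One production time step = one replacement attempt at a uniformly chosen
site, followed by ``c`` mixing swap events.  Kept free of Python objects so
the whole iteration runs in machine code; all randomness flows through
numba's per-kernel NumPy-compatible generator, seeded explicitly for
reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def run_chunk(
    grid,
    counts,
    product,
    influx,
    phi,
    c,
    sigma,
    n_steps,
    t0,
    record_every,
    rec_steps,
    rec_counts,
    first_extinct,
):
    """Advance the lattice by ``n_steps`` production steps in place.

    Records the 15 type counts every ``record_every`` steps into the
    pre-allocated ``rec_steps`` / ``rec_counts`` buffers and returns the
    number of samples written.  ``first_extinct[t]`` is set to the step at
    which type t's count first reached zero (-1 while alive).
    """
    n = grid.shape[0]
    rec_i = 0
    for k in range(n_steps):
        t = t0 + k
        # --- production / influx at one site ---
        i = np.random.randint(n)
        j = np.random.randint(n)
        old = grid[i, j]
        new = 0
        if phi > 0.0 and np.random.random() < phi:
            new = influx[np.random.randint(influx.shape[0])]
        else:
            # opposite neighbour pair and order, each arrangement prob 1/4
            arr = np.random.randint(4)
            if arr == 0:  # north acts first, south second
                first = grid[(i - 1) % n, j]
                second = grid[(i + 1) % n, j]
            elif arr == 1:  # south first, north second
                first = grid[(i + 1) % n, j]
                second = grid[(i - 1) % n, j]
            elif arr == 2:  # west first, east second
                first = grid[i, (j - 1) % n]
                second = grid[i, (j + 1) % n]
            else:  # east first, west second
                first = grid[i, (j + 1) % n]
                second = grid[i, (j - 1) % n]
            new = product[first, second]
        if new != 0:
            grid[i, j] = new
            counts[old] -= 1
            counts[new] += 1
            if counts[old] == 0 and first_extinct[old] < 0:
                first_extinct[old] = t
            if counts[new] == 1:
                first_extinct[new] = -1
        # --- spatial mixing: c swap events ---
        if c > 0 and sigma > 0.0:
            for _ in range(c):
                si = np.random.randint(n)
                sj = np.random.randint(n)
                d = np.random.normal(0.0, sigma)
                # round to nearest site, ties away from zero
                off = int(abs(d) + 0.5)
                if off == 0:
                    continue
                direction = np.random.randint(4)
                if direction == 0:
                    ti, tj = (si - off) % n, sj
                elif direction == 1:
                    ti, tj = (si + off) % n, sj
                elif direction == 2:
                    ti, tj = si, (sj - off) % n
                else:
                    ti, tj = si, (sj + off) % n
                tmp = grid[si, sj]
                grid[si, sj] = grid[ti, tj]
                grid[ti, tj] = tmp
        if record_every > 0 and (t + 1) % record_every == 0:
            rec_steps[rec_i] = t + 1
            for tt in range(16):
                rec_counts[rec_i, tt] = counts[tt]
            rec_i += 1
    return rec_i
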