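"""Stochastic spatial simulation of the composing population.

The population lives on an n x n toroidal lattice, one automaton per site,
at constant size N = n^2.  Each production time step picks one site
uniformly; with probability phi the occupant is replaced by a random influx
draw, otherwise one of the two opposite von-Neumann neighbour pairs
(north/south or east/west) is selected together with an acting order (each
of the four ordered arrangements with probability 1/4) and the functional
composition of the pair replaces the occupant — unless the composition
fails (T0), in which case the occupant survives.  After every production
step, c mixing events swap uniformly chosen occupants over Gaussian
displacements (variance v) along a random cardinal direction.

c -> N, v -> n approximates a well-mixed population; c = v = 0 freezes all
transport, leaving only nearest-neighbour production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _kernels
from .automata import build_composition_table
from .config import Schedule, SimConfig

__all__ = [
    "Lattice",
    "FrequencySeries",
    "SimResult",
    "init_lattice",
    "run",
    "detect_steady_state",
    "count_spatial_clusters",
]


@dataclass
class Lattice:
    """Toroidal grid of automaton type ids (1..15)."""

    grid: np.ndarray  # (n, n) int8

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("lattice grid must be square")
        if ((self.grid < 1) | (self.grid > 15)).any():
            raise ValueError("lattice occupants must be type ids in 1..15 (no T0)")

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    @property
    def population(self) -> int:
        return self.grid.size

    def counts(self) -> np.ndarray:
        """Occupant counts per type id (length 16; index 0 unused)."""
        return np.bincount(self.grid.ravel(), minlength=16).astype(np.int64)

    def frequencies(self) -> np.ndarray:
        """Normalised type frequencies for T1..T15."""
        return self.counts()[1:] / self.population

    def survivors(self) -> frozenset:
        return frozenset(int(t) for t in range(1, 16) if self.counts()[t] > 0)


@dataclass
class FrequencySeries:
    """Sampled type-frequency trajectory; each row lies on the simplex."""

    steps: np.ndarray  # (S,)
    freqs: np.ndarray  # (S, 15)

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (self.steps.size, 15):
            raise ValueError("frequency series must have 15 columns")
        if self.steps.size and np.abs(self.freqs.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("frequency samples must sum to 1")

    def __len__(self) -> int:
        return self.steps.size

    def tail_mean(self, window_steps: int) -> np.ndarray:
        """Mean frequency vector over the trailing window of steps."""
        if not len(self):
            raise ValueError("empty series")
        lo = self.steps[-1] - window_steps
        sel = self.steps > lo
        return self.freqs[sel].mean(axis=0)

    @staticmethod
    def concat(parts: List["FrequencySeries"]) -> "FrequencySeries":
        parts = [p for p in parts if len(p)]
        if not parts:
            return FrequencySeries(np.empty(0, dtype=np.int64), np.empty((0, 15)))
        return FrequencySeries(
            np.concatenate([p.steps for p in parts]),
            np.vstack([p.freqs for p in parts]),
        )


@dataclass
class SimResult:
    """Everything a finished (phase of a) simulation produced."""

    config: SimConfig
    series: FrequencySeries
    lattice: Lattice
    extinctions: Dict[int, int]  # type id -> step of current extinction
    steady_step: Optional[int]
    end_step: int
    metadata: Dict[str, object] = field(default_factory=dict)


def init_lattice(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Lattice:
    """Equal numbers of the 15 types placed by a seeded random permutation.

    When N is not divisible by 15 the remainder is spread over types chosen
    at random, so per-type counts differ by at most one.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    base, extra = divmod(n * n, 15)
    counts = np.full(15, base, dtype=int)
    if extra:
        counts[rng.choice(15, size=extra, replace=False)] += 1
    types = np.repeat(np.arange(1, 16, dtype=np.int8), counts)
    rng.shuffle(types)
    return Lattice(grid=types.reshape(n, n))


def detect_steady_state(
    series: FrequencySeries, window: int = 50_000, tol: float = 0.005
) -> Optional[int]:
    """Earliest sampled step after which frequencies stop drifting.

    Returns the first sampled step s such that, over the trailing window of
    `window` steps ending at s, every type's frequency range (max - min) is
    below `tol`; None if the series never settles.
    """
    if len(series) < 2:
        return None
    steps, freqs = series.steps, series.freqs
    for i in range(len(series)):
        lo_step = steps[i] - window
        if lo_step < steps[0]:
            continue
        sel = (steps > lo_step) & (steps <= steps[i])
        win = freqs[sel]
        if win.shape[0] < 2:
            continue
        if float((win.max(axis=0) - win.min(axis=0)).max()) < tol:
            return int(steps[i])
    return None


def count_spatial_clusters(lattice: Lattice, type_id: int, block: int = 3) -> int:
    """Number of toroidal block x block squares occupied by a single type.

    A fully occupied 3x3 square of T2 or T4 is the nucleation domain that
    protects outgrowth in the immobile (niche-B) regime.
    """
    same = lattice.grid == np.int8(type_id)
    acc = np.ones_like(same)
    for di in range(block):
        for dj in range(block):
            acc &= np.roll(np.roll(same, -di, axis=0), -dj, axis=1)
    return int(acc.sum())


def _run_phase(
    lattice: Lattice,
    counts: np.ndarray,
    config: SimConfig,
    n_steps: int,
    t0: int,
    seed: int,
    first_extinct: np.ndarray,
    stop_window: Optional[int],
    stop_tol: float,
) -> Tuple[FrequencySeries, int]:
    """Advance one parameter phase, optionally stopping at steady state."""
    table = build_composition_table()
    product = np.ascontiguousarray(table.product)
    influx = np.asarray(config.influx_set, dtype=np.int8)
    sigma = float(np.sqrt(config.v))
    rec_every = config.record_every
    _kernels.seed_rng(seed)

    chunk = n_steps if stop_window is None else max(rec_every, stop_window // 2)
    parts: List[FrequencySeries] = []
    done = 0
    pop = lattice.population
    while done < n_steps:
        todo = min(chunk, n_steps - done)
        max_rec = todo // rec_every + 2
        rec_steps = np.zeros(max_rec, dtype=np.int64)
        rec_counts = np.zeros((max_rec, 16), dtype=np.int64)
        nrec = _kernels.run_chunk(
            lattice.grid,
            counts,
            product,
            influx,
            float(config.phi),
            int(config.c),
            sigma,
            todo,
            t0 + done,
            rec_every,
            rec_steps,
            rec_counts,
            first_extinct,
        )
        done += todo
        if nrec:
            parts.append(
                FrequencySeries(rec_steps[:nrec], rec_counts[:nrec, 1:] / pop)
            )
        if stop_window is not None and parts:
            so_far = FrequencySeries.concat(parts)
            settled = detect_steady_state(so_far, window=stop_window, tol=stop_tol)
            if settled is not None and settled >= t0 + stop_window:
                break
    return FrequencySeries.concat(parts), t0 + done


def run(
    config: SimConfig,
    schedule: Optional[Schedule] = None,
    lattice: Optional[Lattice] = None,
    stop_window: Optional[int] = None,
    stop_tol: float = 0.005,
) -> SimResult:
    """Run the simulation, optionally with mid-run parameter changes.

    `schedule` lists (step, overrides) pairs: at the given production step
    the named SimConfig fields are replaced (e.g. perturbations of c, v,
    phi, influx_set).  With `stop_window` set, each phase ends early once
    the frequency drift over that trailing window falls below `stop_tol`.
    Identical (config, schedule, lattice, seed) reproduce identical output.
    """
    schedule = sorted(schedule or [], key=lambda e: e[0])
    rng = np.random.default_rng(config.seed)
    if lattice is None:
        lattice = init_lattice(config, rng)
    counts = lattice.counts()
    first_extinct = np.full(16, -1, dtype=np.int64)
    first_extinct[counts == 0] = 0

    # per-phase kernel seeds derived from the run seed
    seeds = np.random.SeedSequence(config.seed).generate_state(len(schedule) + 1)
    boundaries = [s for s, _ in schedule] + [config.iterations]
    phase_cfg = config
    parts: List[FrequencySeries] = []
    t = 0
    for k, boundary in enumerate(boundaries):
        if k > 0:
            phase_cfg = phase_cfg.replace(**schedule[k - 1][1])
        n_steps = max(0, boundary - t)
        if n_steps:
            series, t = _run_phase(
                lattice,
                counts,
                phase_cfg,
                n_steps,
                t,
                int(seeds[k] & 0x7FFFFFFF),
                first_extinct,
                stop_window,
                stop_tol,
            )
            parts.append(series)
    full = FrequencySeries.concat(parts)
    steady = detect_steady_state(full) if len(full) else None
    extinctions = {
        int(tt): int(first_extinct[tt]) for tt in range(1, 16) if counts[tt] == 0
    }
    return SimResult(
        config=config,
        series=full,
        lattice=lattice,
        extinctions=extinctions,
        steady_step=steady,
        end_step=t,
        metadata={
            "budget_exhausted": t >= config.iterations,
            "schedule": [(s, dict(o)) for s, o in schedule],
        },
    )
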