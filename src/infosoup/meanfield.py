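"""Deterministic well-mixed frequency dynamics of the composing population.

With the population well mixed and no environmental influx, the expected
change of the type-frequency vector f per production event is

    df_c/dt = P_c(f) (1 - f_c) - f_c (1 - P_c(f) - P_0(f)),

where P_x(f) = sum over ordered pairs (a, b) with product x of f_a f_b.
The gain term is the probability that T_c is produced and replaces an
occupant that was not already T_c; the loss term is the probability that a
production event succeeds with some other product and happens to replace a
T_c occupant.  The drift conserves total frequency, and every fixed point
satisfies the self-consistency relation

    f_c = P_c(f) / (1 - P_0(f)).

Global constant factors (e.g. the 1/4 probability of a particular ordered
neighbour arrangement on the lattice) rescale time only and do not alter
fixed points, so they are omitted.

The same dynamics restricted to a type subset — dropping every ordered
pair with an operand outside the subset — is what classifies candidate
self-producing networks as dynamically stable or unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Set, Tuple

import numpy as np

from .automata import CompositionTable, build_composition_table, productive_pairs_within

__all__ = [
    "drift",
    "solve_fixed_point",
    "restricted_trajectory",
    "FixedPointResult",
    "RestrictedTrajectory",
    "uniform_frequencies",
    "EXTINCTION_THRESHOLD",
]

#: frequency below which a type is considered extinct in restricted
#: dynamics; far below any meaningful fixed-point mass on a <=15 simplex and
#: far above accumulated integration error.
EXTINCTION_THRESHOLD = 1e-6

_SIMPLEX_ATOL = 1e-8


def uniform_frequencies(subset: Optional[Iterable[int]] = None) -> np.ndarray:
    """Uniform frequency vector (length 15, entries for T1..T15)."""
    f = np.zeros(15)
    if subset is None:
        f[:] = 1.0 / 15.0
    else:
        idx = [int(t) - 1 for t in subset]
        if not idx:
            raise ValueError("subset must be non-empty")
        f[idx] = 1.0 / len(idx)
    return f


def _check_simplex(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (15,):
        raise ValueError(f"frequency vector must have 15 entries, got {f.shape}")
    if f.min() < -_SIMPLEX_ATOL or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequency vector is not on the 15-type simplex")
    return f


def _pair_mass(f: np.ndarray, table: CompositionTable, subset_mask: Optional[np.ndarray]) -> np.ndarray:
    """P_x(f) for x = 0..15, optionally restricted to within-subset pairs."""
    fa = f[table.pair_first - 1]
    fb = f[table.pair_second - 1]
    w = fa * fb
    if subset_mask is not None:
        w = w * subset_mask
    return np.bincount(table.pair_product, weights=w, minlength=16)


def _subset_pair_mask(subset: FrozenSet[int], table: CompositionTable) -> np.ndarray:
    in_sub = np.zeros(16, dtype=bool)
    in_sub[list(subset)] = True
    return (in_sub[table.pair_first] & in_sub[table.pair_second]).astype(float)


def drift(
    f: np.ndarray,
    table: Optional[CompositionTable] = None,
    subset: Optional[Iterable[int]] = None,
) -> np.ndarray:
    """Instantaneous rate of change of the 15 type frequencies.

    When `subset` is given, only ordered pairs with both operands in the
    subset contribute production; `f` must then be supported on the subset.
    """
    if table is None:
        table = build_composition_table()
    f = _check_simplex(f)
    mask = None
    if subset is not None:
        sub = frozenset(int(t) for t in subset)
        outside = [t for t in range(1, 16) if t not in sub and f[t - 1] > _SIMPLEX_ATOL]
        if outside:
            raise ValueError(f"frequency vector has mass outside subset on {outside}")
        mask = _subset_pair_mask(sub, table)
    P = _pair_mass(f, table, mask)
    p0 = P[0]
    pc = P[1:]
    return pc * (1.0 - f) - f * (1.0 - pc - p0)


@dataclass
class FixedPointResult:
    """Outcome of numerically relaxing the frequency dynamics."""

    f: np.ndarray
    converged: bool
    n_steps: int
    residual: float

    def fixed_point_identity_error(
        self, table: Optional[CompositionTable] = None, subset=None
    ) -> float:
        """max_c |f_c - P_c / (1 - P_0)| at the solution."""
        if table is None:
            table = build_composition_table()
        mask = None
        if subset is not None:
            mask = _subset_pair_mask(frozenset(int(t) for t in subset), table)
        P = _pair_mass(self.f, table, mask)
        return float(np.abs(self.f - P[1:] / (1.0 - P[0])).max())


def solve_fixed_point(
    f0: Optional[np.ndarray] = None,
    table: Optional[CompositionTable] = None,
    subset: Optional[Iterable[int]] = None,
    tol: float = 1e-9,
    max_steps: int = 1_000_000,
    dt: float = 0.1,
) -> FixedPointResult:
    """Relax the dynamics by explicit Euler to an invariant distribution.

    The map is smooth and bounded on the simplex; plain Euler with step 0.1
    and per-step renormalisation converges quickly from any interior start.
    Non-convergence within the budget is flagged, not raised.
    """
    if table is None:
        table = build_composition_table()
    sub = None if subset is None else frozenset(int(t) for t in subset)
    if f0 is None:
        f = uniform_frequencies(sub)
    else:
        f = _check_simplex(f0).copy()
    mask = None if sub is None else _subset_pair_mask(sub, table)
    residual = np.inf
    for step in range(1, max_steps + 1):
        P = _pair_mass(f, table, mask)
        fd = P[1:] * (1.0 - f) - f * (1.0 - P[1:] - P[0])
        f = f + dt * fd
        np.clip(f, 0.0, None, out=f)
        f /= f.sum()
        residual = float(np.abs(fd).max())
        if residual < tol:
            return FixedPointResult(f=f, converged=True, n_steps=step, residual=residual)
    return FixedPointResult(f=f, converged=False, n_steps=max_steps, residual=residual)


@dataclass
class RestrictedTrajectory:
    """Trajectory of the dynamics restricted to a candidate network."""

    subset: FrozenSet[int]
    steps: np.ndarray
    freqs: np.ndarray  # (n_samples, 15)
    member_extinct: bool
    extinct_members: FrozenSet[int]
    leakage: FrozenSet[Tuple[int, int, int]]
    final: np.ndarray = field(default_factory=lambda: np.zeros(15))

    @property
    def stable(self) -> bool:
        """Closed under composition and no member collapsed."""
        return not self.member_extinct and not self.leakage


def restricted_trajectory(
    subset: Iterable[int],
    f0: Optional[np.ndarray] = None,
    table: Optional[CompositionTable] = None,
    horizon: int = 100_000,
    dt: float = 0.1,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    record_every: int = 1000,
    tol: float = 1e-12,
) -> RestrictedTrajectory:
    """Integrate the subset-restricted dynamics from a uniform start.

    Leakage (a within-subset pair producing an outside type) is determined
    from the composition table; member extinction is any member frequency
    falling below `extinction_threshold`.  Integration stops early at a
    fixed point or at first extinction.
    """
    sub = frozenset(int(t) for t in subset)
    if len(sub) < 2:
        raise ValueError("restricted dynamics require a subset of size >= 2")
    if table is None:
        table = build_composition_table()
    pw = productive_pairs_within(sub, table)
    mask = _subset_pair_mask(sub, table)
    f = uniform_frequencies(sub) if f0 is None else _check_simplex(f0).copy()
    idx = np.array(sorted(sub)) - 1
    steps = [0]
    freqs = [f.copy()]
    extinct: Set[int] = set()
    for step in range(1, horizon + 1):
        P = _pair_mass(f, table, mask)
        fd = P[1:] * (1.0 - f) - f * (1.0 - P[1:] - P[0])
        f = f + dt * fd
        np.clip(f, 0.0, None, out=f)
        f /= f.sum()
        if step % record_every == 0:
            steps.append(step)
            freqs.append(f.copy())
        low = f[idx] < extinction_threshold
        if low.any():
            extinct = {int(t) for t in (idx[low] + 1)}
            steps.append(step)
            freqs.append(f.copy())
            break
        if float(np.abs(fd).max()) < tol:
            steps.append(step)
            freqs.append(f.copy())
            break
    return RestrictedTrajectory(
        subset=sub,
        steps=np.asarray(steps),
        freqs=np.asarray(freqs),
        member_extinct=bool(extinct),
        extinct_members=frozenset(extinct),
        leakage=pw.leakage,
        final=f,
    )
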