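"""The 16 one-state binary transducers and their functional composition.

A one-state automaton is a deterministic binary communication channel
described by a subset of the four directed transitions over the alphabet
{0, 1}:

    0->0, 0->1, 1->0, 1->1

Types are indexed 1..15 by the 4-bit mask of their transition set
(bit values 1 = 0->0, 2 = 0->1, 4 = 1->0, 8 = 1->1).  The empty channel T0
("transitionless machine") is the result of a failed composition and is
never a population member.

Functional composition chains two channels: the signal passes through the
first-acting machine and its output feeds the second-acting machine.  In
operator notation the product of feeding ``a`` into ``b`` is ``b o a``,
which here is ``compose(a, b)``.  The resulting transition relation is the
relational product

    x -> z   iff   exists y with (x -> y) in a and (y -> z) in b.

Of the 225 ordered pairs of the 15 population members, 207 compose to a
non-empty channel; the remaining 18 produce T0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

import numpy as np

__all__ = [
    "AutomatonType",
    "CompositionTable",
    "PairsWithin",
    "compose",
    "build_composition_table",
    "productive_pairs_within",
    "transitions_of",
    "mask_of",
    "BIT_SWAP_RELABEL",
]

#: number of population member types (T1..T15)
N_TYPES = 15

#: the 0<->1 alphabet-relabelling permutation of type ids.  Swapping the two
#: alphabet symbols maps transition x->z to (1-x)->(1-z), i.e. permutes the
#: mask bits 1<->8 and 2<->4; it is an automorphism of the composition table.
BIT_SWAP_RELABEL: Dict[int, int] = {}


def _bit_swap(mask: int) -> int:
    out = 0
    if mask & 1:
        out |= 8
    if mask & 8:
        out |= 1
    if mask & 2:
        out |= 4
    if mask & 4:
        out |= 2
    return out


for _t in range(16):
    BIT_SWAP_RELABEL[_t] = _bit_swap(_t)


def transitions_of(type_id: int) -> FrozenSet[Tuple[int, int]]:
    """Transition set {(x, z), ...} encoded by a type id (0..15)."""
    if not 0 <= type_id <= 15:
        raise ValueError(f"type id must be in 0..15, got {type_id}")
    return frozenset(
        (x, z) for x in (0, 1) for z in (0, 1) if type_id >> (2 * x + z) & 1
    )


def mask_of(transitions: Iterable[Tuple[int, int]]) -> int:
    """Inverse of :func:`transitions_of`."""
    mask = 0
    for x, z in transitions:
        if x not in (0, 1) or z not in (0, 1):
            raise ValueError(f"invalid transition {(x, z)}")
        mask |= 1 << (2 * x + z)
    return mask


@dataclass(frozen=True)
class AutomatonType:
    """A one-state automaton, identified by its 4-bit transition mask."""

    id: int

    def __post_init__(self) -> None:
        if not 0 <= self.id <= 15:
            raise ValueError(f"type id must be in 0..15, got {self.id}")

    @property
    def transitions(self) -> FrozenSet[Tuple[int, int]]:
        return transitions_of(self.id)

    @property
    def n_transitions(self) -> int:
        return bin(self.id).count("1")

    @property
    def is_transitionless(self) -> bool:
        return self.id == 0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"T{self.id}"


def _check_member(type_id: int, arg: str) -> None:
    if not isinstance(type_id, (int, np.integer)):
        raise TypeError(f"{arg} must be an integer type id, got {type_id!r}")
    if not 1 <= int(type_id) <= 15:
        raise ValueError(
            f"{arg} must be a population member id in 1..15, got {type_id}"
        )


def compose(first: int | AutomatonType, second: int | AutomatonType) -> int:
    """Compose two channels; the signal passes through `first`, then `second`.

    Returns the product type id (0 for the transitionless machine T0).
    In operator notation this is ``second o first``.
    """
    a = first.id if isinstance(first, AutomatonType) else first
    b = second.id if isinstance(second, AutomatonType) else second
    _check_member(a, "first")
    _check_member(b, "second")
    result = 0
    for x in (0, 1):
        for z in (0, 1):
            for y in (0, 1):
                if a >> (2 * x + y) & 1 and b >> (2 * y + z) & 1:
                    result |= 1 << (2 * x + z)
                    break
    return result


@dataclass(frozen=True)
class PairsWithin:
    """Productive ordered pairs restricted to a type subset.

    ``pairs`` holds the ordered pairs (first-acting, second-acting) with a
    non-T0 product; ``leakage`` holds the triples (a, b, product) whose
    product falls outside the subset — a non-empty leakage set means the
    subset is not compositionally closed.
    """

    subset: FrozenSet[int]
    pairs: FrozenSet[Tuple[int, int]]
    leakage: FrozenSet[Tuple[int, int, int]]

    @property
    def closed(self) -> bool:
        return not self.leakage

    @property
    def product_counts(self) -> Dict[int, int]:
        table = build_composition_table()
        counts: Dict[int, int] = {}
        for a, b in self.pairs:
            c = int(table.product[a, b])
            counts[c] = counts.get(c, 0) + 1
        return counts


class CompositionTable:
    """The full 16x16 product map of the 15 population types.

    Attributes
    ----------
    product : (16, 16) int8 array
        ``product[a, b]`` is the id of ``compose(a, b)``; row and column 0
        are zero (T0 never interacts).
    producers : dict
        Maps each product id 0..15 to the frozen set of ordered pairs
        (a, b) over 1..15 producing it — the exact inverse of ``product``.
    triples : list of (a, b, c)
        The 207 productive ordered compositions.
    """

    def __init__(self) -> None:
        product = np.zeros((16, 16), dtype=np.int8)
        producers: Dict[int, Set[Tuple[int, int]]] = {c: set() for c in range(16)}
        triples: List[Tuple[int, int, int]] = []
        for a in range(1, 16):
            for b in range(1, 16):
                c = compose(a, b)
                product[a, b] = c
                producers[c].add((a, b))
                if c:
                    triples.append((a, b, c))
        self.product = product
        self.product.setflags(write=False)
        self.producers: Dict[int, FrozenSet[Tuple[int, int]]] = {
            c: frozenset(ps) for c, ps in producers.items()
        }
        self.triples: List[Tuple[int, int, int]] = triples
        # flat index arrays over all 225 ordered pairs, used by the
        # mean-field drift and the census scan
        a_idx, b_idx = np.meshgrid(np.arange(1, 16), np.arange(1, 16), indexing="ij")
        self.pair_first = a_idx.ravel()
        self.pair_second = b_idx.ravel()
        self.pair_product = product[self.pair_first, self.pair_second].astype(np.int64)

    @property
    def n_productive(self) -> int:
        """Number of ordered pairs with a non-T0 product (207)."""
        return len(self.triples)

    def self_replicators(self) -> FrozenSet[int]:
        """Types t with compose(t, t) == t."""
        return frozenset(t for t in range(1, 16) if self.product[t, t] == t)

    def as_matrix(self) -> np.ndarray:
        """The 15x15 integer product matrix (row = first-acting type)."""
        return np.asarray(self.product[1:, 1:], dtype=int).copy()

    def to_json(self) -> dict:
        return {
            "product": self.as_matrix().tolist(),
            "producers": {
                str(c): sorted(map(list, ps)) for c, ps in self.producers.items()
            },
            "n_productive": self.n_productive,
        }

    def to_csv(self, path) -> None:
        """Write the 15x15 product matrix (0 marks a T0 product)."""
        import pandas as pd

        labels = [f"T{t}" for t in range(1, 16)]
        pd.DataFrame(self.as_matrix(), index=labels, columns=labels).to_csv(
            path, index_label="first_acting"
        )


@lru_cache(maxsize=1)
def build_composition_table() -> CompositionTable:
    """Build (once) and cache the full composition table."""
    return CompositionTable()


def productive_pairs_within(
    subset: Iterable[int], table: CompositionTable | None = None
) -> PairsWithin:
    """All productive ordered pairs with both operands in `subset`.

    Also reports leakage: within-subset pairs whose product falls outside
    the subset, which disqualifies the subset from compositional closure.
    """
    sub = frozenset(int(t) for t in subset)
    if not sub:
        raise ValueError("subset must be non-empty")
    for t in sub:
        _check_member(t, "subset member")
    if table is None:
        table = build_composition_table()
    pairs = set()
    leakage = set()
    for a in sub:
        for b in sub:
            c = int(table.product[a, b])
            if c:
                pairs.add((a, b))
                if c not in sub:
                    leakage.add((a, b, c))
    return PairsWithin(subset=sub, pairs=frozenset(pairs), leakage=frozenset(leakage))
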