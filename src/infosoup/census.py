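"""Exhaustive census of self-producing sub-networks of the composition table.

Every subset of 2..15 automaton types induces a production digraph: for each
within-subset productive composition (a, b) -> c, both operands contribute a
directed participation edge a -> c and b -> c.  The census classifies all
32 752 subsets into a taxonomy of increasing specialism:

* **network** — every member is produced by at least one within-subset
  interaction other than pure self-replication, and participates in
  producing at least one member other than itself (the degree criterion on
  the production digraph).  7831 subsets qualify.
* **candidate strongly connected** — the production digraph is strongly
  connected: members mutually produce each other through directed cycles.
* **dynamically stable** — additionally closed under composition (no
  within-subset pair produces an outside type) and, under the restricted
  mean-field dynamics from a uniform start, no member's frequency collapses
  below the extinction threshold.  29 subsets qualify.
* **elementary** — a stable network containing no proper stable
  sub-network; the irreducible building blocks.  12 subsets qualify, and
  the 29 stable networks split 17 reducible + 12 elementary.

Stable networks are the model's meta-machines: self-producing, closed,
autonomous organisations.  Information niches are built hierarchically from
elementary networks (:func:`build_hierarchy`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np

from .automata import CompositionTable, build_composition_table, productive_pairs_within
from .meanfield import EXTINCTION_THRESHOLD, restricted_trajectory

__all__ = [
    "production_graph",
    "is_network",
    "is_candidate_strong",
    "classify",
    "full_census",
    "stable_networks",
    "elementary_networks",
    "build_hierarchy",
    "NetworkCensusRecord",
    "CensusResult",
    "NicheHierarchy",
]

#: Euler steps used when integrating restricted dynamics for stability.
STABILITY_HORIZON = 100_000


def production_graph(
    subset: Iterable[int], table: Optional[CompositionTable] = None
) -> nx.DiGraph:
    """Directed participant -> product graph induced on a type subset.

    Parallel participations collapse to simple edges with a ``weight``
    attribute counting them; nodes carry ``self_producing`` flags.
    """
    if table is None:
        table = build_composition_table()
    sub = frozenset(int(t) for t in subset)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(sub), self_producing=False)
    for a in sub:
        for b in sub:
            c = int(table.product[a, b])
            if c and c in sub:
                for p in (a, b):
                    if g.has_edge(p, c):
                        g[p][c]["weight"] += 1
                    else:
                        g.add_edge(p, c, weight=1)
                if c in (a, b):
                    g.nodes[c]["self_producing"] = True
    return g


def _within_triples(sub: FrozenSet[int], table: CompositionTable):
    return [(a, b, c) for a, b, c in table.triples if a in sub and b in sub and c in sub]


def is_network(subset: Iterable[int], table: Optional[CompositionTable] = None) -> bool:
    """Degree criterion: every member produced (beyond pure self-replication)
    and producing (beyond itself) within the subset."""
    if table is None:
        table = build_composition_table()
    sub = frozenset(int(t) for t in subset)
    if len(sub) < 2:
        return False
    trip = _within_triples(sub, table)
    for x in sub:
        if not any(c == x and not (a == b == x) for a, b, c in trip):
            return False
        if not any(x in (a, b) and c != x for a, b, c in trip):
            return False
    return True


def is_candidate_strong(
    subset: Iterable[int], table: Optional[CompositionTable] = None
) -> bool:
    """Mutual production: the production digraph is strongly connected.

    For a subset of size >= 2 strong connectivity implies the degree
    criterion of :func:`is_network`, so every candidate is a network.
    """
    if table is None:
        table = build_composition_table()
    sub = frozenset(int(t) for t in subset)
    if not 2 <= len(sub) <= 15:
        return False
    g = production_graph(sub, table)
    if g.number_of_edges() == 0:
        return False
    return nx.is_strongly_connected(g)


@dataclass(frozen=True)
class NetworkCensusRecord:
    """Classification of one type subset."""

    subset: FrozenSet[int]
    classification: str  # not_network | general | candidate | stable | elementary
    leakage: FrozenSet[Tuple[int, int, int]]
    extinct_members: FrozenSet[int]
    fixed_point: Optional[np.ndarray] = None

    @property
    def is_stable(self) -> bool:
        return self.classification in ("stable", "elementary")


def _stability(sub: FrozenSet[int], table: CompositionTable):
    """(closed, extinct_members, final_f) under restricted dynamics."""
    traj = restricted_trajectory(
        sub,
        table=table,
        horizon=STABILITY_HORIZON,
        extinction_threshold=EXTINCTION_THRESHOLD,
        record_every=STABILITY_HORIZON,
    )
    return (not traj.leakage), traj.extinct_members, traj.final


def _closed_subsets(table: CompositionTable) -> List[FrozenSet[int]]:
    """Compositionally closed subsets of size >= 2 with >= 1 productive pair."""
    masks = np.array(
        [m for m in range(1, 1 << 15) if bin(m).count("1") >= 2], dtype=np.int64
    )
    pa, pb, pc = table.pair_first - 1, table.pair_second - 1, table.pair_product
    pair_in = (((masks[:, None] >> pa) & 1) & ((masks[:, None] >> pb) & 1)).astype(bool)
    productive = pc != 0
    prod_outside = productive & ~(((masks[:, None] >> (pc - 1)) & 1).astype(bool))
    leaky = (pair_in & prod_outside).any(axis=1)
    any_pair = (pair_in & productive).any(axis=1)
    out = []
    for m in masks[~leaky & any_pair]:
        out.append(frozenset(int(t) + 1 for t in range(15) if m >> t & 1))
    return out


@lru_cache(maxsize=1)
def stable_networks(table: Optional[CompositionTable] = None) -> Tuple[FrozenSet[int], ...]:
    """The dynamically stable networks (closed candidates keeping all members)."""
    if table is None:
        table = build_composition_table()
    out: List[FrozenSet[int]] = []
    for sub in _closed_subsets(table):
        if not is_candidate_strong(sub, table):
            continue
        closed, extinct, _ = _stability(sub, table)
        if closed and not extinct:
            out.append(sub)
    return tuple(sorted(out, key=lambda s: (len(s), sorted(s))))


@lru_cache(maxsize=1)
def elementary_networks(table: Optional[CompositionTable] = None) -> Tuple[FrozenSet[int], ...]:
    """Stable networks containing no proper stable sub-network."""
    stab = stable_networks(table)
    return tuple(s for s in stab if not any(o < s for o in stab))


def classify(
    subset: Iterable[int], table: Optional[CompositionTable] = None
) -> NetworkCensusRecord:
    """Full taxonomy classification of one subset.

    ``elementary`` < ``stable`` < ``candidate`` < ``general`` in order of
    increasing generality; subsets failing the degree criterion are
    ``not_network``.
    """
    if table is None:
        table = build_composition_table()
    sub = frozenset(int(t) for t in subset)
    leakage = (
        productive_pairs_within(sub, table).leakage if len(sub) >= 1 else frozenset()
    )
    if not is_network(sub, table):
        return NetworkCensusRecord(sub, "not_network", leakage, frozenset())
    if not is_candidate_strong(sub, table):
        return NetworkCensusRecord(sub, "general", leakage, frozenset())
    if leakage:
        return NetworkCensusRecord(sub, "candidate", leakage, frozenset())
    closed, extinct, final = _stability(sub, table)
    if extinct:
        return NetworkCensusRecord(sub, "candidate", leakage, frozenset(extinct))
    label = "elementary" if sub in set(elementary_networks(table)) else "stable"
    return NetworkCensusRecord(sub, label, leakage, frozenset(), fixed_point=final)


@dataclass
class CensusResult:
    """Outcome of the exhaustive subset scan."""

    records: List[NetworkCensusRecord]
    summary: Dict[str, int]

    def by_class(self, classification: str) -> List[FrozenSet[int]]:
        return [r.subset for r in self.records if r.classification == classification]

    @property
    def networks(self) -> List[FrozenSet[int]]:
        return [r.subset for r in self.records]

    @property
    def candidates(self) -> List[FrozenSet[int]]:
        return [
            r.subset
            for r in self.records
            if r.classification in ("candidate", "stable", "elementary")
        ]

    @property
    def stable(self) -> List[FrozenSet[int]]:
        return [r.subset for r in self.records if r.is_stable]

    @property
    def elementary(self) -> List[FrozenSet[int]]:
        return [r.subset for r in self.records if r.classification == "elementary"]


def full_census(table: Optional[CompositionTable] = None) -> CensusResult:
    """Scan all 32 752 subsets of sizes 2..15 and classify each network.

    Returns one record per qualifying network (degree criterion), plus a
    summary with the class counts.  The scan is deterministic and
    independent of iteration order; the degree and connectivity stages are
    vectorised over subsets for speed.
    """
    if table is None:
        table = build_composition_table()

    masks = np.array(
        [m for m in range(1, 1 << 15) if bin(m).count("1") >= 2], dtype=np.int64
    )
    tri = np.array(table.triples, dtype=np.int64)  # (207, 3), ids 1..15
    a_bit, b_bit, c_bit = tri[:, 0] - 1, tri[:, 1] - 1, tri[:, 2] - 1
    # within[m, k]: triple k has all three types inside subset mask m
    within = (
        (masks[:, None] >> a_bit) & (masks[:, None] >> b_bit) & (masks[:, None] >> c_bit)
    ) & 1
    within = within.astype(bool)

    contains = ((masks[:, None] >> np.arange(15)) & 1).astype(bool)  # (S, 15)

    # degree criterion, vectorised per type
    produced_ok = np.ones_like(contains)
    produces_ok = np.ones_like(contains)
    pure_self = (tri[:, 0] == tri[:, 1]) & (tri[:, 1] == tri[:, 2])
    for t in range(1, 16):
        in_cols = (tri[:, 2] == t) & ~pure_self
        out_cols = ((tri[:, 0] == t) | (tri[:, 1] == t)) & (tri[:, 2] != t)
        produced_ok[:, t - 1] = within[:, in_cols].any(axis=1)
        produces_ok[:, t - 1] = within[:, out_cols].any(axis=1)
    network_flag = (~contains | (produced_ok & produces_ok)).all(axis=1)

    # closure over all 225 ordered pairs
    pa, pb, pc = table.pair_first - 1, table.pair_second - 1, table.pair_product
    pair_in = (
        ((masks[:, None] >> pa) & 1) & ((masks[:, None] >> pb) & 1)
    ).astype(bool)
    prod_outside = (pc != 0) & ~(((masks[:, None] >> (pc - 1)) & 1).astype(bool))
    leaky = (pair_in & prod_outside).any(axis=1)

    # strong connectivity via boolean transitive closure, networks only
    def _strong(mask_idx: int) -> bool:
        adj = np.zeros((15, 15), dtype=bool)
        cols = np.flatnonzero(within[mask_idx])
        adj[a_bit[cols], c_bit[cols]] = True
        adj[b_bit[cols], c_bit[cols]] = True
        nodes = np.flatnonzero(contains[mask_idx])
        reach = adj | np.eye(15, dtype=bool)
        for _ in range(4):  # (2^4 = 16) > 15 path length
            reach = reach | (reach @ reach)
        sub_reach = reach[np.ix_(nodes, nodes)]
        return bool(sub_reach.all() and sub_reach.T.all())

    stable_set = set(stable_networks(table))
    elem_set = set(elementary_networks(table))

    records: List[NetworkCensusRecord] = []
    counts = {"general": 0, "candidate": 0, "stable": 0, "elementary": 0}
    for i in np.flatnonzero(network_flag):
        sub = frozenset(int(t) + 1 for t in np.flatnonzero(contains[i]))
        if not _strong(i):
            cls = "general"
        elif sub in elem_set:
            cls = "elementary"
        elif sub in stable_set:
            cls = "stable"
        else:
            cls = "candidate"
        leakage: FrozenSet[Tuple[int, int, int]] = frozenset()
        if cls != "general" and leaky[i]:
            leakage = productive_pairs_within(sub, table).leakage
        records.append(NetworkCensusRecord(sub, cls, leakage, frozenset()))
        counts[cls] += 1

    summary = {
        "subsets_scanned": int(masks.size),
        "networks": len(records),
        "general": counts["general"],
        "candidates": counts["candidate"] + counts["stable"] + counts["elementary"],
        "stable": counts["stable"] + counts["elementary"],
        "elementary": counts["elementary"],
    }
    return CensusResult(records=records, summary=summary)


@dataclass
class NicheHierarchy:
    """Bottom-up construction of a niche from its elementary networks.

    ``levels[0]`` holds the elementary networks contained in the niche;
    ``levels[k]`` holds the stable unions of level-(k-1) networks.
    ``new_types`` records, per union, the types producible within the union
    but within none of its constituents; ``redundancy`` counts, per type,
    the elementary networks that produce it.
    """

    niche: FrozenSet[int]
    levels: List[List[FrozenSet[int]]]
    new_types: Dict[FrozenSet[int], FrozenSet[int]]
    redundancy: Dict[int, int]

    @property
    def non_hierarchical(self) -> bool:
        return len(self.levels) <= 1


def _products_within(sub: FrozenSet[int], table: CompositionTable) -> FrozenSet[int]:
    return frozenset(
        int(table.product[a, b])
        for a in sub
        for b in sub
        if table.product[a, b]
    )


def build_hierarchy(
    niche_subset: Iterable[int], table: Optional[CompositionTable] = None
) -> NicheHierarchy:
    """Levelled composition of a stable niche out of elementary networks."""
    if table is None:
        table = build_composition_table()
    niche = frozenset(int(t) for t in niche_subset)
    stab = set(stable_networks(table))
    if niche not in stab:
        raise ValueError(f"niche {sorted(niche)} is not a dynamically stable network")
    level0 = sorted(
        (e for e in elementary_networks(table) if e <= niche), key=sorted
    )
    levels: List[List[FrozenSet[int]]] = [list(level0)]
    seen = set(level0)
    new_types: Dict[FrozenSet[int], FrozenSet[int]] = {}
    while True:
        prev = levels[-1]
        nxt = set()
        for u, w in combinations(prev, 2):
            union = u | w
            if union in seen or not union <= niche or union not in stab:
                continue
            nxt.add(union)
            constituent_products = _products_within(u, table) | _products_within(w, table)
            new_types[union] = _products_within(union, table) - constituent_products
        if not nxt:
            break
        levels.append(sorted(nxt, key=sorted))
        seen |= nxt
        if niche in nxt:
            break
    redundancy = {
        t: sum(1 for e in level0 if t in _products_within(e, table)) for t in sorted(niche)
    }
    return NicheHierarchy(
        niche=niche, levels=levels, new_types=new_types, redundancy=redundancy
    )
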