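"""Information niches: classification, landscape scans and transitions.

An information niche is a distinct steady-state organisation of the
population — a survivor set plus a cluster structure of comparable
frequencies.  The rule table below maps a steady-state frequency vector to
one of the named niches:

===== =============================================================
label structure
===== =============================================================
A     nine survivors {1,2,3,4,5,8,10,12,15}; T15 the single top
      cluster above {3,5,10,12} above {1,2,4,8} (well mixed, no influx)
B     survivors {1,2,4,8} with T2+T4 holding most of the mass
      (frozen lattice, no influx)
C     all 15 types sustained, four clusters with T15 on top
      (mixing with substantial influx)
D     near-uniform over all 15 (influx-dominated)
E     all 15 sustained with B-like T2+T4 dominance (frozen, low influx)
F     T15 dominant over a sustained {6,7,9,11,13,14} group, the
      remaining eight types gone (type-restricted influx)
X     secondary: {1,2,4,8} equalised into one cluster, optionally
      with a {3,5,10,12} partner group, T15 absent
Y     secondary: near-pure T15
===== =============================================================

Classification is a pure function of the frequency vector (plus the
lattice survivor set when available); ambiguous states are reported as
``unclassified`` rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .automata import build_composition_table
from .config import SimConfig
from .lattice import Lattice, SimResult, run
from .metrics import interaction_complexity, production_threshold

__all__ = [
    "NicheLabel",
    "TransitionRecord",
    "classify_niche",
    "frequency_clusters",
    "landscape_scan",
    "LandscapePoint",
    "perturb_and_revert",
    "transition_graph",
    "information_rule_holds",
]

NINE_SURVIVORS = frozenset({1, 2, 3, 4, 5, 8, 10, 12, 15})
FOUR_SET = frozenset({1, 2, 4, 8})
SLOW_SET = frozenset({3, 5, 10, 12})
SIX_SET = frozenset({6, 7, 9, 11, 13, 14})
EIGHT_SET = FOUR_SET | SLOW_SET

#: frequency above which a type counts as sustained (30 occupants on a
#: 100 x 100 lattice); types below it are decaying traces or influx noise.
PRESENT_TOL = 0.003


@dataclass(frozen=True)
class NicheLabel:
    """A niche classification with its supporting structure.

    ``survivors`` is the sustained type set observed in the state;
    ``core`` is the niche-defining production subset used for
    production-threshold bookkeeping (e.g. the {1,2,4,8} network that
    dominates production in niches B and X even when decaying traces of
    other types are still present).
    """

    label: str
    survivors: FrozenSet[int]
    clusters: Tuple[Tuple[int, ...], ...]
    dominant: Tuple[int, ...]
    core: FrozenSet[int] = frozenset()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def frequency_clusters(
    f: np.ndarray, members: Iterable[int], gap_ratio: float = 1.5
) -> List[List[int]]:
    """Group types with comparable steady frequencies.

    Types are sorted by decreasing frequency and split wherever the ratio
    between consecutive frequencies exceeds `gap_ratio`.
    """
    order = sorted(members, key=lambda t: -f[t - 1])
    groups: List[List[int]] = []
    for t in order:
        if groups and f[groups[-1][-1] - 1] <= gap_ratio * f[t - 1]:
            groups[-1].append(t)
        else:
            groups.append([t])
    return groups


def classify_niche(
    f: np.ndarray,
    survivors: Optional[Iterable[int]] = None,
    present_tol: float = PRESENT_TOL,
) -> NicheLabel:
    """Apply the niche rule table to a steady-state frequency vector.

    `survivors` may give the exact set of types with non-zero lattice
    counts; types below `present_tol` are treated as not sustained either
    way.  The function is total: states matching no rule are labelled
    ``unclassified``.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (15,):
        raise ValueError("frequency vector must have 15 entries")
    alive = (
        frozenset(range(1, 16)) if survivors is None else frozenset(int(t) for t in survivors)
    )
    sustained = frozenset(t for t in alive if f[t - 1] >= present_tol)
    clusters = tuple(tuple(g) for g in frequency_clusters(f, sustained)) if sustained else ()

    all15 = frozenset(range(1, 16))

    def _result(label: str, dominant: Sequence[int], core: FrozenSet[int]) -> NicheLabel:
        return NicheLabel(label, sustained, clusters, tuple(dominant), core)

    if not sustained:
        return _result("unclassified", (), sustained)
    top = clusters[0]
    f24 = f[1] + f[3]
    f15 = f[14]

    if len(sustained) == 15 and np.abs(f - 1.0 / 15.0).max() < 0.01:
        return _result("D", tuple(range(1, 16)), all15)
    if f15 >= 0.95:
        return _result("Y", (15,), frozenset({15}))
    if (
        15 in sustained
        and SIX_SET <= sustained
        and not (sustained & EIGHT_SET)
        and f15 > 0.5
    ):
        return _result("F", (15,), frozenset({15}) | SIX_SET)
    if sustained == all15:
        top_two = set(int(t) + 1 for t in np.argsort(-f)[:2])
        # B-like structuring: T2 and T4 lead the population; the influx of
        # all 15 types dilutes their joint mass well below niche B's level
        if f24 > 0.5 or (top_two == {2, 4} and f24 >= 0.25):
            return _result("E", (2, 4), all15)
        if f15 == f.max():
            return _result("C", (15,), all15)
        return _result("unclassified", top, sustained)
    if sustained == NINE_SURVIVORS and f15 == f.max():
        return _result("A", (15,), NINE_SURVIVORS)
    if FOUR_SET <= sustained <= EIGHT_SET:
        four_cluster = next((c for c in clusters if 2 in c), ())
        if f24 > 0.5 and set(four_cluster) <= {2, 4}:
            return _result("B", (2, 4), FOUR_SET)
        if FOUR_SET <= set(four_cluster):
            # production is dominated by the equalised {1,2,4,8} network
            return _result("X", tuple(sorted(four_cluster)), FOUR_SET)
    return _result("unclassified", top, sustained)


@dataclass(frozen=True)
class LandscapePoint:
    c: int
    v: float
    phi: float
    label: str
    c_mu_bits: float
    steady: bool


def landscape_scan(
    points: Iterable[Tuple[int, float, float]],
    base_config: SimConfig,
    stop_window: int = 50_000,
    stop_tol: float = 0.005,
) -> List[LandscapePoint]:
    """One seeded run per (c, v, phi) grid point; label + C_mu recorded.

    Runs that fail steady-state detection within the budget are flagged
    (``steady=False``) and classified from their final window anyway.
    """
    table = build_composition_table()
    out = []
    for c, v, phi in points:
        cfg = base_config.replace(c=int(c), v=float(v), phi=float(phi))
        res = run(cfg, stop_window=stop_window, stop_tol=stop_tol)
        fbar = res.series.tail_mean(stop_window)
        label = classify_niche(fbar, res.lattice.survivors())
        out.append(
            LandscapePoint(
                c=int(c),
                v=float(v),
                phi=float(phi),
                label=label.label,
                c_mu_bits=interaction_complexity(fbar, table),
                steady=res.steady_step is not None,
            )
        )
    return out


@dataclass
class TransitionRecord:
    """One perturb-and-revert experiment between information niches."""

    from_label: str
    perturbation: Dict[str, object]
    to_label: str
    back_label: str
    reversible: bool
    threshold_before: float
    threshold_after: float
    threshold_back: float
    reverted_phi: float
    phases: List[SimResult] = field(default_factory=list)

    @property
    def edges(self) -> List[Tuple[str, str, bool]]:
        return [
            (self.from_label, self.to_label, False),
            (self.to_label, self.back_label, False),
        ]


def _phase_state(res: SimResult, window: int) -> Tuple[NicheLabel, np.ndarray]:
    fbar = res.series.tail_mean(window)
    return classify_niche(fbar, res.lattice.survivors()), fbar


def _threshold_of(label: NicheLabel) -> float:
    core = label.core or label.survivors
    if not core:
        return float("nan")
    try:
        return production_threshold(core)
    except ValueError:
        return float("nan")


def perturb_and_revert(
    base_config: SimConfig,
    perturbation: Dict[str, object],
    settle1: int,
    settle2: int,
    settle3: int,
    stop_window: int = 50_000,
    stop_tol: float = 0.005,
) -> TransitionRecord:
    """Establish a niche, perturb it, revert, and record the transition.

    Each phase runs until steady (trailing drift below `stop_tol` over
    `stop_window` steps) or until its budget; the three resulting states
    are classified and their production thresholds compared.  The
    transition is reversible when reverting the parameters re-establishes
    the original niche label.
    """
    cfg1 = base_config.replace(iterations=settle1)
    res1 = run(cfg1, stop_window=stop_window, stop_tol=stop_tol)
    lab1, _ = _phase_state(res1, stop_window)

    cfg2 = base_config.replace(iterations=settle2, **perturbation)
    res2 = run(cfg2, lattice=Lattice(res1.lattice.grid.copy()),
               stop_window=stop_window, stop_tol=stop_tol)
    lab2, _ = _phase_state(res2, stop_window)

    cfg3 = base_config.replace(iterations=settle3, seed=base_config.seed + 1)
    res3 = run(cfg3, lattice=Lattice(res2.lattice.grid.copy()),
               stop_window=stop_window, stop_tol=stop_tol)
    lab3, _ = _phase_state(res3, stop_window)

    return TransitionRecord(
        from_label=lab1.label,
        perturbation=dict(perturbation),
        to_label=lab2.label,
        back_label=lab3.label,
        reversible=lab3.label == lab1.label,
        threshold_before=_threshold_of(lab1),
        threshold_after=_threshold_of(lab2),
        threshold_back=_threshold_of(lab3),
        reverted_phi=float(cfg3.phi),
        phases=[res1, res2, res3],
    )


def information_rule_holds(record: TransitionRecord, tol: float = 1e-9) -> bool:
    """Transitions losing production-threshold bits are one-way unless the
    return environment supplies information (influx).

    Reversibility requires either no loss of threshold bits on the forward
    transition or a reverted environment with phi > 0.
    """
    if not record.reversible:
        return True
    no_loss = record.threshold_after >= record.threshold_before - tol
    return no_loss or record.reverted_phi > 0


def transition_graph(records: Iterable[TransitionRecord]) -> nx.DiGraph:
    """Directed niche-transition diagram from recorded experiments.

    Nodes are niche labels annotated with their production threshold in
    bits; edges are annotated with reversibility and whether they satisfy
    the information rule.
    """
    records = list(records)
    if not records:
        raise ValueError("at least one transition record is required")
    g = nx.DiGraph()
    for r in records:
        for lab, thr in (
            (r.from_label, r.threshold_before),
            (r.to_label, r.threshold_after),
            (r.back_label, r.threshold_back),
        ):
            if lab not in g:
                g.add_node(lab, threshold_bits=thr)
        g.add_edge(
            r.from_label,
            r.to_label,
            reversible=r.reversible,
            rule_ok=information_rule_holds(r),
        )
        if r.back_label != r.from_label or not r.reversible:
            g.add_edge(r.to_label, r.back_label, reversible=r.reversible, rule_ok=True)
    return g
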