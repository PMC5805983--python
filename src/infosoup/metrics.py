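"""Information measures of the interacting population.

Two complementary Shannon measures (base 2 throughout, 0 log 0 = 0):

* **Interaction network complexity** C_mu(G): the entropy of the
  frequency-weighted distribution over the productive ordered compositions.
  Each productive pair (a, b) carries probability f_a f_b / V with
  V = sum of f_a f_b over all productive pairs.  At the uniform
  15-type population this is log2(207) ~ 7.7 bits; it shrinks as the
  population structures itself into a niche.

* **Production threshold** H(X): the entropy of the distribution, over
  product types, of the productive compositions available within a type
  subset — x_i = (number of within-subset pairs producing type i) /
  (total within-subset productive pairs).  It measures the information
  needed to keep producing every member of a niche, and governs which
  niche transitions are reversible.

C_mu admits a second reading in which the pair weights are first
aggregated per product type; that variant is exposed separately as
:func:`production_complexity`.  Only the pair-level entropy reproduces the
log2(207) anchor of the unstructured population.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy.stats import entropy as _shannon

from .automata import CompositionTable, build_composition_table, productive_pairs_within

__all__ = [
    "interaction_distribution",
    "interaction_complexity",
    "production_complexity",
    "production_threshold",
]


def interaction_distribution(
    f: np.ndarray, table: Optional[CompositionTable] = None
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Weights f_a f_b / V over the productive ordered pairs.

    Returns ``(pairs, weights, V)`` where `pairs` is a (207, 2) array of
    ordered (first-acting, second-acting) type ids.
    """
    if table is None:
        table = build_composition_table()
    f = np.asarray(f, dtype=float)
    if f.shape != (15,):
        raise ValueError("frequency vector must have 15 entries")
    pairs = np.array([(a, b) for a, b, _ in table.triples])
    w = f[pairs[:, 0] - 1] * f[pairs[:, 1] - 1]
    v = float(w.sum())
    if v > 0:
        w = w / v
    return pairs, w, v


def interaction_complexity(
    f: np.ndarray, table: Optional[CompositionTable] = None
) -> float:
    """C_mu(G): entropy (bits) of the productive-interaction distribution.

    Returns 0 (with a warning) for a degenerate population in which no
    productive interaction has positive probability.
    """
    _, w, v = interaction_distribution(f, table)
    if v <= 0:
        warnings.warn(
            "no productive interaction has positive probability; C_mu set to 0",
            stacklevel=2,
        )
        return 0.0
    return float(_shannon(w, base=2))


def production_complexity(
    f: np.ndarray, table: Optional[CompositionTable] = None
) -> float:
    """Entropy (bits) of the same weights aggregated per product type.

    This is the type-level reading of the complexity measure: the
    probability of producing type c is sum of f_a f_b / V over the pairs
    with product c.  Bounded by log2(15); kept distinct from
    :func:`interaction_complexity`, which is the niche-complexity measure.
    """
    if table is None:
        table = build_composition_table()
    pairs, w, v = interaction_distribution(f, table)
    if v <= 0:
        warnings.warn(
            "no productive interaction has positive probability; entropy set to 0",
            stacklevel=2,
        )
        return 0.0
    products = table.product[pairs[:, 0], pairs[:, 1]].astype(int)
    mass = np.bincount(products, weights=w, minlength=16)[1:]
    return float(_shannon(mass[mass > 0], base=2))


def production_threshold(
    subset: Iterable[int], table: Optional[CompositionTable] = None
) -> float:
    """H(X): entropy (bits) of products of within-subset interactions.

    `subset` is a niche's surviving composition (type ids).  Raises if the
    subset admits no productive interaction, in which case the threshold
    is undefined.
    """
    if table is None:
        table = build_composition_table()
    pw = productive_pairs_within(subset, table)
    if not pw.pairs:
        raise ValueError(
            f"subset {sorted(pw.subset)} admits no productive interaction; "
            "production threshold undefined"
        )
    counts = np.array(list(pw.product_counts.values()), dtype=float)
    return float(_shannon(counts, base=2))


def product_count_distribution(
    subset: Iterable[int], table: Optional[CompositionTable] = None
) -> Dict[int, int]:
    """Per-type counts of within-subset productive interactions."""
    if table is None:
        table = build_composition_table()
    return productive_pairs_within(subset, table).product_counts
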