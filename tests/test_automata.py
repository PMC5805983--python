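"""Composition algebra of the 15 one-state transducers."""

import itertools

import numpy as np
import pytest

from infosoup import AutomatonType, compose, productive_pairs_within
from infosoup.automata import BIT_SWAP_RELABEL, mask_of, transitions_of

from conftest import NINE_SURVIVORS, RELABEL


def _compose_sets(sa, sb):
    """Relational composition on transition sets (independent oracle)."""
    return frozenset(
        (x, z) for x, y1 in sa for y2, z in sb if y1 == y2
    )


class TestTypeEncoding:
    def test_masks_round_trip(self):
        for t in range(16):
            assert mask_of(transitions_of(t)) == t

    @pytest.mark.parametrize(
        "type_id,expected",
        [(3, {(0, 0), (0, 1)}), (13, {(0, 0), (1, 0), (1, 1)}), (0, set())],
    )
    def test_documented_transition_sets(self, type_id, expected):
        assert transitions_of(type_id) == frozenset(expected)

    def test_transition_count_classes(self):
        by_count = {k: {t for t in range(1, 16) if AutomatonType(t).n_transitions == k}
                    for k in (1, 2, 3, 4)}
        assert by_count[1] == {1, 2, 4, 8}
        assert by_count[2] == {3, 5, 6, 9, 10, 12}
        assert by_count[3] == {7, 11, 13, 14}
        assert by_count[4] == {15}


class TestCompose:
    @pytest.mark.parametrize(
        "first,second,product",
        [
            (13, 2, 10),  # the worked signal-chaining example
            (8, 8, 8),
            (2, 2, 0),    # range of T2 disjoint from its own domain
            (9, 6, 6),
            (6, 6, 9),
            (6, 9, 6),
        ],
    )
    def test_examples(self, first, second, product):
        assert compose(first, second) == product

    def test_matches_set_level_oracle(self):
        for a in range(1, 16):
            for b in range(1, 16):
                expected = mask_of(_compose_sets(transitions_of(a), transitions_of(b)))
                assert compose(a, b) == expected

    def test_associative_on_transition_sets(self):
        sets = {t: transitions_of(t) for t in range(1, 16)}
        for a, b, c in itertools.product(range(1, 16), repeat=3):
            left = _compose_sets(_compose_sets(sets[a], sets[b]), sets[c])
            right = _compose_sets(sets[a], _compose_sets(sets[b], sets[c]))
            assert left == right

    def test_t9_is_two_sided_identity(self):
        for a in range(1, 16):
            assert compose(a, 9) == a
            assert compose(9, a) == a

    def test_t15_is_total(self):
        for a in range(1, 16):
            assert compose(a, 15) != 0
            assert compose(15, a) != 0

    def test_monotone_in_both_operands(self):
        # adding a transition to either operand never shrinks the product
        for a in range(1, 16):
            for b in range(1, 16):
                base = compose(a, b)
                for bit in (1, 2, 4, 8):
                    if not a & bit:
                        assert compose(a | bit, b) & base == base
                    if not b & bit:
                        assert compose(a, b | bit) & base == base

    def test_commutes_with_alphabet_relabelling(self):
        for a in range(1, 16):
            for b in range(1, 16):
                assert compose(RELABEL[a], RELABEL[b]) == BIT_SWAP_RELABEL[compose(a, b)]

    @pytest.mark.parametrize("bad", [0, 16, -1])
    def test_rejects_non_members(self, bad):
        with pytest.raises(ValueError):
            compose(bad, 1)
        with pytest.raises(ValueError):
            compose(1, bad)


class TestCompositionTable:
    def test_productive_count(self, table):
        assert table.n_productive == 207
        assert len(table.producers[0]) == 225 - 207

    def test_producers_inverse_of_product(self, table):
        for c in range(16):
            for a, b in table.producers[c]:
                assert table.product[a, b] == c
        assert sum(len(p) for p in table.producers.values()) == 225

    def test_t15_produced_by_35_pairs(self, table):
        assert len(table.producers[15]) == 35

    def test_closure(self, table):
        assert set(np.unique(table.product)) <= set(range(16))

    def test_self_replicators(self, table):
        # every type whose transition relation has a fixed point composes
        # with itself to itself; {2,4} and {6,7,14} map elsewhere
        assert table.self_replicators() == frozenset({1, 3, 5, 8, 9, 10, 11, 12, 13, 15})

    def test_matrix_and_json_export(self, table, tmp_path):
        m = table.as_matrix()
        assert m.shape == (15, 15)
        assert (m[8] == [t for t in range(1, 16)]).all()  # row of the identity T9
        j = table.to_json()
        assert j["n_productive"] == 207
        csv = tmp_path / "table.csv"
        table.to_csv(csv)
        import pandas as pd

        back = pd.read_csv(csv, index_col=0)
        assert (back.to_numpy() == m).all()


class TestProductivePairsWithin:
    def test_single_transition_niche(self, table):
        pw = productive_pairs_within({1, 2, 4, 8}, table)
        assert len(pw.pairs) == 8
        assert pw.closed

    def test_nine_survivors(self, table):
        pw = productive_pairs_within(NINE_SURVIVORS, table)
        assert len(pw.pairs) == 63

    def test_six_nine_pair(self, table):
        pw = productive_pairs_within({6, 9}, table)
        assert pw.pairs == {(6, 6), (6, 9), (9, 6), (9, 9)}
        assert pw.closed
        assert pw.product_counts == {9: 2, 6: 2}

    def test_leakage_reported(self, table):
        pw = productive_pairs_within({2, 7, 10}, table)
        assert not pw.closed
        assert any(c == 5 for _, _, c in pw.leakage)

    def test_empty_subset_rejected(self, table):
        with pytest.raises(ValueError):
            productive_pairs_within(set(), table)
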