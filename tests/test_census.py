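"""Census of self-producing sub-networks and the niche hierarchy."""

import itertools

import networkx as nx
import pytest

from infosoup import (
    build_hierarchy,
    classify,
    elementary_networks,
    full_census,
    is_candidate_strong,
    is_network,
    production_graph,
    stable_networks,
)

from conftest import FOUR_SET, NINE_SURVIVORS

#: the six two-type networks into which the intermediate level of the
#: nine-survivor niche decomposes, plus the two documented small networks
DOCUMENTED_ELEMENTARY = [
    {1, 3}, {1, 5}, {3, 12}, {5, 10}, {8, 10}, {8, 12}, {6, 9}, {1, 2, 4, 8},
]


class TestProductionGraph:
    def test_edges_point_at_products(self, table):
        g = production_graph({6, 9}, table)
        assert set(g.edges()) == {(6, 9), (9, 6), (6, 6), (9, 9)}
        assert g.nodes[9]["self_producing"]

    def test_weights_count_participations(self, table):
        g = production_graph(FOUR_SET, table)
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert total == 2 * 8  # two participants per productive pair


class TestCandidateRules:
    @pytest.mark.parametrize(
        "subset,expected",
        [
            (FOUR_SET, True),
            ({6, 9}, True),
            ({2, 7, 10}, False),  # T2 is produced by no within-subset pair
            ({1, 3}, True),
            ({3, 15}, True),
        ],
    )
    def test_candidate_examples(self, table, subset, expected):
        assert is_candidate_strong(subset, table) is expected

    def test_network_degree_rule_examples(self, table):
        assert is_network(FOUR_SET, table)
        assert is_network({1, 3}, table)
        # T1 is produced only by its own self-replication within {1,2}
        assert not is_network({1, 2}, table)
        assert not is_network({2, 6}, table)

    def test_candidates_are_networks(self, table):
        for size in (2, 3):
            for combo in itertools.combinations(range(1, 16), size):
                if is_candidate_strong(set(combo), table):
                    assert is_network(set(combo), table)

    def test_small_subsets_match_naive_oracle(self, table):
        # independent edge-listing implementation of strong connectivity
        for size in (2, 3, 4):
            for combo in itertools.combinations(range(1, 16), size):
                sub = set(combo)
                g = nx.DiGraph()
                g.add_nodes_from(sub)
                for a in sub:
                    for b in sub:
                        c = int(table.product[a, b])
                        if c and c in sub:
                            g.add_edge(a, c)
                            g.add_edge(b, c)
                naive = g.number_of_edges() > 0 and nx.is_strongly_connected(g)
                assert is_candidate_strong(sub, table) is naive


class TestClassification:
    def test_four_set_elementary(self, table):
        assert classify(FOUR_SET, table).classification == "elementary"

    def test_six_nine_elementary(self, table):
        assert classify({6, 9}, table).classification == "elementary"

    def test_nine_survivors_stable_not_elementary(self, table):
        rec = classify(NINE_SURVIVORS, table)
        assert rec.classification == "stable"

    def test_full_population_not_stable(self, table):
        # the full production graph splits into three strongly connected
        # blocks ({nine survivors}, {7,11,13,14}, {6,9}), so the complete
        # 15-type set is a general network, not a mutually-producing one
        rec = classify(set(range(1, 16)), table)
        assert rec.classification == "general"

    def test_leaky_candidate(self, table):
        # {1,2,4} is strongly connected but (4,2) -> T8 leaks outside
        rec = classify({1, 2, 4}, table)
        assert rec.classification == "candidate"
        assert any(c == 8 for _, _, c in rec.leakage)

    def test_stable_networks_closed(self, table):
        from infosoup import productive_pairs_within

        for s in stable_networks(table):
            assert productive_pairs_within(s, table).closed

    def test_monotone_hierarchy(self, table):
        stab = set(stable_networks(table))
        elem = set(elementary_networks(table))
        assert elem <= stab
        assert all(is_candidate_strong(s, table) for s in stab)
        assert len(elem) <= len(stab)

    def test_elementary_contains_documented_networks(self, table):
        elem = {frozenset(s) for s in elementary_networks(table)}
        for s in DOCUMENTED_ELEMENTARY:
            assert frozenset(s) in elem

    def test_elementary_are_minimal(self, table):
        stab = set(stable_networks(table))
        for e in elementary_networks(table):
            assert not any(o < e for o in stab)


@pytest.fixture(scope="module")
def census():
    return full_census()


class TestFullCensus:
    def test_summary_consistency(self, census):
        s = census.summary
        assert s["subsets_scanned"] == 32752
        assert s["networks"] == s["general"] + s["candidates"]
        assert s["elementary"] <= s["stable"] <= s["candidates"] <= s["networks"]

    def test_stable_and_elementary_counts(self, census):
        assert census.summary["stable"] == 29
        assert census.summary["elementary"] == 12
        # the stable class splits into 17 reducible + 12 elementary
        assert census.summary["stable"] - census.summary["elementary"] == 17

    def test_network_count(self, census):
        assert census.summary["networks"] == 7831

    def test_deterministic(self, census):
        again = full_census()
        assert again.summary == census.summary
        assert [r.subset for r in again.records] == [r.subset for r in census.records]

    def test_matches_single_subset_classifier(self, census, table):
        by_subset = {r.subset: r.classification for r in census.records}
        for sub in (frozenset(FOUR_SET), frozenset({6, 9}), frozenset(NINE_SURVIVORS)):
            assert by_subset[sub] == classify(sub, table).classification


class TestHierarchy:
    def test_nine_survivor_niche(self, table):
        h = build_hierarchy(NINE_SURVIVORS, table)
        assert len(h.levels[0]) == 11  # all elementary networks except {6,9}
        assert frozenset({6, 9}) not in set(h.levels[0])
        assert not h.non_hierarchical
        # redundancy: every type produced by >= 2 elementary networks
        # except the pair T2, T4 (members of the single {1,2,4,8} network)
        for t, n in h.redundancy.items():
            if t in (2, 4):
                assert n == 1
            else:
                assert n >= 2

    def test_four_set_niche_non_hierarchical(self, table):
        h = build_hierarchy(FOUR_SET, table)
        assert h.levels == [[frozenset(FOUR_SET)]]
        assert h.non_hierarchical

    def test_unstable_niche_rejected(self, table):
        with pytest.raises(ValueError):
            build_hierarchy({2, 7, 10}, table)
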