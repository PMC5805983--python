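"""The composition algebra of the 15 one-state automata.

Builds the 16x16 product table and prints the interaction counts that
shape everything downstream: how many ordered pairs compose successfully,
and how production concentrates on the four-transition machine T15.
"""

from infosoup import build_composition_table, compose, productive_pairs_within

table = build_composition_table()

print("ordered pairs:", 15 * 15)
print("productive (non-T0) pairs:", table.n_productive)
print("pairs producing T15:", len(table.producers[15]))
print()
print("worked example: the signal passes T13 then T2 ->", f"T{compose(13, 2)}")
print("  (T13's outputs {0,0,1} are re-transduced by T2, leaving {0->1, 1->1})")
print()
for subset in ({1, 2, 4, 8}, {6, 9}, {1, 2, 3, 4, 5, 8, 10, 12, 15}):
    pw = productive_pairs_within(subset)
    print(f"within {sorted(subset)}: {len(pw.pairs)} productive pairs, "
          f"closed={pw.closed}")
print()
print("A closed subset keeps all of its products inside itself - the")
print("precondition for a self-maintaining production network.")
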