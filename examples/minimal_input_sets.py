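"""Enumerating every distinct minimal input combination for a target.

A diamond network (A -> O and B -> O through separate events) has two
redundant routes; the minimal-input-set query quantifies that redundancy by
integer cuts, and the brute-force oracle confirms it on this small system.
"""

from siglogic import (
    BooleanSystem, SignallingEvent, brute_force_minimal_input_sets,
    minimal_input_sets,
)

diamond = BooleanSystem.from_events([
    SignallingEvent("e1", frozenset({"A"}), frozenset({"O"})),
    SignallingEvent("e2", frozenset({"B"}), frozenset({"O"})),
])

mis = minimal_input_sets(diamond, {"O": 1})
print(f"minimal input sets for O=1: {mis.as_sorted_lists()}")
print(f"set count (redundancy metric): {mis.size}")
print(f"integer problems solved: {mis.n_problems}")

oracle = brute_force_minimal_input_sets(diamond, {"O": 1})
print(f"brute-force oracle agrees: {oracle.sets == mis.sets}")

# Two singleton sets {A} and {B}: either input alone activates O, and
# neither set is contained in the other (the result is an antichain).
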