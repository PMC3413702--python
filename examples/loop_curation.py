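"""Why logical loops must be curated before asking Minimum Input.

The model: input I produces X; X and J form the complex X:J; the complex is
converted to X:J'; dissociation releases J' and recycles X.  The recycling
edge forms a strongly connected component that lets the solver justify X
from downstream, so the uncurated answer for "what must be supplied to
activate J'?" is too small.
"""

from siglogic import (
    apply_dissociation_fix, build_dependency_graph, find_sccs, minimum_input,
    toy_loop_model,
)

system = toy_loop_model()
res = minimum_input(system, {"J'": 1})
print(f"uncurated minimum input for J': {res.objective_value}  "
      f"(J={res.assignment['J']}, I={res.assignment['I']})")

report = find_sccs(build_dependency_graph(system), system)
for comp, kind in zip(report.components, report.classification):
    print(f"SCC [{kind}]: {', '.join(sorted(comp))}")

curated, action = apply_dissociation_fix(system, report.components[0])
print(f"fix applied: {action.note}")
res = minimum_input(curated, {"J'": 1})
print(f"curated minimum input for J': {res.objective_value}  "
      f"(J={res.assignment['J']}, I={res.assignment['I']})")

# Uncurated the answer is 1 (J alone); after removing the recycled X from
# the dissociation outputs, both I and J are required -- the biologically
# correct requirement.
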