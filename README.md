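# siglogic

Boolean steady-state modelling of cellular signalling networks via binary
integer programming.

Curated databases of signal transduction (Reactome, Panther Pathways,
NCI-Nature PID) now describe thousands of reactions, far beyond what
kinetically parameterised models can cover.  `siglogic` targets the
constraint-based middle ground: it compiles a set of *signalling events*
(reactions transducing information from active input signals — including
catalysts and activators — to output signals) into a system of Boolean
statements, translates that system into a binary integer program, and uses
exact optimisation to answer reachability and redundancy questions at
network scale.  It is a library first (the API below) with a thin
`siglogic` command-line wrapper; typical users are systems biologists who
want testable hypotheses about which receptor-level inputs can produce a
given downstream state.

## The model

Each signal *s* and each event *e* gets a binary variable.  An event with
inputs `x1..xk` and inhibitors `z1..zq` contributes the activation
equivalence

```
r_e  <=>  x1 ∧ … ∧ xk ∧ ¬z1 ∧ … ∧ ¬zq
```

and every produced signal *s* with producing reactions `r1..rp` contributes
the derivation equivalence

```
s  <=>  r1 ∨ … ∨ rp
```

Inhibition is attached at the **event** level: an inhibitor prevents a
signalling event from firing rather than deactivating a signal.  This keeps
the system feasible when an activator and an inhibitor co-occur (the output
is simply off) and ensures the *absence* of an inhibitor is never itself a
cause.  The statements are rewritten to CNF and each clause becomes one
linear constraint `Σ pos + Σ (1 − neg) ≥ 1` over 0/1 variables; HiGHS
(via `scipy.optimize.milp`) solves the programs exactly.

Three query types are provided:

* **Minimum Input** — `min Σ inputs` subject to a fixed target state: the
  fewest system inputs that must be active to produce the state.
* **Output Maximization** — `max Σ outputs` given (partially) fixed inputs.
* **Minimal Input Sets (MIS)** — all pairwise-distinct, individually
  minimal input combinations achieving the target, enumerated by recursive
  single-variable integer cuts (each solution of size *j* spawns *j*
  descendants fixing one active input to 0) rather than the exponential
  powerset of cuts.  The set count is a redundancy metric.

Logical loops (recycled catalysts, complex-dissociation cycles) let the
solver "bootstrap" internal species and under-report input requirements, so
a curation subsystem detects strongly connected components in the
dependency graph, auto-fixes the two canonical motifs, and round-trips GML
for manual editing in Cytoscape.

## Worked example

```python
from siglogic import (apply_dissociation_fix, build_dependency_graph,
                      find_sccs, minimum_input, toy_loop_model)

system = toy_loop_model()          # I→X; X,J→X:J; X:J→X:J'; X:J'→X,J'
res = minimum_input(system, {"J'": 1})
print(res.objective_value)         # 1  (J alone appears sufficient)

report = find_sccs(build_dependency_graph(system), system)
print(report.classification)       # ('complex-dissociation',)

curated, action = apply_dissociation_fix(system, report.components[0])
print(minimum_input(curated, {"J'": 1}).objective_value)   # 2  (I and J)
```

Uncurated, the dissociation event recycles `X`, the loop justifies itself,
and one input is reported.  After the fix removes `X` from the dissociation
outputs, both upstream inputs are (correctly) required.  The scripts in
`examples/` walk through inhibition semantics, loop curation, MIS
enumeration and network statistics; each prints the numbers shown in its
trailing comment.

Models are read from BioPAX Level 3 OWL files (`read_biopax`) or from the
plain-text SIGTXT format (`read_sigtext`); results are written as TSV
summaries and GML visualisations.  From a shell:

```
siglogic solve model.sig --problem min-input --fix "J'=1"
siglogic curate model.owl --gml-out model.gml --out curated.sig
siglogic summarize curated.sig --out summary.tsv
```

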