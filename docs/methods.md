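# Methods

## Model and assumptions

A signalling system is a pair (signals, events).  Signals are physical
entities — proteins, complexes, small molecules, RNAs — each carried by one
binary variable (active/inactive).  A signalling event is a reaction step
with a conjunctive input set (upstream signals, catalysts and activating
signals are treated identically: all are required), a non-empty output set,
and an optional set of event-specific inhibitors; each event gets one
reaction variable shared by all of its outputs.  General inhibitions
("signal I prevents signalling by S") are lowered onto every event that
produces S.

The model is steady-state and non-parametric: no stoichiometry, quantities,
compartments (beyond identity) or time.  All events fire instantaneously,
so an oscillation appears as the union of the states it visits, and kinetic
competition between events is representable only if stated explicitly as
inhibition.  Complexes are first-class signals (labelled with `:` joining
their components); component signals are not implicitly activated by
complex activity.

### Statement semantics

Statements are encoded as *equivalences*, not one-way implications:

* `r_e <=> AND(inputs) AND NOT(each inhibitor)` — an event fires exactly
  when its condition holds;
* `s <=> OR(producing reactions)` — a produced signal is active exactly
  when some producer fired (signals with no producer are free variables,
  the system inputs).

One-way implications were rejected because they (i) let an output be active
with no cause, making Minimum Input trivially 0, (ii) make activator +
inhibitor co-occurrence contradictory under the naive signal-level
inhibition encoding, and (iii) fail to reproduce the two-completion
behaviour of the dissociation loop that the curation machinery is built
around.  The flawed one-way encoding is kept in the test suite as a
negative control only.

An event listing the same signal as input and inhibitor is accepted
(compiled as a permanently inactive event, with a warning): the tautological
completion clause is dropped and the pairwise clauses force the reaction
variable to 0.

## CNF and integer translation

Each activation equivalence with k inputs and q inhibitors yields k+q
binary clauses plus one completion clause; each derivation with p producers
yields p+1 clauses.  A clause becomes the constraint
`Σ positive vars + Σ (1 − negated vars) ≥ 1`; the 0/1 feasible set equals
the CNF satisfaction set (verified exhaustively in tests for systems of
≤ 15 variables).  Statements are processed sorted by consequent id so the
emitted clause list, constraint matrix and LP export are byte-stable.

Solving uses HiGHS through `scipy.optimize.milp` behind a four-field
adapter (`status`, `assignment`, `objective_value`, errors).  Proven
infeasibility is a regular result; any other solver failure raises, never
masquerading as infeasibility.  Tie-breaking among co-optimal assignments
is deliberately unconstrained; all downstream algorithms are correct for
any optimal witness.

## Queries

**Minimum Input.**  Fix the target state (any signals), objective
`Σ system-input variables`, minimize (or maximize on request).  System
inputs are signals on the input side of ≥ 1 event (inhibitor roles count as
input-side) and never produced.

**Output Maximization.**  Fix input states, objective `Σ system outputs`,
maximize.  Unfixed inputs are free by default or forced inactive with
`free_inputs_allowed=False`.  Fixing a non-input raises in strict mode.

**Minimal Input Sets.**  Depth-first tree of integer cuts: solve Minimum
Input; a solution activating inputs `{s1..sj}` spawns j children, each
adding the cut `s_i = 0` to all ancestor cuts; recurse until infeasible.
Properties used:

* every returned active set is globally inclusion-minimal (a strict subset
  would be a cheaper feasible point of the same node);
* every inclusion-minimal achievable set is returned (from any node whose
  cut set avoids it, the witness either equals it or contains a cuttable
  extra element).

Nodes are memoized on their cut set — without this, identical subproblems
recur factorially.  Survivors are deduplicated, superset-filtered, and each
is certified minimal by one extra solve (all other inputs fixed 0, demand
`Σ inputs ≤ |S| − 1`; infeasibility certifies).  A zero-cost root optimum
means the target is constitutive: empty set, flagged, terminate.  A
configurable solver-call budget (default 10⁶, comfortably above what batch
analyses of database-scale networks have needed) raises a resource error
carrying partial results.  Batch summaries share results across outputs
with identical producer sets (the redundancy-grouping check) and run
sequentially; the per-output table reports aggregates both over feasible,
non-constitutive outputs and over all outputs, since either averaging
convention is defensible.

**Brute-force oracle.**  Independent of the ILP path: clauses are evaluated
directly over bit-packed assignments.  Input combinations are visited by
ascending cardinality; a combination containing an already-achievable set
cannot be minimal and is skipped, so each achievable combination actually
tested is minimal.  Caps: ≤ 16 inputs, ≤ 24 total variables.

## Curation

Dependency graph: one node per variable, edge u → v iff u occurs in the
antecedent of a statement with consequent v (inhibitor literals included).
SCCs come from networkx's strongly-connected-components algorithm
(Tarjan-equivalent, linear time), reported only when of order ≥ 2 or a
self-loop singleton — trivial singletons are not loops and would swamp the
counts.  Two motifs are fixed automatically when the match is unambiguous:

* **catalysis** (order-2 SCC `{C, r}`, C ∈ inputs ∩ outputs of r): remove C
  from the outputs.  Pre-fix the loop lets C justify itself, so products of
  r appear reachable without supplying C at all; the fix restores the
  genuine requirement.
* **complex dissociation**: the dissociation event is the SCC member with
  at least one output *outside* the component (the modified product) and
  one inside it that feeds another SCC event (the recycled reactant); the
  recycled reactant is removed from its outputs.  Multiple candidate
  (event, reactant) pairs make the match ambiguous: the fix then demands an
  explicit choice, because automatic depth-first edge deletion can remove
  the complex-*formation* dependency instead, after which the complex is
  achievable without ever supplying the reactant (kept as a negative
  control in the tests).

Everything else is manual by design: the dependency graph exports to GML
(deterministic node/edge order; provenance as a graph attribute, since GML
has no comment syntax), is edited externally (e.g. Cytoscape), and
re-imported — deleted edges remove the corresponding antecedent literal or
derivation membership, deleted nodes remove the signal/event and incident
statements.  An unedited round trip is the identity on the statement set.
Source/sink classification is recomputed after every action and the delta
reported, since breaking a loop can expose new system inputs and outputs.

Graph statistics: order, size; degree maxima over signal nodes (a species,
not a reaction — the number of events it enters/leaves); source/sink counts
per the input/output definitions above; non-trivial SCC count; mean
undirected neighbour count; characteristic path length as the mean finite
directed shortest-path length over ordered reachable pairs (self-pairs
excluded); diameter as the maximum finite shortest path; radius as the
minimum positive eccentricity over nodes reaching at least one other node.
The path-statistic conventions are tool-dependent in the wider literature;
these were fixed once and documented rather than tuned.

## Input formats

BioPAX Level 3 OWL is parsed with rdflib (Level 2 files are rejected with a
clear message).  Mapping: reaction `left` → inputs, `right` → outputs;
Catalysis/Control controllers with activating control types join the
inputs; controls with an `INHIBITION*` control type become event inhibitors
when the controlled element resolves (possibly through a Catalysis) to a
reaction, and general inhibitions when it is a physical entity.  This
control-type mapping is a documented decision — the vocabulary used by
upstream exporters varies — and lives in one function for adjustment.
Complexes take their identity from the sorted multiset of component names
joined with `:`.  Ids are deterministic across runs.

SIGTXT is the package's own line format (`SIGNAL`, `EVENT ... IN/OUT/INH/
CAT`, `GENINH`; `#` comments; double quotes protect whitespace/commas in
ids).  `CAT` merges into inputs at compile time.  Round trips are lossless,
and serialized files start with a provenance comment (tool version, content
hash).

## Synthetic data

`FixtureSpec`/`random_system` generates layered acyclic systems: inputs
feed events whose outputs occupy strictly increasing layers, so the only
cycles are planted motifs (catalysis and dissociation loops inserted
verbatim on fresh signals), giving exact ground truth for SCC counts and
classifications.  Optional output reuse (`p_reuse`) creates multi-producer
derivation statements while preserving acyclicity; optional inhibitors are
drawn from input signals.  Defaults (30 inputs, 100 internal signals, 50
events) follow the typical scale of randomly generated signalling networks
in the literature; oracle-comparison tests use schedules of 2–8 inputs and
3–7 events so exhaustive enumeration stays within its 24-variable cap.
What the generator does **not** emulate: realistic degree distributions,
crosstalk structure, or the density of real interactomes — passing tests
demonstrate algorithmic correctness on exactly-known ground truth, not
biological fidelity of any particular database.

## Known limitations

* No time parameterisation or kinetics (by design; see assumptions).
* Database-scale runs are supported but not exercised here; the properties
  that make them feasible (single cuts vs powerset descendants, cut-set
  memoization, redundancy grouping, call-count instrumentation) are tested
  on small systems instead.
* The BioPAX control-type mapping covers the common Reactome/Panther
  vocabulary; exotic control types fall back to activation with a log
  entry.
* "Other"-class SCCs receive no automatic interpretation; they are left to
  the GML round trip.
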