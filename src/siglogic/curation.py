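"""Dependency-graph curation: SCC detection, loop fixes, GML round trip.

Logical loops in compiled signalling systems admit self-justifying
satisfying assignments: a complex that is dissolved back into its own
reactant lets the solver "bootstrap" the reactant from downstream, so the
Minimum Input problem under-reports what must actually be supplied.  The
remedy is structural: build the directed dependency graph over all
variables (an edge u -> v whenever u appears in the antecedent of a
statement with consequent v), find strongly connected components, and break
the two recurring biological motifs:

* **catalysis** -- an order-2 SCC {C, r} where the catalyst C is both input
  and output of the same event; the fix removes C from the outputs (C stays
  a required input).
* **complex dissociation** -- a complex forms, one member is modified, and
  the complex dissociates, recycling an unmodified member; the fix removes
  the recycled reactant from the dissociation event's outputs, keeping the
  modified product derivable while requiring the reactant to be genuinely
  supplied.

Curation is deliberately semi-automatic: the motif fixes apply only when
the pattern match is unambiguous; everything else goes through a GML export
for manual editing (e.g. in Cytoscape) and re-import, which deletes the
corresponding statements or literals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .boolean_model import BooleanSystem, classify_signals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SCCReport:
    """Non-trivial strongly connected components with motif classification."""

    components: tuple[frozenset[str], ...]
    classification: tuple[str, ...]  # catalysis | complex-dissociation | other

    def __len__(self) -> int:
        return len(self.components)

    def by_class(self, kind: str) -> list[frozenset[str]]:
        return [c for c, k in zip(self.components, self.classification)
                if k == kind]


@dataclass(frozen=True)
class CurationAction:
    """One structural edit applied to the system (strictly removes)."""

    kind: str  # remove-catalyst-output | remove-derivation-membership
    event_id: str
    signal_id: str
    note: str = ""


class AmbiguousMotifError(ValueError):
    """Motif fix needs a manual choice; candidates are attached."""

    def __init__(self, message: str, candidates):
        super().__init__(message)
        self.candidates = candidates


@dataclass(frozen=True)
class GraphStatistics:
    order: int
    size: int
    max_indegree: int
    max_outdegree: int
    n_sinks: int
    n_sources: int
    n_nontrivial_sccs: int
    avg_neighbours: float
    characteristic_path_length: float
    diameter: int
    radius: int


def build_dependency_graph(system: BooleanSystem) -> nx.DiGraph:
    """Directed graph over all variables; u -> v iff u is in the antecedent
    of a statement whose consequent is v (inhibitors included)."""
    g = nx.DiGraph()
    for var in system.variables:
        cls = "signal" if var in system.signals else "reaction"
        g.add_node(var, cls=cls)
    for st in system.statements:
        for lit in st.antecedent:
            g.add_edge(lit.variable, st.consequent)
    return g


def find_sccs(graph: nx.DiGraph, system: BooleanSystem | None = None) -> SCCReport:
    """All maximal SCCs of order >= 2 (plus self-loop singletons), Tarjan-
    style, in deterministic order (sorted by smallest member id).

    If the originating system is supplied, each component is classified as a
    catalysis motif, a complex-dissociation motif, or other.
    """
    comps = []
    for comp in nx.strongly_connected_components(graph):
        if len(comp) >= 2 or graph.has_edge(next(iter(comp)), next(iter(comp))):
            comps.append(frozenset(comp))
    comps.sort(key=lambda c: min(c))
    kinds = tuple(_classify_scc(c, system) for c in comps)
    return SCCReport(tuple(comps), kinds)


def _classify_scc(comp: frozenset[str], system: BooleanSystem | None) -> str:
    if system is None:
        return "other"
    if len(comp) == 2:
        sig = [v for v in comp if v in system.signals]
        evt = [v for v in comp if v in system.events]
        if len(sig) == 1 and len(evt) == 1:
            ev = system.events[evt[0]]
            if sig[0] in ev.inputs and sig[0] in ev.outputs:
                return "catalysis"
        return "other"
    if _dissociation_candidates(comp, system):
        return "complex-dissociation"
    return "other"


def _dissociation_candidates(comp, system):
    """(event, recycled signal) pairs fitting the dissociation motif.

    The dissociation event sits in the SCC, releases at least one product
    outside the SCC (the modified species) and one inside it (the recycled
    reactant), and the recycled reactant feeds another event of the SCC.
    """
    if system is None:
        return []
    pairs = []
    for eid in sorted(comp):
        if eid not in system.events:
            continue
        ev = system.events[eid]
        released_outside = ev.outputs - comp
        if not released_outside:
            continue
        for sig in sorted(ev.outputs & comp):
            if sig not in system.signals:
                continue
            feeds = any(
                sig in system.events[other].inputs
                for other in comp if other in system.events and other != eid)
            if feeds:
                pairs.append((eid, sig))
    return pairs


def _remove_output(system: BooleanSystem, event_id: str,
                   signal_id: str) -> BooleanSystem:
    out = system.copy()
    ev = out.events[event_id]
    if len(ev.outputs) == 1:
        raise ValueError(
            f"removing {signal_id!r} would empty outputs of {event_id!r}")
    ev.outputs = ev.outputs - {signal_id}
    out.recompile()
    return out


def apply_catalysis_fix(system: BooleanSystem,
                        scc: frozenset[str]) -> tuple[BooleanSystem, CurationAction]:
    """Break an order-2 catalysis SCC {C, r}: drop C from the outputs of r.

    C remains a required input; the derivation statement of C loses its
    membership for r (and disappears entirely if r was the only producer).
    """
    if len(scc) != 2:
        raise ValueError(f"catalysis fix needs an order-2 SCC, got {sorted(scc)}")
    sig = [v for v in scc if v in system.signals]
    evt = [v for v in scc if v in system.events]
    if len(sig) != 1 or len(evt) != 1:
        raise ValueError(f"SCC {sorted(scc)} is not a {{signal, event}} pair")
    catalyst, eid = sig[0], evt[0]
    ev = system.events[eid]
    if catalyst not in ev.inputs or catalyst not in ev.outputs:
        raise ValueError(
            f"SCC {sorted(scc)} does not match the catalysis motif")
    fixed = _remove_output(system, eid, catalyst)
    action = CurationAction(
        "remove-catalyst-output", eid, catalyst,
        note=f"catalyst {catalyst} removed from outputs of {eid}")
    return fixed, action


def apply_dissociation_fix(
    system: BooleanSystem,
    scc: frozenset[str],
    recycled: tuple[str, str] | None = None,
) -> tuple[BooleanSystem, CurationAction]:
    """Break a complex-dissociation SCC by un-recycling one reactant.

    The recycled reactant is removed from the dissociation event's outputs;
    forming the complex then genuinely requires the reactant, while the
    modified product stays derivable.  If several (event, signal) pairs
    match the motif the choice is manual: an :class:`AmbiguousMotifError`
    lists the candidates, one of which can be passed as ``recycled``.
    """
    candidates = _dissociation_candidates(scc, system)
    if not candidates:
        raise ValueError(
            f"SCC {sorted(scc)} does not match the dissociation motif")
    if recycled is not None:
        if tuple(recycled) not in candidates:
            raise ValueError(
                f"{recycled} is not a motif candidate; options: {candidates}")
        eid, sig = recycled
    elif len(candidates) > 1:
        raise AmbiguousMotifError(
            f"multiple recycled-reactant candidates in SCC {sorted(scc)}: "
            f"{candidates}; pass recycled=(event, signal)", candidates)
    else:
        eid, sig = candidates[0]
    fixed = _remove_output(system, eid, sig)
    action = CurationAction(
        "remove-derivation-membership", eid, sig,
        note=f"recycled reactant {sig} removed from outputs of {eid}")
    return fixed, action


def curate_all(system: BooleanSystem,
               max_rounds: int = 100) -> tuple[BooleanSystem, list[CurationAction]]:
    """Apply catalysis and unambiguous dissociation fixes until no
    classifiable SCC remains; ambiguous or 'other' SCCs are left for the
    GML round trip."""
    actions: list[CurationAction] = []
    for _ in range(max_rounds):
        report = find_sccs(build_dependency_graph(system), system)
        progressed = False
        for comp, kind in zip(report.components, report.classification):
            try:
                if kind == "catalysis":
                    system, act = apply_catalysis_fix(system, comp)
                elif kind == "complex-dissociation":
                    system, act = apply_dissociation_fix(system, comp)
                else:
                    continue
            except AmbiguousMotifError as err:
                logger.warning("manual curation needed: %s", err)
                continue
            actions.append(act)
            progressed = True
            break  # graph changed; re-detect
        if not progressed:
            break
    return system, actions


def classification_delta(before: BooleanSystem,
                         after: BooleanSystem) -> dict[str, set[str]]:
    """Source/sink changes caused by curation.

    Breaking a loop can expose previously obscured system inputs and
    outputs (a recycled catalyst with no other producer becomes terminal);
    classification is recomputed after every action and the delta reported.
    """
    b_src, b_snk, _, _ = classify_signals(before)
    a_src, a_snk, _, _ = classify_signals(after)
    return {
        "new_sources": a_src - b_src,
        "lost_sources": b_src - a_src,
        "new_sinks": a_snk - b_snk,
        "lost_sinks": b_snk - a_snk,
    }


# -- GML round trip --------------------------------------------------------

def export_gml(system: BooleanSystem, path, provenance: str = "") -> None:
    """Write the dependency graph as GML for external (manual) curation.

    Node attributes: ``label``, ``cls`` (signal|reaction), ``xref``.  Node
    and edge order is deterministic for diffability.  GML has no comment
    syntax, so provenance is stored as a graph attribute.
    """
    g = nx.DiGraph()
    if provenance:
        g.graph["provenance"] = provenance
    dep = build_dependency_graph(system)
    for node in sorted(dep.nodes):
        if node in system.signals:
            sig = system.signals[node]
            xref = ";".join(f"{db}:{acc}" for db, acc in sig.xrefs)
            g.add_node(node, label=sig.name or node, cls="signal", xref=xref)
        else:
            g.add_node(node, label=node, cls="reaction", xref="")
    for u, v in sorted(dep.edges):
        g.add_edge(u, v)
    nx.write_gml(g, path)


def import_curated_gml(system: BooleanSystem, path) -> BooleanSystem:
    """Re-import an externally edited GML and apply the deletions.

    Deleting an edge removes the corresponding antecedent literal (input or
    inhibitor) or derivation membership (event output); deleting a node
    removes the signal or event and all incident statements.  An unedited
    round trip is the identity on the statement set.
    """
    try:
        g = nx.read_gml(path)
    except Exception as err:  # malformed GML
        raise ValueError(f"cannot parse GML {path}: {err}") from err
    known = set(system.variables)
    unknown = set(g.nodes) - known
    if unknown:
        raise ValueError(
            f"GML {path} references unknown nodes: {sorted(unknown)}")
    kept_nodes = set(g.nodes)
    kept_edges = set(g.edges)

    out = system.copy()
    # Drop deleted signals and events.
    out.signals = {sid: s for sid, s in out.signals.items()
                   if sid in kept_nodes}
    out.events = {eid: ev for eid, ev in out.events.items()
                  if eid in kept_nodes}
    out.general_inhibitions = [
        (i, t) for i, t in out.general_inhibitions
        if i in kept_nodes and t in kept_nodes]
    # Apply edge deletions and scrub references to deleted signals.
    dead_events = []
    for eid, ev in out.events.items():
        ev.inputs = frozenset(
            s for s in ev.inputs
            if s in kept_nodes and (s, eid) in kept_edges)
        ev.inhibitors = frozenset(
            s for s in ev.inhibitors
            if s in kept_nodes and (s, eid) in kept_edges)
        ev.outputs = frozenset(
            s for s in ev.outputs
            if s in kept_nodes and (eid, s) in kept_edges)
        if not ev.outputs:
            logger.warning("event %s lost all outputs during curation; "
                           "removed", eid)
            dead_events.append(eid)
    for eid in dead_events:
        del out.events[eid]
    out.recompile()
    return out


# -- statistics -------------------------------------------------------------

def graph_statistics(graph: nx.DiGraph,
                     system: BooleanSystem | None = None) -> GraphStatistics:
    """Topology statistics of the dependency graph.

    Degree maxima and source/sink counts are over *signal* nodes (a species,
    not a reaction).  Path statistics are directed, over reachable ordered
    pairs only; radius is the minimum positive eccentricity among nodes that
    reach at least one other node.
    """
    signals = [n for n, d in graph.nodes(data=True)
               if d.get("cls", "signal") == "signal"]
    if system is not None:
        signals = [n for n in graph.nodes if n in system.signals]
        sources, sinks, _, _ = classify_signals(system)
        n_sources, n_sinks = len(sources), len(sinks)
    else:
        n_sources = sum(1 for n in signals
                        if graph.in_degree(n) == 0 and graph.out_degree(n) > 0)
        n_sinks = sum(1 for n in signals
                      if graph.out_degree(n) == 0 and graph.in_degree(n) > 0)
    max_in = max((graph.in_degree(n) for n in signals), default=0)
    max_out = max((graph.out_degree(n) for n in signals), default=0)
    n_scc = len(find_sccs(graph, system))
    und = graph.to_undirected()
    avg_neigh = (sum(len(list(und.neighbors(n))) for n in und.nodes)
                 / und.number_of_nodes()) if und.number_of_nodes() else 0.0

    total, count = 0, 0
    diameter = 0
    eccentricities = []
    for node in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, node)
        finite = [d for tgt, d in lengths.items() if tgt != node]
        if finite:
            total += sum(finite)
            count += len(finite)
            ecc = max(finite)
            diameter = max(diameter, ecc)
            eccentricities.append(ecc)
    cpl = total / count if count else float("nan")
    radius = min(eccentricities) if eccentricities else 0
    return GraphStatistics(
        order=graph.number_of_nodes(),
        size=graph.number_of_edges(),
        max_indegree=max_in,
        max_outdegree=max_out,
        n_sinks=n_sinks,
        n_sources=n_sources,
        n_nontrivial_sccs=n_scc,
        avg_neighbours=avg_neigh,
        characteristic_path_length=cpl,
        diameter=diameter,
        radius=radius,
    )
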