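"""Reading and writing model descriptions and results.

Two input routes produce the same in-memory events:

* **BioPAX Level 3** OWL (the community exchange format used by Reactome,
  Panther and the NCI-Nature PID exports), parsed with :mod:`rdflib`.  Each
  biochemical reaction becomes one signalling event: left participants are
  inputs, right participants outputs, catalysis controllers join the inputs,
  and inhibitory controls become event-specific inhibitors (or general
  inhibitions when they target an entity rather than a reaction).
* **SIGTXT**, a line-oriented plain-text format for fixtures and interchange
  (see :func:`read_sigtext`).

Outputs: SIGTXT, tab-delimited summaries (in :mod:`siglogic.problems`) and
GML solution visualizations where every variable appears as a node coloured
by its 0/1 state.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import networkx as nx
from rdflib import Graph, RDF, Namespace

from .boolean_model import BooleanSystem, Signal, SignallingEvent

logger = logging.getLogger(__name__)

BP3 = Namespace("http://www.biopax.org/release/biopax-level3.owl#")
BP2_URI = "http://www.biopax.org/release/biopax-level2.owl#"

_REACTION_TYPES = (
    "BiochemicalReaction", "ComplexAssembly", "Transport",
    "TransportWithBiochemicalReaction", "Conversion", "Degradation",
)


def _version() -> str:
    from . import __version__
    return __version__


def provenance_line(input_hash: str = "", seed=None) -> str:
    parts = [f"siglogic v{_version()}"]
    if input_hash:
        parts.append(f"input-sha1={input_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def _sha1(text: str) -> str:
    return hashlib.sha1(text.encode("utf-8")).hexdigest()[:12]


# -- SIGTXT -----------------------------------------------------------------

def _tokenize(line: str) -> list[list[str]]:
    """Split a line into fields; fields split on commas into atoms.

    Double quotes protect whitespace, commas and ``#`` inside ids; a bare
    ``#`` starts a comment.
    """
    fields: list[list[str]] = []
    atoms: list[str] = []
    cur: list[str] = []
    has_atom = False
    in_quotes = False

    def end_atom():
        nonlocal cur, has_atom
        if has_atom:
            atoms.append("".join(cur))
        cur = []
        has_atom = False

    def end_field():
        nonlocal atoms
        end_atom()
        if atoms:
            fields.append(atoms)
        atoms = []

    for ch in line:
        if in_quotes:
            if ch == '"':
                in_quotes = False
            else:
                cur.append(ch)
        elif ch == '"':
            in_quotes = True
            has_atom = True
        elif ch == "#":
            break
        elif ch == ",":
            end_atom()
        elif ch.isspace():
            end_field()
        else:
            cur.append(ch)
            has_atom = True
    if in_quotes:
        raise ValueError("unterminated quote")
    end_field()
    return fields


def _quote(atom: str) -> str:
    if any(c.isspace() for c in atom) or any(c in atom for c in '",#'):
        return '"' + atom + '"'
    return atom


class SigtextError(ValueError):
    pass


def parse_sigtext(text: str) -> tuple[
        list[SignallingEvent], list[tuple[str, str]], dict[str, Signal]]:
    """Parse SIGTXT content into (events, general inhibitions, signals).

    Directives (one per line, ``#`` comments, ids with whitespace quoted)::

        SIGNAL <id> [NAME <label>] [XREF <db>:<acc>]...
        EVENT <id> [IN <id>[,<id>...]] OUT <id>[,<id>...]
              [INH <id>[,...]] [CAT <id>[,...]]
        GENINH <inhibitor-id> OF <signal-id>

    CAT lists catalysts, merged into the conjunctive inputs at compile time.
    Line order is irrelevant to the resulting system.
    """
    events: list[SignallingEvent] = []
    seen_event_ids: set[str] = set()
    geninh: list[tuple[str, str]] = []
    signals: dict[str, Signal] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        try:
            fields = _tokenize(raw)
        except ValueError as err:
            raise SigtextError(f"line {lineno}: {err}") from err
        if not fields:
            continue
        directive = fields[0][0]
        try:
            if directive == "SIGNAL":
                signals.update(_parse_signal(fields))
            elif directive == "EVENT":
                ev = _parse_event(fields)
                if ev.id in seen_event_ids:
                    raise SigtextError(f"duplicate event id {ev.id!r}")
                seen_event_ids.add(ev.id)
                events.append(ev)
            elif directive == "GENINH":
                # GENINH <inh> OF <target>
                if len(fields) != 4 or fields[2] != ["OF"]:
                    raise SigtextError("expected: GENINH <id> OF <id>")
                geninh.append((fields[1][0], fields[3][0]))
            else:
                raise SigtextError(f"unknown directive {directive!r}")
        except SigtextError as err:
            raise SigtextError(f"line {lineno}: {err}") from None
    return events, geninh, signals


def _parse_signal(fields: list[list[str]]) -> dict[str, Signal]:
    if len(fields) < 2:
        raise SigtextError("SIGNAL needs an id")
    sid = fields[1][0]
    name = sid
    xrefs: list[tuple[str, str]] = []
    i = 2
    while i < len(fields):
        key = fields[i][0]
        if key == "NAME":
            if i + 1 >= len(fields):
                raise SigtextError("NAME needs a value")
            name = fields[i + 1][0]
            i += 2
        elif key == "XREF":
            if i + 1 >= len(fields):
                raise SigtextError("XREF needs db:acc")
            db, _, acc = fields[i + 1][0].partition(":")
            xrefs.append((db, acc))
            i += 2
        else:
            raise SigtextError(f"unknown SIGNAL attribute {key!r}")
    return {sid: Signal(sid, name=name, xrefs=tuple(xrefs))}


def _parse_event(fields: list[list[str]]) -> SignallingEvent:
    if len(fields) < 2:
        raise SigtextError("EVENT needs an id")
    eid = fields[1][0]
    parts: dict[str, list[str]] = {}
    i = 2
    while i < len(fields):
        key = fields[i][0]
        if key not in ("IN", "OUT", "INH", "CAT"):
            raise SigtextError(f"unknown EVENT section {key!r}")
        if i + 1 >= len(fields):
            raise SigtextError(f"{key} needs a signal list")
        parts[key] = fields[i + 1]
        i += 2
    if "OUT" not in parts:
        raise SigtextError("EVENT needs an OUT list")
    inputs = set(parts.get("IN", [])) | set(parts.get("CAT", []))
    return SignallingEvent(
        eid, inputs=frozenset(inputs),
        outputs=frozenset(parts["OUT"]),
        inhibitors=frozenset(parts.get("INH", [])))


def serialize_sigtext(
    events: list[SignallingEvent],
    general_inhibitions: list[tuple[str, str]] | None = None,
    signals: dict[str, Signal] | None = None,
    provenance: bool = True,
) -> str:
    lines = []
    body: list[str] = []
    for sid in sorted(signals or {}):
        sig = (signals or {})[sid]
        parts = ["SIGNAL", _quote(sid)]
        if sig.name and sig.name != sid:
            parts += ["NAME", _quote(sig.name)]
        for db, acc in sig.xrefs:
            parts += ["XREF", _quote(f"{db}:{acc}")]
        body.append(" ".join(parts))
    for ev in sorted(events, key=lambda e: e.id):
        parts = ["EVENT", _quote(ev.id)]
        if ev.inputs:
            parts += ["IN", ",".join(_quote(s) for s in sorted(ev.inputs))]
        parts += ["OUT", ",".join(_quote(s) for s in sorted(ev.outputs))]
        if ev.inhibitors:
            parts += ["INH", ",".join(_quote(s) for s in sorted(ev.inhibitors))]
        body.append(" ".join(parts))
    for inh, target in sorted(general_inhibitions or []):
        body.append(f"GENINH {_quote(inh)} OF {_quote(target)}")
    text = "\n".join(body) + "\n"
    if provenance:
        lines.append(f"# {provenance_line(input_hash=_sha1(text))}")
    lines.append(text)
    return "\n".join(lines)


def read_sigtext(path) -> BooleanSystem:
    """Read a SIGTXT file into a compiled system."""
    text = Path(path).read_text(encoding="utf-8")
    events, geninh, signals = parse_sigtext(text)
    return BooleanSystem.from_events(events, signals=signals,
                                     general_inhibitions=geninh)


def write_sigtext(system: BooleanSystem, path) -> None:
    """Serialize a system's events (lossless SIGTXT round trip).

    General inhibitions are emitted as GENINH lines; the inhibitors they
    lowered onto events are omitted from INH lists so re-reading
    reconstructs the identical system.
    """
    gen = set(system.general_inhibitions)
    events = []
    for ev in system.events.values():
        lowered = {
            inh for (inh, target) in gen
            if inh in ev.inhibitors and target in ev.outputs}
        events.append(SignallingEvent(
            ev.id, inputs=ev.inputs, outputs=ev.outputs,
            inhibitors=ev.inhibitors - lowered))
    meta = {sid: sig for sid, sig in system.signals.items()}
    Path(path).write_text(
        serialize_sigtext(events, sorted(gen), meta), encoding="utf-8")


# -- BioPAX -----------------------------------------------------------------

class BioPAXError(ValueError):
    pass


def read_biopax(path) -> tuple[
        list[SignallingEvent], list[tuple[str, str]], dict[str, Signal]]:
    """Read a BioPAX Level 3 OWL file.

    Returns ``(events, general_inhibitions, signals)`` ready for
    :meth:`BooleanSystem.from_events`.  Mapping: reaction left participants
    and catalysis controllers become conjunctive inputs, right participants
    outputs; Control/Modulation with an INHIBITION control type becomes an
    event inhibitor when it (possibly via a Catalysis) targets a reaction,
    and a general inhibition when it targets a physical entity.  A complex
    is a single signal identified by its component multiset, joined with
    ``:``.  Ids are deterministic across runs.
    """
    g = Graph()
    try:
        g.parse(str(path))
    except Exception as err:
        raise BioPAXError(f"cannot parse {path}: {err}") from err
    if any(str(t).startswith(BP2_URI)
           for t in set(g.objects(None, RDF.type))):
        raise BioPAXError(
            f"{path} is BioPAX Level 2; only Level 3 is supported")

    names: dict = {}

    def entity_id(node) -> str:
        if node in names:
            return names[node]
        components = sorted(
            entity_id(c) for c in g.objects(node, BP3.component))
        if components:
            sid = ":".join(components)
        else:
            sid = None
            for prop in (BP3.displayName, BP3.standardName, BP3.name):
                val = g.value(node, prop)
                if val is not None:
                    sid = str(val)
                    break
            if sid is None:
                sid = str(node).rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        names[node] = sid
        return sid

    def entity_xrefs(node):
        xrefs = []
        for xr in g.objects(node, BP3.xref):
            db = g.value(xr, BP3.db)
            acc = g.value(xr, BP3.id)
            if db is not None and acc is not None:
                xrefs.append((str(db), str(acc)))
        return tuple(sorted(xrefs))

    reactions = set()
    for tname in _REACTION_TYPES:
        reactions |= set(g.subjects(RDF.type, BP3[tname]))
    reactions = sorted(reactions, key=str)

    signals: dict[str, Signal] = {}

    def register(node) -> str:
        sid = entity_id(node)
        if sid not in signals:
            signals[sid] = Signal(sid, name=sid, xrefs=entity_xrefs(node))
        return sid

    events: dict = {}
    event_ids: dict[str, str] = {}
    for rx in reactions:
        frag = str(rx).rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        eid = f"rx_{frag}"
        if eid in event_ids.values():
            eid = f"rx_{frag}_{len(event_ids)}"
        event_ids[str(rx)] = eid
        left = sorted(register(n) for n in g.objects(rx, BP3.left))
        right = sorted(register(n) for n in g.objects(rx, BP3.right))
        if not right:
            logger.warning("reaction %s has no products; skipped", frag)
            continue
        events[str(rx)] = {
            "id": eid, "inputs": set(left), "outputs": set(right),
            "inhibitors": set()}

    general_inhibitions: list[tuple[str, str]] = []
    controls = set()
    for tname in ("Control", "Catalysis", "Modulation",
                  "TemplateReactionRegulation"):
        controls |= set(g.subjects(RDF.type, BP3[tname]))

    def resolve_reactions(node, depth=0):
        """Reaction URIs a control (possibly via another control) targets."""
        if depth > 3:
            return []
        if str(node) in events:
            return [str(node)]
        out = []
        for sub in g.objects(node, BP3.controlled):
            out.extend(resolve_reactions(sub, depth + 1))
        return out

    for ctrl in sorted(controls, key=str):
        ctype = g.value(ctrl, BP3.controlType)
        is_catalysis = (ctrl, RDF.type, BP3.Catalysis) in g
        inhibitory = ctype is not None and "INHIBITION" in str(ctype).upper()
        controllers = sorted(
            (n for n in g.objects(ctrl, BP3.controller)), key=str)
        controlled = list(g.objects(ctrl, BP3.controlled))
        if not controllers or not controlled:
            logger.warning("control %s has dangling references; skipped",
                           str(ctrl).rsplit('#', 1)[-1])
            continue
        for tgt in controlled:
            rx_keys = resolve_reactions(tgt)
            if rx_keys:
                for key in rx_keys:
                    for controller in controllers:
                        sid = register(controller)
                        if inhibitory:
                            events[key]["inhibitors"].add(sid)
                        else:
                            events[key]["inputs"].add(sid)
            elif inhibitory and (tgt, RDF.type, None) in g:
                # Inhibition of an entity's activity: general inhibition.
                target_sid = register(tgt)
                for controller in controllers:
                    general_inhibitions.append(
                        (register(controller), target_sid))
            else:
                logger.warning(
                    "control target %s unresolved; skipped",
                    str(tgt).rsplit('#', 1)[-1])
        _ = is_catalysis  # catalysis and activation map identically

    out_events = [
        SignallingEvent(e["id"], inputs=frozenset(e["inputs"]),
                        outputs=frozenset(e["outputs"]),
                        inhibitors=frozenset(e["inhibitors"]))
        for e in sorted(events.values(), key=lambda e: e["id"])]
    return out_events, sorted(set(general_inhibitions)), signals


# -- solution GML -----------------------------------------------------------

def write_solution_gml(system: BooleanSystem, assignment: dict[str, int],
                       path, provenance: str = "") -> None:
    """Write a solved network state as GML for Cytoscape/Graphviz.

    Hypergraph-style rendering: reaction nodes link their participant
    signals, as in biochemical diagrams.  Every variable appears once with a
    ``state`` attribute (0 = species absent, 1 = present).  Output is
    deterministic; an incomplete assignment is an error.
    """
    missing = [v for v in system.variables if v not in assignment]
    if missing:
        raise ValueError(f"assignment missing variables: {missing}")
    g = nx.DiGraph()
    g.graph["provenance"] = provenance or provenance_line()
    for var in sorted(system.variables):
        cls = "signal" if var in system.signals else "reaction"
        label = (system.signals[var].name or var) if cls == "signal" else var
        g.add_node(var, label=label, cls=cls, state=int(assignment[var]))
    edges = set()
    for ev in system.events.values():
        for s in ev.inputs:
            edges.add((s, ev.id, "input"))
        for s in ev.outputs:
            edges.add((ev.id, s, "output"))
        for s in ev.inhibitors:
            edges.add((s, ev.id, "inhibition"))
    for u, v, role in sorted(edges):
        g.add_edge(u, v, role=role)
    nx.write_gml(g, path)
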