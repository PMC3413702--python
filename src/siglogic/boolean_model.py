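"""Compile signalling events into a Boolean statement system.

A signalling network is described by *signals* (proteins, complexes, small
molecules, RNAs) and *signalling events* -- reactions transducing information
from a conjunctive set of active input signals (upstream signals, catalysts,
activators) to a set of output signals.  Each event gets a dedicated binary
*reaction variable*; each signal gets a binary *signal variable* in bijection
with the physical entity.

The compiled system holds two statement kinds:

* ``event-activation``: the reaction variable is active exactly when every
  event input is active and every event inhibitor is inactive.  Inhibition is
  attached here, at the event level, as negated literals -- an inhibitor
  blocks the *event*, it does not deactivate a signal.  This keeps the system
  feasible when an activator and an inhibitor co-occur.
* ``output-derivation``: a produced signal is active exactly when at least
  one of its producing reactions is active.  There is exactly one such
  statement per produced signal.

General (signal-level) inhibitions are lowered onto every event producing the
target signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

EVENT_ACTIVATION = "event-activation"
OUTPUT_DERIVATION = "output-derivation"


@dataclass(frozen=True)
class Signal:
    """A physical entity carrying signal state (protein, complex, ...)."""

    id: str
    name: str = ""
    xrefs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if not self.id:
            raise ValueError("signal id must be non-empty")


@dataclass
class SignallingEvent:
    """One reaction step: conjunctive inputs -> outputs, blocked by inhibitors.

    ``inputs`` contains upstream signals, catalysts and activating signals
    alike -- all are required for the event to fire.  ``inhibitors`` are
    event-specific: any active member prevents this event only.
    """

    id: str
    inputs: frozenset[str] = frozenset()
    outputs: frozenset[str] = frozenset()
    inhibitors: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.id:
            raise ValueError("event id must be non-empty")
        self.inputs = frozenset(self.inputs)
        self.outputs = frozenset(self.outputs)
        self.inhibitors = frozenset(self.inhibitors)
        if not self.outputs:
            raise ValueError(f"event {self.id!r} has an empty output set")
        overlap = self.inputs & self.inhibitors
        if overlap:
            # Legal but suspicious: the event can never fire.
            logger.warning(
                "event %s: signals %s are both inputs and inhibitors; "
                "the event is permanently inactive", self.id, sorted(overlap))


@dataclass(frozen=True, order=True)
class Literal:
    """A signed occurrence of a binary variable in a statement antecedent."""

    variable: str
    sign: str = POSITIVE

    def __post_init__(self):
        if self.sign not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bad literal sign {self.sign!r}")

    @property
    def positive(self) -> bool:
        return self.sign == POSITIVE

    def negate(self) -> "Literal":
        return Literal(self.variable, NEGATIVE if self.positive else POSITIVE)

    def __str__(self) -> str:
        return self.variable if self.positive else f"!{self.variable}"


@dataclass(frozen=True)
class BooleanStatement:
    """antecedent (conjunction of literals) => consequent variable.

    Semantically the statement is an *equivalence*: the consequent holds iff
    the antecedent condition holds (for derivations, iff at least one
    producing reaction is active).
    """

    kind: str
    antecedent: frozenset[Literal]
    consequent: str

    def __post_init__(self):
        if self.kind not in (EVENT_ACTIVATION, OUTPUT_DERIVATION):
            raise ValueError(f"bad statement kind {self.kind!r}")
        object.__setattr__(self, "antecedent", frozenset(self.antecedent))
        if self.kind == OUTPUT_DERIVATION:
            if any(not lit.positive for lit in self.antecedent):
                raise ValueError(
                    "output-derivation antecedents are positive literals only")

    def __str__(self) -> str:
        lhs = " & ".join(str(l) for l in sorted(self.antecedent))
        return f"{lhs or 'TRUE'} => {self.consequent}"


@dataclass
class BooleanSystem:
    """The compiled logical model: signals, events and their statements."""

    signals: dict[str, Signal]
    events: dict[str, SignallingEvent]
    statements: list[BooleanStatement]
    general_inhibitions: list[tuple[str, str]] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_events(
        cls,
        events: list[SignallingEvent],
        signals: dict[str, Signal] | None = None,
        general_inhibitions: list[tuple[str, str]] | None = None,
    ) -> "BooleanSystem":
        """Compile a full system from its event list.

        Signal metadata is optional; signals referenced by events but absent
        from ``signals`` get bare ``Signal`` records.
        """
        event_map: dict[str, SignallingEvent] = {}
        for ev in events:
            if ev.id in event_map:
                raise ValueError(f"duplicate event id {ev.id!r}")
            event_map[ev.id] = ev
        signal_ids: set[str] = set()
        for ev in event_map.values():
            signal_ids |= ev.inputs | ev.outputs | ev.inhibitors
        clash = signal_ids & set(event_map)
        if clash:
            raise ValueError(f"ids used as both signal and event: {sorted(clash)}")
        signal_map = dict(signals or {})
        for sid in signal_ids:
            signal_map.setdefault(sid, Signal(sid, name=sid))
        system = cls(
            signals=signal_map,
            events=event_map,
            statements=compile_statements(list(event_map.values())),
            general_inhibitions=[],
        )
        if general_inhibitions:
            system = attach_inhibitors(system, {}, general_inhibitions)
        return system

    def recompile(self) -> None:
        """Rebuild all statements from the current event definitions."""
        self.statements = compile_statements(list(self.events.values()))
        gen = self.general_inhibitions
        self.general_inhibitions = []
        _apply_general(self, gen)

    # -- queries ----------------------------------------------------------

    @property
    def variables(self) -> list[str]:
        """All binary variables: signal ids then event ids, sorted."""
        return sorted(self.signals) + sorted(self.events)

    def producers_of(self, signal_id: str) -> set[str]:
        return {ev.id for ev in self.events.values() if signal_id in ev.outputs}

    def activation_statement(self, event_id: str) -> BooleanStatement:
        for st in self.statements:
            if st.kind == EVENT_ACTIVATION and st.consequent == event_id:
                return st
        raise KeyError(event_id)

    def derivation_statement(self, signal_id: str) -> BooleanStatement | None:
        for st in self.statements:
            if st.kind == OUTPUT_DERIVATION and st.consequent == signal_id:
                return st
        return None

    def copy(self) -> "BooleanSystem":
        return BooleanSystem(
            signals=dict(self.signals),
            events={eid: replace(ev) for eid, ev in self.events.items()},
            statements=list(self.statements),
            general_inhibitions=list(self.general_inhibitions),
        )


def compile_statements(events: list[SignallingEvent]) -> list[BooleanStatement]:
    """Translate events into activation and derivation statements.

    Produces one event-activation statement per event (conjunction of its
    inputs implying the reaction variable) and, for every signal produced by
    at least one event, a single output-derivation statement listing all of
    its producing reactions.  Statement count is therefore
    ``len(events) + number of distinct produced signals``.
    """
    seen: set[str] = set()
    statements: list[BooleanStatement] = []
    produced: dict[str, set[str]] = {}
    for ev in events:
        if ev.id in seen:
            raise ValueError(f"duplicate event id {ev.id!r}")
        seen.add(ev.id)
        if not ev.outputs:
            raise ValueError(f"event {ev.id!r} has an empty output set")
        ante = {Literal(s) for s in ev.inputs}
        ante |= {Literal(s, NEGATIVE) for s in ev.inhibitors}
        statements.append(
            BooleanStatement(EVENT_ACTIVATION, frozenset(ante), ev.id))
        for out in ev.outputs:
            produced.setdefault(out, set()).add(ev.id)
    for sig in sorted(produced):
        ante = frozenset(Literal(r) for r in produced[sig])
        statements.append(BooleanStatement(OUTPUT_DERIVATION, ante, sig))
    return statements


def _apply_general(system: BooleanSystem,
                   general_inhibitions: list[tuple[str, str]]) -> None:
    """Lower general inhibitions onto producing events, in place."""
    for inhibitor, target in general_inhibitions:
        producers = system.producers_of(target)
        if not producers:
            logger.warning(
                "general inhibition of %s by %s ignored: no producing events",
                target, inhibitor)
            if (inhibitor, target) not in system.general_inhibitions:
                system.general_inhibitions.append((inhibitor, target))
            continue
        for eid in producers:
            ev = system.events[eid]
            if inhibitor not in ev.inhibitors:
                ev.inhibitors = ev.inhibitors | {inhibitor}
        if (inhibitor, target) not in system.general_inhibitions:
            system.general_inhibitions.append((inhibitor, target))
    # Inhibitor signals may be new to the system.
    for inhibitor, _ in general_inhibitions:
        system.signals.setdefault(inhibitor, Signal(inhibitor, name=inhibitor))


def attach_inhibitors(
    system: BooleanSystem,
    event_inhibitions: dict[str, set[str]] | None = None,
    general_inhibitions: list[tuple[str, str]] | None = None,
) -> BooleanSystem:
    """Return a system with additional inhibition attached.

    Event-specific inhibitors become negated literals in that event's
    activation statement only.  A general inhibitor of signal ``S`` is added
    to every event producing ``S``.  The operation is idempotent: attaching
    the same inhibition twice changes nothing.
    """
    out = system.copy()
    for eid, inhibs in (event_inhibitions or {}).items():
        if eid not in out.events:
            raise KeyError(f"unknown event id {eid!r}")
        ev = out.events[eid]
        ev.inhibitors = ev.inhibitors | frozenset(inhibs)
        for sid in inhibs:
            out.signals.setdefault(sid, Signal(sid, name=sid))
    for inhibitor, target in (general_inhibitions or []):
        if target not in out.signals:
            raise KeyError(f"unknown signal id {target!r}")
    gen = list(general_inhibitions or [])
    prev_gen = out.general_inhibitions
    out.general_inhibitions = []
    out.statements = compile_statements(list(out.events.values()))
    _apply_general(out, prev_gen + gen)
    out.statements = compile_statements(list(out.events.values()))
    return out


def classify_signals(
    system: BooleanSystem,
) -> tuple[set[str], set[str], set[str], set[str]]:
    """Partition signals into (sources, sinks, internal, isolated).

    *System inputs* (sources) take part on the input side of at least one
    event -- as input or inhibitor -- but are never produced.  *System
    outputs* (sinks) are produced but never consumed.  *Internal* signals do
    both.  Signals referenced by no event are returned separately as
    isolated.
    """
    input_side: set[str] = set()
    output_side: set[str] = set()
    for ev in system.events.values():
        input_side |= ev.inputs | ev.inhibitors
        output_side |= ev.outputs
    sources = input_side - output_side
    sinks = output_side - input_side
    internal = input_side & output_side
    isolated = set(system.signals) - input_side - output_side
    return sources, sinks, internal, isolated
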