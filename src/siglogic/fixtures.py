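"""Deterministic model generators: worked toy systems and random networks.

The two toy models reproduce the canonical behaviours every other module is
tested against:

* :func:`toy_inhibition_model` -- one event ``S1 -> S2`` blocked by an
  event-level inhibitor ``I``; exercises the inhibition semantics (presence
  of the activator with the inhibitor absent activates the output; absence
  of the inhibitor alone does not; co-occurrence is feasible with the output
  off).
* :func:`toy_loop_model` -- complex formation/modification/dissociation
  loop: ``I`` produces ``X``; ``X`` and ``J`` form ``X:J``; ``X:J`` converts
  to ``X:J'``; dissociation yields ``X`` and ``J'``.  Uncurated, the
  recycled ``X`` lets the solver bootstrap the loop, so one input (``J``)
  suffices for ``J'``; after the dissociation fix both ``I`` and ``J`` are
  required.

:func:`random_system` generates layered acyclic systems with optional
planted catalysis / dissociation motifs, giving exact ground truth for SCC
counts and keeping within brute-force oracle caps.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .boolean_model import BooleanSystem, Signal, SignallingEvent


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random signalling system; same spec+seed gives a
    byte-identical system.

    Defaults follow the typical scale of randomly generated signalling
    networks in the literature: on the order of 150 signals driven by 50
    events.
    """

    n_inputs: int = 30
    n_internal: int = 100
    n_events: int = 50
    max_inputs_per_event: int = 3
    p_inhibit: float = 0.0
    p_reuse: float = 0.0
    acyclic: bool = True
    planted_catalysis: int = 0
    planted_dissociation: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("need at least one input signal")
        if self.n_events < 1:
            raise ValueError("need at least one event")
        if self.max_inputs_per_event < 1:
            raise ValueError("max_inputs_per_event must be >= 1")
        if not 0.0 <= self.p_inhibit <= 1.0:
            raise ValueError("p_inhibit must be a probability")


def toy_inhibition_model() -> BooleanSystem:
    """S1 activates S2 through one event; I inhibits that event."""
    ev = SignallingEvent("r1", inputs=frozenset({"S1"}),
                         outputs=frozenset({"S2"}),
                         inhibitors=frozenset({"I"}))
    return BooleanSystem.from_events([ev])


def toy_loop_model(curated: bool = False) -> BooleanSystem:
    """The complex-formation/dissociation loop (see module docstring).

    With ``curated=True`` the dissociation fix is pre-applied: ``X`` is no
    longer recycled by the dissociation event.
    """
    dissoc_outputs = {"J'"} if curated else {"X", "J'"}
    events = [
        SignallingEvent("r_X", inputs=frozenset({"I"}),
                        outputs=frozenset({"X"})),
        SignallingEvent("r_complex", inputs=frozenset({"X", "J"}),
                        outputs=frozenset({"X:J"})),
        SignallingEvent("r_convert", inputs=frozenset({"X:J"}),
                        outputs=frozenset({"X:J'"})),
        SignallingEvent("r_dissoc", inputs=frozenset({"X:J'"}),
                        outputs=frozenset(dissoc_outputs)),
    ]
    return BooleanSystem.from_events(events)


def mek_erk_model() -> BooleanSystem:
    """Kinase/substrate complex phosphorylation motif.

    Active MEK and ERK (each driven by an upstream input) form a complex;
    the complex phosphorylates ERK and dissociates, recycling MEK.  The
    recycling edge creates the same loop topology as the toy loop.
    """
    events = [
        SignallingEvent("r_act_MEK", inputs=frozenset({"up_MEK"}),
                        outputs=frozenset({"MEK"})),
        SignallingEvent("r_act_ERK", inputs=frozenset({"up_ERK"}),
                        outputs=frozenset({"ERK"})),
        SignallingEvent("r_form", inputs=frozenset({"MEK", "ERK"}),
                        outputs=frozenset({"MEK:ERK"})),
        SignallingEvent("r_phos", inputs=frozenset({"MEK:ERK"}),
                        outputs=frozenset({"MEK:ERKp"})),
        SignallingEvent("r_dissoc", inputs=frozenset({"MEK:ERKp"}),
                        outputs=frozenset({"ERKp", "MEK"})),
    ]
    return BooleanSystem.from_events(events)


def random_system(spec: FixtureSpec) -> BooleanSystem:
    """Generate a layered random signalling system.

    Inputs feed internal layers feed outputs; acyclic by construction, with
    cycles only via planted motifs (inserted verbatim on fresh signals so
    SCC detection must recover exactly the planted count).  Every produced
    signal is reachable from at least one input.
    """
    spec.validate()
    rng = random.Random(spec.seed)

    inputs = [f"in{i}" for i in range(spec.n_inputs)]
    internal = [f"sig{i}" for i in range(spec.n_internal)]
    events: list[SignallingEvent] = []
    signals: dict[str, Signal] = {}

    available = list(inputs)  # signals already producible / supplied
    layer = {s: 0 for s in inputs}
    produced: list[str] = []
    unproduced = list(internal)
    for e in range(spec.n_events):
        k = rng.randint(1, min(spec.max_inputs_per_event, len(available)))
        ins = rng.sample(available, k)
        max_in_layer = max(layer[s] for s in ins)
        out = None
        if spec.p_reuse > 0 and rng.random() < spec.p_reuse:
            # Reuse a produced signal from a strictly later layer so the
            # system stays acyclic (edges always increase layer).
            candidates = [s for s in produced
                          if layer[s] > max_in_layer and s not in ins]
            if candidates:
                out = rng.choice(candidates)
        if out is None:
            if unproduced:
                out = unproduced.pop(0)
            else:
                out = f"sig{spec.n_internal + e}"
            layer[out] = max_in_layer + 1
        inhibitors: set[str] = set()
        if spec.p_inhibit > 0 and rng.random() < spec.p_inhibit:
            pool = [s for s in inputs if s not in ins]
            if pool:
                inhibitors.add(rng.choice(pool))
        events.append(SignallingEvent(
            f"ev{e}", inputs=frozenset(ins), outputs=frozenset({out}),
            inhibitors=frozenset(inhibitors)))
        if out not in available:
            available.append(out)
            produced.append(out)

    for m in range(spec.planted_catalysis):
        c, x, y = f"cat{m}_C", f"cat{m}_X", f"cat{m}_Y"
        events.append(SignallingEvent(
            f"cat{m}_r", inputs=frozenset({c, x}),
            outputs=frozenset({c, y})))
    for m in range(spec.planted_dissociation):
        p = f"dis{m}_"
        events.extend([
            SignallingEvent(p + "r_X", inputs=frozenset({p + "I"}),
                            outputs=frozenset({p + "X"})),
            SignallingEvent(p + "r_complex",
                            inputs=frozenset({p + "X", p + "J"}),
                            outputs=frozenset({p + "XJ"})),
            SignallingEvent(p + "r_convert", inputs=frozenset({p + "XJ"}),
                            outputs=frozenset({p + "XJm"})),
            SignallingEvent(p + "r_dissoc", inputs=frozenset({p + "XJm"}),
                            outputs=frozenset({p + "X", p + "Jm"})),
        ])
    return BooleanSystem.from_events(events, signals=signals)
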