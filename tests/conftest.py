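"""Shared fixtures: small hand-built systems and random-model schedules."""

import pytest

from siglogic.boolean_model import BooleanSystem, SignallingEvent
from siglogic.fixtures import FixtureSpec


@pytest.fixture
def diamond():
    """Two independent routes to one output: A -> O and B -> O."""
    return BooleanSystem.from_events([
        SignallingEvent("e1", frozenset({"A"}), frozenset({"O"})),
        SignallingEvent("e2", frozenset({"B"}), frozenset({"O"})),
    ])


@pytest.fixture
def chain():
    """A -> B -> O single chain."""
    return BooleanSystem.from_events([
        SignallingEvent("e1", frozenset({"A"}), frozenset({"B"})),
        SignallingEvent("e2", frozenset({"B"}), frozenset({"O"})),
    ])


def oracle_spec(seed: int) -> FixtureSpec:
    """Random-system schedule for brute-force oracle comparisons.

    Sizes stay within the oracle caps (<= 8 inputs, <= 10 events, <= 24
    variables); inhibitors are present on odd seeds, and output reuse gives
    multi-producer derivation statements.
    """
    n_in = 2 + (seed * 5) % 7          # 2..8
    n_ev = 3 + (seed * 3) % 5          # 3..7
    while n_in + 2 * n_ev > 22:
        n_ev -= 1
    return FixtureSpec(
        n_inputs=n_in, n_internal=n_ev, n_events=n_ev,
        max_inputs_per_event=3,
        p_inhibit=0.4 if seed % 2 else 0.0,
        p_reuse=0.3, seed=seed)
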