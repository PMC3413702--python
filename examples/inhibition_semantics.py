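"""Event-level inhibition on the two-signal toy system.

S1 activates S2 through one signalling event; I inhibits that *event* (not
the signal S2).  The three printed cases show why this matters: the output
needs a cause (absence of the inhibitor is not one), and activator plus
inhibitor together stay feasible with the output simply off.
"""

from siglogic import output_maximization, toy_inhibition_model

system = toy_inhibition_model()
for s1, i in ((1, 0), (0, 0), (1, 1)):
    res = output_maximization(system, {"S1": s1, "I": i})
    print(f"S1={s1} I={i} -> feasible={res.optimal} S2={res.assignment['S2']}")

# S2 follows S1 only when the inhibitor is off; with I active the event is
# blocked and S2 stays 0 without making the system infeasible.
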