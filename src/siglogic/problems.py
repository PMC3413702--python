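"""Network queries: Minimum Input, Output Maximization, Minimal Input Sets.

All three queries share the same machinery: fix some signal variables,
attach an objective over system inputs or outputs, and solve the binary
integer program of the compiled system.

The Minimal Input Sets query quantifies redundancy: how many pairwise
distinct, individually minimal combinations of active system inputs produce
a target network state.  Two input combinations A and B are *distinct* iff
A \\ B and B \\ A are both non-empty, so the result is an antichain under
set inclusion.  Enumeration proceeds by iterative integer cuts: solve the
Minimum Input problem, then from a solution with j active inputs spawn j
descendant problems, each forcing one previously-active input to zero while
retaining every ancestor cut, and recurse until infeasible.  This
single-variable-cut strategy visits every minimal set while avoiding the
exponential powerset-of-cuts alternative (a 10-input solution would spawn
2**10 = 1024 powerset descendants at one step alone).

A brute-force enumerator over all input combinations doubles as the
correctness oracle for small systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .boolean_model import BooleanSystem, classify_signals
from .ilp_encoding import (
    MAXIMIZE,
    MINIMIZE,
    SolveResult,
    solve,
    system_ilp,
    to_cnf,
)

logger = logging.getLogger(__name__)

StateFixing = dict[str, int]


@dataclass
class SolveStats:
    """Counts integer problems solved (cost accounting / telemetry)."""

    calls: int = 0


class ResourceBudgetError(RuntimeError):
    """Solver-call budget exceeded; carries any partial result."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class MinimalInputSets:
    """Antichain of distinct minimal input combinations for a target state."""

    target: tuple[tuple[str, int], ...]
    sets: frozenset[frozenset[str]]
    constitutive: bool = False
    infeasible: bool = False
    n_problems: int = 0

    @property
    def size(self) -> int:
        return len(self.sets)

    def as_sorted_lists(self) -> list[list[str]]:
        return sorted(sorted(s) for s in self.sets)


@dataclass
class OutputSummary:
    """Per-output minimum-input / minimal-input-set table with aggregates."""

    rows: list[dict] = field(default_factory=list)

    @property
    def feasible_rows(self) -> list[dict]:
        return [r for r in self.rows
                if not r["infeasible"] and not r["constitutive"]]

    def _vals(self, key: str, feasible_only: bool) -> list[float]:
        rows = self.feasible_rows if feasible_only else self.rows
        return [r[key] for r in rows if r[key] is not None]

    def aggregates(self, feasible_only: bool = True) -> dict:
        mins = self._vals("min_input", feasible_only)
        sizes = self._vals("mis_size", feasible_only)
        return {
            "mean_min_input": _mean(mins),
            "median_min_input": _median(mins),
            "median_mis_size": _median(sizes),
            "pct_outputs_mis_gt1":
                (100.0 * sum(1 for s in sizes if s > 1) / len(sizes))
                if sizes else float("nan"),
        }


def _mean(xs):
    return sum(xs) / len(xs) if xs else float("nan")


def _median(xs):
    if not xs:
        return float("nan")
    xs = sorted(xs)
    n = len(xs)
    mid = n // 2
    return float(xs[mid]) if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0


def _check_target(system: BooleanSystem, target: StateFixing) -> None:
    for sid, val in target.items():
        if sid not in system.signals:
            raise KeyError(f"target references unknown signal {sid!r}")
        if val not in (0, 1):
            raise ValueError(f"target state {sid}={val} is not binary")


def minimum_input(
    system: BooleanSystem,
    target: StateFixing,
    direction: str = MINIMIZE,
    extra_fixings: StateFixing | None = None,
    stats: SolveStats | None = None,
) -> SolveResult:
    """Smallest (or largest) number of active system inputs achieving a
    target state.

    The target fixes any signals (outputs, internal nodes, even inputs); the
    objective is the sum of all system-input variables.  Returns the optimal
    count with one witness assignment, or infeasible.
    """
    _check_target(system, target)
    sources, _, _, _ = classify_signals(system)
    base = system_ilp(system)
    prob = base.with_objective({s: 1 for s in sorted(sources)}, direction)
    prob = prob.fixed(dict(target))
    if extra_fixings:
        prob = prob.fixed(dict(extra_fixings))
    if stats is not None:
        stats.calls += 1
    return solve(prob)


def output_maximization(
    system: BooleanSystem,
    input_states: StateFixing,
    free_inputs_allowed: bool = True,
    strict: bool = True,
    stats: SolveStats | None = None,
) -> SolveResult:
    """Maximal set of system outputs reachable from the given input states.

    Inputs absent from ``input_states`` stay free when
    ``free_inputs_allowed``, otherwise they are fixed inactive.  When every
    input is fixed the output set is unique and maximal.  Fixing a
    non-input signal raises in strict mode (warns otherwise).
    """
    _check_target(system, input_states)
    sources, sinks, _, _ = classify_signals(system)
    non_inputs = set(input_states) - sources
    if non_inputs:
        msg = f"fixed signals are not system inputs: {sorted(non_inputs)}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    prob = system_ilp(system).with_objective(
        {s: 1 for s in sorted(sinks)}, MAXIMIZE)
    fixings = dict(input_states)
    if not free_inputs_allowed:
        for s in sources:
            fixings.setdefault(s, 0)
    prob = prob.fixed(fixings)
    if stats is not None:
        stats.calls += 1
    return solve(prob)


def minimal_input_sets(
    system: BooleanSystem,
    target: StateFixing,
    max_problems: int = 10**6,
    stats: SolveStats | None = None,
) -> MinimalInputSets:
    """Enumerate all distinct minimal input combinations for a target state.

    Algorithm: solve Minimum Input; if infeasible, return the infeasible
    flag; if the optimum activates zero inputs the target is constitutive
    and the set is empty.  Otherwise each solution of size j spawns j
    descendants, one per active input, fixing that input to 0 on top of all
    ancestor cuts; recursion stops at infeasible nodes.  Identical cut sets
    are solved once.  Collected solutions are deduplicated, supersets
    discarded, and each survivor's minimality certified by a strictly-fewer-
    inputs feasibility probe.

    Raises :class:`ResourceBudgetError` (carrying partial results) if more
    than ``max_problems`` integer problems would be needed.
    """
    _check_target(system, target)
    stats = stats if stats is not None else SolveStats()
    sources, _, _, _ = classify_signals(system)
    sources = sorted(sources)
    base = system_ilp(system).with_objective({s: 1 for s in sources}, MINIMIZE)
    base = base.fixed(dict(target))
    target_key = tuple(sorted(target.items()))

    solutions: set[frozenset[str]] = set()
    seen_cuts: set[frozenset[str]] = set()
    n_problems = 0
    # Depth-first over cut sets; each node = set of inputs forced inactive.
    frontier: list[frozenset[str]] = [frozenset()]
    constitutive = False
    infeasible_root = False
    while frontier:
        cuts = frontier.pop()
        if cuts in seen_cuts:
            continue
        seen_cuts.add(cuts)
        if n_problems >= max_problems:
            raise ResourceBudgetError(
                f"solver-call budget of {max_problems} exceeded",
                partial=MinimalInputSets(
                    target_key, frozenset(_reduce(solutions)),
                    n_problems=n_problems))
        if any(base.fixings.get(s) == 1 for s in cuts):
            # Cut contradicts a target-fixed active input: infeasible.
            if not cuts:
                infeasible_root = True
            continue
        n_problems += 1
        stats.calls += 1
        res = solve(base.fixed({s: 0 for s in cuts}))
        if not res.optimal:
            if not cuts:
                infeasible_root = True
            continue
        active = frozenset(
            s for s in sources if res.assignment[s] == 1 and s not in cuts)
        if not active:
            if not cuts:
                constitutive = True
                break
            continue
        solutions.add(active)
        for s in sorted(active):
            frontier.append(cuts | {s})

    if infeasible_root:
        return MinimalInputSets(target_key, frozenset(), infeasible=True,
                                n_problems=n_problems)
    if constitutive:
        return MinimalInputSets(target_key, frozenset(), constitutive=True,
                                n_problems=n_problems)

    survivors = _reduce(solutions)
    # Certify minimality of each survivor: with all other inputs off and the
    # target fixed, demanding strictly fewer active inputs must be infeasible.
    certified = set()
    for cand in survivors:
        off = {s: 0 for s in sources if s not in cand}
        probe = base.fixed(off)
        probe.constraints = probe.constraints + [
            _card_le(sorted(cand), len(cand) - 1)]
        n_problems += 1
        stats.calls += 1
        if not solve(probe).optimal:
            certified.add(cand)
        else:
            logger.warning("dropping non-minimal candidate %s", sorted(cand))
    return MinimalInputSets(target_key, frozenset(certified),
                            n_problems=n_problems)


def _card_le(variables: list[str], k: int):
    from .ilp_encoding import ILPConstraint
    return ILPConstraint.from_dict({v: 1 for v in variables}, "<=", k)


def _reduce(solutions: set[frozenset[str]]) -> set[frozenset[str]]:
    """Drop duplicates and supersets, leaving an antichain."""
    out = set()
    for s in sorted(solutions, key=len):
        if not any(t < s for t in out):
            out.add(s)
    return out


def brute_force_minimal_input_sets(
    system: BooleanSystem,
    target: StateFixing,
    max_inputs: int = 16,
    max_variables: int = 24,
) -> MinimalInputSets:
    """Oracle enumeration: test every input combination exhaustively.

    For each input assignment, achievability of the target is decided by
    exhaustive satisfaction search over the remaining variables (clauses
    evaluated directly, no integer programming involved).  Combinations are
    visited by ascending cardinality; a combination containing an already
    achievable set cannot be minimal and is skipped, so every achievable
    combination actually tested is a minimal distinct set.
    """
    _check_target(system, target)
    sources, _, _, _ = classify_signals(system)
    sources = sorted(sources)
    variables = system.variables
    if len(sources) > max_inputs:
        raise ValueError(f"{len(sources)} inputs exceeds cap {max_inputs}")
    if len(variables) > max_variables:
        raise ValueError(
            f"{len(variables)} variables exceeds cap {max_variables}")
    index = {v: i for i, v in enumerate(variables)}
    # Bitmask clause representation for fast exhaustive evaluation.
    clause_masks = []
    for cl in to_cnf(system):
        pos = neg = 0
        for lit in cl.literals:
            if lit.positive:
                pos |= 1 << index[lit.variable]
            else:
                neg |= 1 << index[lit.variable]
        clause_masks.append((pos, neg))
    target_key = tuple(sorted(target.items()))

    fixed_pos = {index[s]: v for s, v in target.items()}
    source_bits = {s: index[s] for s in sources}
    free_positions = [i for v, i in index.items()
                      if i not in fixed_pos and v not in source_bits]
    base_target = sum(1 << i for i, v in fixed_pos.items() if v)

    def achievable(active: frozenset[str]) -> bool:
        base = base_target
        for s in sources:
            want = 1 if s in active else 0
            pos = source_bits[s]
            if pos in fixed_pos and fixed_pos[pos] != want:
                return False  # conflicts with a target-fixed input
            base |= want << pos
        for combo in range(1 << len(free_positions)):
            x = base
            t = combo
            for p in free_positions:
                x |= (t & 1) << p
                t >>= 1
            if all((x & pos) or (neg & ~x) for pos, neg in clause_masks):
                return True
        return False

    minimal: list[frozenset[str]] = []
    any_achievable = False
    for k in range(len(sources) + 1):
        for combo in combinations(sources, k):
            s = frozenset(combo)
            if any(m <= s for m in minimal):
                continue  # contains an achievable set: not minimal
            if achievable(s):
                any_achievable = True
                if k == 0:
                    return MinimalInputSets(
                        target_key, frozenset(), constitutive=True)
                minimal.append(s)
    if not any_achievable:
        return MinimalInputSets(target_key, frozenset(), infeasible=True)
    return MinimalInputSets(target_key, frozenset(minimal))


def powerset_descendant_count(n: int) -> int:
    """Descendant count of the rejected powerset-of-cuts strategy: 2**n."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return 2 ** n


def redundant_output_groups(system: BooleanSystem) -> list[list[str]]:
    """Group system outputs whose producing-reaction sets are identical.

    Batch analyses compute once per group and copy the result to the other
    members, saving solver calls.
    """
    _, sinks, _, _ = classify_signals(system)
    groups: dict[frozenset[str], list[str]] = {}
    for out in sorted(sinks):
        key = frozenset(system.producers_of(out))
        groups.setdefault(key, []).append(out)
    return sorted(groups.values())


def summarize_outputs(
    system: BooleanSystem,
    max_problems_per_output: int = 10**6,
    group_redundant: bool = True,
    stats: SolveStats | None = None,
) -> OutputSummary:
    """Per-output minimum input and minimal-input-set size, with aggregates.

    Every system output is fixed active in turn; outputs sharing an
    identical producer set are computed once and copied.  Resource errors on
    one output are recorded in its row without aborting the batch.
    """
    stats = stats if stats is not None else SolveStats()
    groups = redundant_output_groups(system)
    if not group_redundant:
        groups = [[out] for grp in groups for out in grp]
    summary = OutputSummary()
    for group in groups:
        rep = group[0]
        row = _analyse_output(system, rep, max_problems_per_output, stats)
        for out in group:
            r = dict(row)
            r["id"] = out
            r["name"] = system.signals[out].name or out
            r["copied_from"] = rep if out != rep else None
            summary.rows.append(r)
    summary.rows.sort(key=lambda r: r["id"])
    return summary


def _analyse_output(system, output_id, max_problems, stats):
    row = {
        "id": output_id, "name": output_id, "min_input": None,
        "mis_size": None, "constitutive": False, "infeasible": False,
        "budget_exceeded": False, "copied_from": None,
    }
    res = minimum_input(system, {output_id: 1}, stats=stats)
    if not res.optimal:
        row["infeasible"] = True
        return row
    row["min_input"] = res.objective_value
    try:
        mis = minimal_input_sets(system, {output_id: 1},
                                 max_problems=max_problems, stats=stats)
    except ResourceBudgetError as err:
        row["budget_exceeded"] = True
        row["mis_size"] = err.partial.size if err.partial else None
        return row
    row["mis_size"] = mis.size
    row["constitutive"] = mis.constitutive
    if mis.constitutive:
        row["min_input"] = 0
    return row


def summary_to_tsv(summary: OutputSummary, provenance: str = "") -> str:
    """Render the per-output table as TSV with an aggregate footer."""
    lines = []
    if provenance:
        lines.append(f"# {provenance}")
    lines.append("id\tname\tmin_input\tmis_size\tconstitutive\tinfeasible")
    for r in summary.rows:
        lines.append("\t".join([
            r["id"], r["name"],
            "" if r["min_input"] is None else str(r["min_input"]),
            "" if r["mis_size"] is None else str(r["mis_size"]),
            "1" if r["constitutive"] else "0",
            "1" if r["infeasible"] else "0",
        ]))
    for label, feas in (("feasible-only", True), ("all-outputs", False)):
        agg = summary.aggregates(feasible_only=feas)
        lines.append(
            f"# aggregate[{label}]"
            f"\tmean_min_input={agg['mean_min_input']:.4g}"
            f"\tmedian_min_input={agg['median_min_input']:.4g}"
            f"\tmedian_mis_size={agg['median_mis_size']:.4g}"
            f"\tpct_outputs_mis_gt1={agg['pct_outputs_mis_gt1']:.4g}")
    return "\n".join(lines) + "\n"
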