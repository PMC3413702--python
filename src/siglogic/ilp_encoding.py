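"""CNF rewriting of the Boolean system and its binary integer program.

Each compiled statement is encoded as a logical *equivalence*:

* activation ``r <=> x1 & ... & xk & !z1 & ... & !zq`` yields the clauses
  ``(!r | xi)`` for every input, ``(!r | !zj)`` for every inhibitor, and the
  completion clause ``(r | !x1 | ... | !xk | z1 | ... | zq)``;
* derivation ``s <=> r1 | ... | rp`` yields ``(!s | r1 | ... | rp)`` and
  ``(s | !ri)`` per producer.

Equivalence (rather than one-way implication) is what gives the intended
steady-state semantics: a signal cannot be active without a cause, and an
inhibited event forces its reaction variable off without forcing the output
signal into contradiction.

Each CNF clause then becomes one linear constraint over binary variables:
``sum(positive vars) + sum(1 - negated vars) >= 1``.  Satisfying assignments
of the CNF and feasible 0/1 points of the integer program coincide.  Solving
is delegated to an exact MILP back end (HiGHS via ``scipy.optimize.milp``)
behind a narrow adapter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .boolean_model import (
    BooleanSystem,
    EVENT_ACTIVATION,
    Literal,
    NEGATIVE,
)

MINIMIZE = "minimize"
MAXIMIZE = "maximize"


class SolverError(RuntimeError):
    """The MILP back end failed (limit hit, numerical trouble) -- distinct
    from proven infeasibility, which is a regular result."""


@dataclass(frozen=True)
class CNFClause:
    """A disjunction of literals; satisfied when any literal holds."""

    literals: frozenset[Literal]

    def __post_init__(self):
        lits = frozenset(self.literals)
        object.__setattr__(self, "literals", lits)
        if not lits:
            raise ValueError("empty clause")
        vars_pos = {l.variable for l in lits if l.positive}
        vars_neg = {l.variable for l in lits if not l.positive}
        if vars_pos & vars_neg:
            raise ValueError("variable occurs with both signs in one clause")

    @property
    def variables(self) -> set[str]:
        return {l.variable for l in self.literals}

    def __str__(self) -> str:
        return "(" + " | ".join(str(l) for l in sorted(self.literals)) + ")"


@dataclass(frozen=True)
class ILPConstraint:
    """A single linear constraint over binary variables."""

    coefficients: tuple[tuple[str, int], ...]
    sense: str  # ">=", "<=", "="
    rhs: int

    @classmethod
    def from_dict(cls, coeffs: dict[str, int], sense: str, rhs: int):
        return cls(tuple(sorted(coeffs.items())), sense, rhs)

    @property
    def coeff_dict(self) -> dict[str, int]:
        return dict(self.coefficients)


@dataclass
class ILPProblem:
    """A binary integer program: variables, constraints, objective, fixings."""

    variables: list[str]
    constraints: list[ILPConstraint] = field(default_factory=list)
    objective: dict[str, int] = field(default_factory=dict)
    direction: str = MINIMIZE
    fixings: dict[str, int] = field(default_factory=dict)

    def fixed(self, fixings: dict[str, int]) -> "ILPProblem":
        """A copy with additional variable fixings."""
        for var, val in fixings.items():
            if var not in self.variables:
                raise KeyError(f"unknown variable {var!r}")
            if val not in (0, 1):
                raise ValueError(f"fixing {var}={val} is not binary")
            if self.fixings.get(var, val) != val:
                raise ValueError(f"conflicting fixings for {var!r}")
        return ILPProblem(
            variables=list(self.variables),
            constraints=list(self.constraints),
            objective=dict(self.objective),
            direction=self.direction,
            fixings={**self.fixings, **fixings},
        )

    def with_objective(self, objective: dict[str, int],
                       direction: str = MINIMIZE) -> "ILPProblem":
        prob = ILPProblem(
            variables=list(self.variables),
            constraints=list(self.constraints),
            objective=dict(objective),
            direction=direction,
            fixings=dict(self.fixings),
        )
        for var in objective:
            if var not in prob.variables:
                raise KeyError(f"unknown objective variable {var!r}")
        return prob

    def to_lp_string(self) -> str:
        """Render in the LP file format (for external solver debugging)."""
        sense_map = {">=": ">=", "<=": "<=", "=": "="}
        lines = []
        lines.append("Minimize" if self.direction == MINIMIZE else "Maximize")
        terms = " + ".join(
            f"{c} {_lp_name(v)}" for v, c in sorted(self.objective.items()))
        lines.append(" obj: " + (terms or "0 " + _lp_name(self.variables[0])))
        lines.append("Subject To")
        for i, con in enumerate(self.constraints):
            parts = []
            for var, coef in con.coefficients:
                sign = "+" if coef >= 0 else "-"
                parts.append(f"{sign} {abs(coef)} {_lp_name(var)}")
            lines.append(
                f" c{i}: " + " ".join(parts) +
                f" {sense_map[con.sense]} {con.rhs}")
        lines.append("Bounds")
        for var in self.variables:
            if var in self.fixings:
                v = self.fixings[var]
                lines.append(f" {v} <= {_lp_name(var)} <= {v}")
            else:
                lines.append(f" 0 <= {_lp_name(var)} <= 1")
        lines.append("Binary")
        lines.append(" " + " ".join(_lp_name(v) for v in self.variables))
        lines.append("End")
        return "\n".join(lines) + "\n"


def _lp_name(var: str) -> str:
    # LP format forbids spaces/colons in names.
    out = []
    for ch in var:
        out.append(ch if (ch.isalnum() or ch in "_.") else "_")
    name = "".join(out)
    if name and name[0].isdigit():
        name = "x" + name
    return name or "x"


@dataclass(frozen=True)
class SolveResult:
    """Outcome of one MILP solve."""

    status: str  # "optimal" | "infeasible"
    assignment: dict[str, int] | None = None
    objective_value: int | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def to_cnf(system: BooleanSystem) -> list[CNFClause]:
    """Rewrite the statement system in conjunctive normal form.

    Statements are processed sorted by consequent id so the emitted clause
    list (and the integer program derived from it) is canonical.
    """
    clauses: list[CNFClause] = []
    for st in sorted(system.statements, key=lambda s: (s.kind, s.consequent)):
        c = st.consequent
        if st.kind == EVENT_ACTIVATION:
            # r <=> conjunction of antecedent literals
            completion = {Literal(c)}
            for lit in sorted(st.antecedent):
                clauses.append(CNFClause(frozenset({Literal(c, NEGATIVE), lit})))
                completion.add(lit.negate())
            comp_pos = {l.variable for l in completion if l.positive}
            comp_neg = {l.variable for l in completion if not l.positive}
            if comp_pos & comp_neg:
                # A signal both input and inhibitor: the completion clause is
                # a tautology; the pairwise clauses already force r = 0.
                continue
            clauses.append(CNFClause(frozenset(completion)))
        else:
            # s <=> disjunction of producing reactions
            big = {Literal(c, NEGATIVE)}
            for lit in sorted(st.antecedent):
                big.add(lit)
                clauses.append(
                    CNFClause(frozenset({Literal(c), lit.negate()})))
            clauses.append(CNFClause(frozenset(big)))
    return clauses


def clauses_to_ilp(clauses: list[CNFClause],
                   variables: list[str] | None = None) -> ILPProblem:
    """One constraint per clause: sum(pos) + sum(1 - neg) >= 1.

    Rearranged, ``sum(pos vars) - sum(neg vars) >= 1 - #neg``.  All
    variables are binary; no objective is set.
    """
    var_set: set[str] = set(variables or [])
    for cl in clauses:
        var_set |= cl.variables
    problem = ILPProblem(variables=sorted(var_set))
    for cl in clauses:
        coeffs: dict[str, int] = {}
        n_neg = 0
        for lit in cl.literals:
            if lit.positive:
                coeffs[lit.variable] = coeffs.get(lit.variable, 0) + 1
            else:
                coeffs[lit.variable] = coeffs.get(lit.variable, 0) - 1
                n_neg += 1
        problem.constraints.append(
            ILPConstraint.from_dict(coeffs, ">=", 1 - n_neg))
    return problem


def system_ilp(system: BooleanSystem) -> ILPProblem:
    """CNF-encode a compiled system and return its integer program."""
    return clauses_to_ilp(to_cnf(system), variables=system.variables)


def solve(problem: ILPProblem) -> SolveResult:
    """Solve a binary integer program exactly.

    Returns ``optimal`` with an assignment satisfying every constraint and
    fixing (objective value is unique even when the argmin is not), or
    ``infeasible`` when no 0/1 point exists.  Back-end failures raise
    :class:`SolverError` instead of masquerading as infeasibility.
    """
    n = len(problem.variables)
    if n == 0:
        return SolveResult("optimal", {}, 0)
    index = {v: i for i, v in enumerate(problem.variables)}
    c = np.zeros(n)
    for var, coef in problem.objective.items():
        c[index[var]] = coef
    sign = 1.0 if problem.direction == MINIMIZE else -1.0
    lb = np.zeros(n)
    ub = np.ones(n)
    for var, val in problem.fixings.items():
        lb[index[var]] = ub[index[var]] = float(val)
    constraints = []
    if problem.constraints:
        m = len(problem.constraints)
        A = np.zeros((m, n))
        c_lb = np.full(m, -np.inf)
        c_ub = np.full(m, np.inf)
        for i, con in enumerate(problem.constraints):
            for var, coef in con.coefficients:
                A[i, index[var]] = coef
            if con.sense == ">=":
                c_lb[i] = con.rhs
            elif con.sense == "<=":
                c_ub[i] = con.rhs
            elif con.sense == "=":
                c_lb[i] = c_ub[i] = con.rhs
            else:
                raise ValueError(f"bad sense {con.sense!r}")
        constraints = [LinearConstraint(A, c_lb, c_ub)]
    res = milp(
        c=sign * c,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
    )
    # scipy milp status: 0 optimal, 2 infeasible, 3 unbounded, else failure
    if res.status == 0:
        assignment = {v: int(round(res.x[index[v]])) for v in problem.variables}
        obj = int(round(sum(
            coef * assignment[var] for var, coef in problem.objective.items())))
        return SolveResult("optimal", assignment, obj)
    if res.status == 2:
        return SolveResult("infeasible")
    raise SolverError(
        f"MILP back end failed (status {res.status}): {res.message}")


def satisfies(clauses: list[CNFClause], assignment: dict[str, int]) -> bool:
    """True iff every clause has at least one satisfied literal."""
    for cl in clauses:
        ok = False
        for lit in cl.literals:
            if lit.variable not in assignment:
                raise KeyError(f"assignment missing variable {lit.variable!r}")
            val = bool(assignment[lit.variable])
            if val == lit.positive:
                ok = True
                break
        if not ok:
            return False
    return True


def enumerate_satisfying(
    clauses: list[CNFClause],
    variables: list[str],
    fixings: dict[str, int] | None = None,
) -> list[dict[str, int]]:
    """All satisfying assignments by exhaustion (small systems only)."""
    fixings = fixings or {}
    free = [v for v in variables if v not in fixings]
    if len(free) > 24:
        raise ValueError(f"too many free variables ({len(free)}) to enumerate")
    out = []
    for bits in product((0, 1), repeat=len(free)):
        assignment = dict(fixings)
        assignment.update(zip(free, bits))
        if satisfies(clauses, assignment):
            out.append(assignment)
    return out
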