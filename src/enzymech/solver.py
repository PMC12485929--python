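"""MILP formulations for parsimonious mechanism construction.

Three formulations over the rule matrix T and reaction target T°:

* ``solve_min_order_rules`` — the monolithic problem: jointly pick how often
  each rule fires (integer y_r) and assign rules to ordered steps (binary
  z_{k,r}), minimizing total steps subject to moiety balance, per-step
  exclusivity, contiguity, and prefix non-negativity of every non-catalytic
  moiety's running count.
* ``solve_min_rules`` — the selection half of the decomposition: minimize
  Σ y_r subject to T·y = T° and Σ y_r ≤ W, with integer cuts excluding prior
  selections.
* ``solve_order_rules`` — the ordering half: a pure feasibility problem that
  sequences a fixed rule multiset so no unlabeled moiety's cumulative count
  ever goes negative (catalytic M* moieties are exempt: the enzyme's
  machinery is reusable).

``enumerate_mechanisms`` iterates selection → ordering with integer cuts to
produce a ranked list of the most parsimonious ordered mechanisms.

The backend is scipy's HiGHS-based ``milp``, wrapped in a minimal
model-building contract (integer/binary variables, linear constraints,
objective, time limit) so another MILP engine could be swapped in.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .moieties import MoietyId, MoietyVector
from .rules import RuleMatrix

__all__ = [
    "ReactionProblem",
    "SolverConfig",
    "RuleSelection",
    "OrderedMechanism",
    "Cut",
    "SolveTimeout",
    "MilpModel",
    "solve_min_rules",
    "solve_order_rules",
    "solve_min_order_rules",
    "add_integer_cut",
    "enumerate_mechanisms",
    "EnumerationResult",
]


class SolveTimeout(Exception):
    """The backend hit its time limit before proving optimality/infeasibility."""


@dataclass(frozen=True)
class ReactionProblem:
    """One reaction posed to the solver.

    ``target`` is the net moiety-change vector T°; ``initial_counts`` the
    moiety counts C° of all substrates (non-negative); ``labeled_set``
    overrides/extends the rule matrix's catalytic set M*.
    """

    target: MoietyVector
    initial_counts: MoietyVector
    rule_matrix: RuleMatrix
    labeled_set: frozenset[MoietyId] = frozenset()

    def __post_init__(self) -> None:
        if not self.initial_counts.is_nonnegative():
            raise ValueError("initial_counts must be non-negative")

    @property
    def exempt(self) -> frozenset[MoietyId]:
        return self.labeled_set | self.rule_matrix.labeled_set


@dataclass(frozen=True)
class SolverConfig:
    """Solver knobs.

    ``max_rules`` is the cap W on total steps (default 20); ``max_steps``
    the step horizon K of the monolithic formulation (defaults to W — a
    longer horizon is useless under Σ y_r ≤ W).  ``top_n`` is the length of
    the ranked list (default 10).  ``time_limit`` is the per-reaction wall
    clock in seconds shared by all solves; ``per_order_time_limit`` caps any
    single ordering solve (default time_limit/10) so one hard ordering
    cannot starve enumeration.
    """

    max_rules: int = 20
    max_steps: Optional[int] = None
    top_n: int = 10
    time_limit: float = 1200.0
    per_order_time_limit: Optional[float] = None
    cut_style: Literal["as_printed", "support_exact"] = "as_printed"
    solver_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rules < 1:
            raise ValueError("max_rules (W) must be >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.max_steps is not None and self.max_steps < self.max_rules:
            raise ValueError("max_steps (K) must be >= max_rules (W)")

    @property
    def horizon(self) -> int:
        return self.max_steps if self.max_steps is not None else self.max_rules

    @property
    def order_limit(self) -> float:
        if self.per_order_time_limit is not None:
            return self.per_order_time_limit
        return self.time_limit / 10.0


@dataclass(frozen=True)
class RuleSelection:
    """A rule multiset: counts y_r > 0, support S, total steps Σ y_r."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.counts.values()):
            raise ValueError("selection counts must be positive")

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.counts)

    @property
    def total_steps(self) -> int:
        return sum(self.counts.values())

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, RuleSelection):
            return self.counts == other.counts
        return NotImplemented


@dataclass(frozen=True)
class OrderedMechanism:
    """An ordered rule sequence realizing the target with feasible prefixes."""

    sequence: tuple[int, ...]
    selection: RuleSelection
    parsimony_rank: int = 0

    @property
    def total_steps(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Cut:
    """An integer cut excluding a previously seen selection.

    ``style``:
      * ``as_printed`` — Σ_{r∈S} y_r ≤ |S|−1 (the printed form; also
        excludes solutions reusing S's rules at higher multiplicity).
      * ``support_exact`` — indicator-based cut excluding exactly the
        support set S, no other combination.
      * ``count_exact`` — no-good cut excluding exactly this count vector
        y*; used for selections whose ordering proved infeasible, so that
        orderable selections sharing rules are never lost.
    """

    style: str
    counts: dict[int, int]

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.counts)


# ---------------------------------------------------------------------------
# Backend wrapper
# ---------------------------------------------------------------------------


class MilpModel:
    """Minimal mixed-integer model contract over scipy's HiGHS backend."""

    def __init__(self) -> None:
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._obj: dict[int, float] = {}
        self._rows: list[dict[int, float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []

    def add_var(self, lb: float = 0, ub: float = np.inf) -> int:
        self._lb.append(lb)
        self._ub.append(ub)
        return len(self._lb) - 1

    def add_binary(self) -> int:
        return self.add_var(0, 1)

    def add_constraint(self, coeffs: dict[int, float], sense: str, rhs: float) -> None:
        if sense == "<=":
            lo, hi = -np.inf, rhs
        elif sense == ">=":
            lo, hi = rhs, np.inf
        elif sense == "==":
            lo, hi = rhs, rhs
        else:
            raise ValueError(f"unknown sense {sense!r}")
        self._rows.append(dict(coeffs))
        self._row_lb.append(lo)
        self._row_ub.append(hi)

    def set_objective(self, coeffs: dict[int, float]) -> None:
        self._obj = dict(coeffs)

    def solve(self, time_limit: Optional[float] = None) -> tuple[str, Optional[np.ndarray]]:
        """Returns (status, values); status in optimal|infeasible|timeout|error."""
        n = len(self._lb)
        if n == 0:
            return "optimal", np.zeros(0)
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = v
        constraints = []
        if self._rows:
            data, indices, indptr = [], [], [0]
            for row in self._rows:
                for j, v in sorted(row.items()):
                    indices.append(j)
                    data.append(v)
                indptr.append(len(indices))
            A = csr_matrix((data, indices, indptr), shape=(len(self._rows), n))
            constraints.append(
                LinearConstraint(A, np.array(self._row_lb), np.array(self._row_ub))
            )
        options: dict = {}
        if time_limit is not None:
            options["time_limit"] = max(float(time_limit), 0.0)
        res = milp(
            c,
            integrality=np.ones(n),
            bounds=Bounds(np.array(self._lb, float), np.array(self._ub, float)),
            constraints=constraints,
            options=options,
        )
        if res.status == 0:
            return "optimal", res.x
        if res.status == 2:
            return "infeasible", None
        if res.status == 1:  # iteration/time limit
            return "timeout", res.x
        return "error", None


# ---------------------------------------------------------------------------
# Model construction helpers
# ---------------------------------------------------------------------------


def _moiety_universe(problem: ReactionProblem) -> list[MoietyId]:
    """All moieties the balance constraints range over (rule ∪ target support)."""
    keys = set(problem.rule_matrix.moiety_index) | set(problem.target.support)
    return sorted(keys)


def add_integer_cut(
    model: MilpModel,
    y_vars: dict[int, int],
    cut: Cut,
    W: int,
    u_vars: Optional[dict[int, int]] = None,
) -> None:
    """Append one integer cut to a selection model.

    ``u_vars`` (rule_id → binary var index with u_r = 1 iff y_r ≥ 1) must be
    supplied for ``support_exact`` cuts; they are shared across cuts.
    """
    S = cut.support
    if not S:
        raise ValueError("cannot cut an empty support")
    if cut.style == "as_printed":
        model.add_constraint({y_vars[r]: 1.0 for r in S}, "<=", len(S) - 1)
    elif cut.style == "support_exact":
        assert u_vars is not None
        coeffs = {}
        for r, yj in y_vars.items():
            coeffs[u_vars[r]] = 1.0 if r in S else -1.0
        model.add_constraint(coeffs, "<=", len(S) - 1)
    elif cut.style == "count_exact":
        # No-good cut on the exact count vector: binaries e_r (y_r ≥ y*_r+1)
        # and f_r (y_r ≤ y*_r−1); at least one must fire.
        indicators = []
        for r, yj in y_vars.items():
            c = cut.counts.get(r, 0)
            if c < W:
                e = model.add_binary()
                # e=1 ⟹ y_r ≥ c+1
                model.add_constraint({yj: 1.0, e: -(c + 1.0)}, ">=", 0.0)
                indicators.append(e)
            if c >= 1:
                f = model.add_binary()
                # f=1 ⟹ y_r ≤ c−1  (big-M: y + (W−c+1)·f ≤ W)
                model.add_constraint({yj: 1.0, f: (W - c + 1.0)}, "<=", float(W))
                indicators.append(f)
        model.add_constraint({v: 1.0 for v in indicators}, ">=", 1.0)
    else:
        raise ValueError(f"unknown cut style {cut.style!r}")


def _add_support_indicators(
    model: MilpModel, y_vars: dict[int, int], W: int
) -> dict[int, int]:
    """Binary u_r with u_r = 1 iff y_r ≥ 1 (linked both ways)."""
    u_vars = {}
    for r, yj in y_vars.items():
        u = model.add_binary()
        model.add_constraint({yj: 1.0, u: -float(W)}, "<=", 0.0)  # y ≤ W·u
        model.add_constraint({u: 1.0, yj: -1.0}, "<=", 0.0)  # u ≤ y
        u_vars[r] = u
    return u_vars


def _selection_from_values(
    rules: Sequence, y_vars: dict[int, int], values: np.ndarray
) -> RuleSelection:
    counts = {}
    for r, j in y_vars.items():
        v = int(round(values[j]))
        if v > 0:
            counts[r] = v
    return RuleSelection(counts=counts)


# ---------------------------------------------------------------------------
# minRules (selection)
# ---------------------------------------------------------------------------


def _build_min_rules_model(
    problem: ReactionProblem, config: SolverConfig, cuts: Sequence[Cut]
) -> tuple[MilpModel, dict[int, int]]:
    model = MilpModel()
    W = config.max_rules
    rules = problem.rule_matrix.rules
    y_vars = {r.rule_id: model.add_var(0, W) for r in rules}

    # Moiety balance: Σ_r T[m,r]·y_r = T°_m for every m.
    for m in _moiety_universe(problem):
        coeffs = {}
        for r in rules:
            t = r.delta[m]
            if t:
                coeffs[y_vars[r.rule_id]] = float(t)
        model.add_constraint(coeffs, "==", float(problem.target[m]))

    # Σ y_r ≤ W
    model.add_constraint({j: 1.0 for j in y_vars.values()}, "<=", float(W))

    u_vars = None
    if any(c.style == "support_exact" for c in cuts):
        u_vars = _add_support_indicators(model, y_vars, W)
    for cut in cuts:
        add_integer_cut(model, y_vars, cut, W, u_vars=u_vars)

    model.set_objective({j: 1.0 for j in y_vars.values()})
    return model, y_vars


def solve_min_rules(
    problem: ReactionProblem,
    config: SolverConfig,
    prior_solutions: Iterable[RuleSelection] = (),
    cuts: Optional[Sequence[Cut]] = None,
    time_limit: Optional[float] = None,
) -> Optional[RuleSelection]:
    """Most parsimonious rule multiset balancing the target, or None.

    ``prior_solutions`` are excluded with ``config.cut_style`` cuts;
    pre-built ``cuts`` (mixed styles) may be passed instead/in addition.
    Raises :class:`SolveTimeout` if the backend cannot decide in time.
    """
    all_cuts = list(cuts or [])
    for sel in prior_solutions:
        all_cuts.append(Cut(style=config.cut_style, counts=dict(sel.counts)))
    model, y_vars = _build_min_rules_model(problem, config, all_cuts)
    status, values = model.solve(time_limit if time_limit is not None else config.time_limit)
    if status == "infeasible":
        return None
    if status in ("timeout", "error") or values is None:
        raise SolveTimeout("minRules hit the time limit")
    return _selection_from_values(problem.rule_matrix.rules, y_vars, values)


# ---------------------------------------------------------------------------
# OrderRules (sequencing a fixed multiset)
# ---------------------------------------------------------------------------


def solve_order_rules(
    problem: ReactionProblem,
    selection: RuleSelection,
    config: SolverConfig,
    time_limit: Optional[float] = None,
) -> Optional[OrderedMechanism]:
    """Feasible ordering of a selected rule multiset, or None.

    A pure feasibility problem over K = total_steps steps: one rule per
    step, every rule used exactly y_r times, and for every prefix the
    cumulative count of each moiety outside M* stays ≥ 0 starting from C°.
    """
    K = selection.total_steps
    if K == 0:
        return OrderedMechanism(sequence=(), selection=selection)
    matrix = problem.rule_matrix
    sel_rules = [matrix.rule_by_id(r) for r in sorted(selection.support)]

    model = MilpModel()
    z = {}  # (k, rule_id) -> var
    for k in range(K):
        for rule in sel_rules:
            z[(k, rule.rule_id)] = model.add_binary()

    # One rule per step (equality is implied by Σy = K, but ≤ matches the form).
    for k in range(K):
        model.add_constraint(
            {z[(k, r.rule_id)]: 1.0 for r in sel_rules}, "<=", 1.0
        )
    # Each rule used exactly y_r times.
    for rule in sel_rules:
        model.add_constraint(
            {z[(k, rule.rule_id)]: 1.0 for k in range(K)},
            "==",
            float(selection.counts[rule.rule_id]),
        )
    # Prefix non-negativity for unlabeled moieties touched by the selection.
    exempt = problem.exempt
    touched = sorted({m for r in sel_rules for m in r.delta if m not in exempt})
    for m in touched:
        c0 = float(problem.initial_counts[m])
        for k in range(K):
            coeffs = {}
            for rule in sel_rules:
                t = rule.delta[m]
                if t:
                    for kp in range(k + 1):
                        coeffs[z[(kp, rule.rule_id)]] = float(t)
            model.add_constraint(coeffs, ">=", -c0)

    model.set_objective({})  # dummy objective
    status, values = model.solve(time_limit if time_limit is not None else config.order_limit)
    if status == "infeasible":
        return None
    if status in ("timeout", "error") or values is None:
        raise SolveTimeout("OrderRules hit the time limit")
    sequence = []
    for k in range(K):
        for rule in sel_rules:
            if values[z[(k, rule.rule_id)]] > 0.5:
                sequence.append(rule.rule_id)
    assert len(sequence) == K
    return OrderedMechanism(sequence=tuple(sequence), selection=selection)


# ---------------------------------------------------------------------------
# minOrderRules (monolithic)
# ---------------------------------------------------------------------------


def solve_min_order_rules(
    problem: ReactionProblem,
    config: SolverConfig,
    cuts: Optional[Sequence[Cut]] = None,
    time_limit: Optional[float] = None,
) -> Optional[OrderedMechanism]:
    """Jointly optimal selection and feasible ordering, or None.

    The reference formulation: minimize Σ y_r over a K-step horizon with
    balance, one-rule-per-step, step-utilization, contiguity, linking and
    prefix non-negativity constraints.
    """
    model = MilpModel()
    W = config.max_rules
    K = config.horizon
    rules = problem.rule_matrix.rules
    y_vars = {r.rule_id: model.add_var(0, W) for r in rules}
    z = {(k, r.rule_id): model.add_binary() for k in range(K) for r in rules}

    for m in _moiety_universe(problem):
        coeffs = {}
        for r in rules:
            t = r.delta[m]
            if t:
                coeffs[y_vars[r.rule_id]] = float(t)
        model.add_constraint(coeffs, "==", float(problem.target[m]))

    exempt = problem.exempt
    touched = sorted({m for r in rules for m in r.delta if m not in exempt})
    for m in touched:
        c0 = float(problem.initial_counts[m])
        running: dict[int, float] = {}
        for k in range(K):
            for r in rules:
                t = r.delta[m]
                if t:
                    running[z[(k, r.rule_id)]] = float(t)
            model.add_constraint(dict(running), ">=", -c0)

    for k in range(K):
        model.add_constraint({z[(k, r.rule_id)]: 1.0 for r in rules}, "<=", 1.0)
    # Step utilization: k·Σ_r z_{k,r} ≤ Σ_r y_r  (steps beyond Σy unused).
    for k in range(K):
        coeffs = {z[(k, r.rule_id)]: float(k + 1) for r in rules}
        for r in rules:
            coeffs[y_vars[r.rule_id]] = coeffs.get(y_vars[r.rule_id], 0.0) - 1.0
        model.add_constraint(coeffs, "<=", 0.0)
    # Contiguity: Σ_r z_{k,r} ≥ Σ_r z_{k+1,r}.
    for k in range(K - 1):
        coeffs = {}
        for r in rules:
            coeffs[z[(k, r.rule_id)]] = 1.0
            coeffs[z[(k + 1, r.rule_id)]] = -1.0
        model.add_constraint(coeffs, ">=", 0.0)
    # Linking: Σ_k z_{k,r} = y_r.
    for r in rules:
        coeffs = {z[(k, r.rule_id)]: 1.0 for k in range(K)}
        coeffs[y_vars[r.rule_id]] = -1.0
        model.add_constraint(coeffs, "==", 0.0)

    u_vars = None
    all_cuts = list(cuts or [])
    if any(c.style == "support_exact" for c in all_cuts):
        u_vars = _add_support_indicators(model, y_vars, W)
    for cut in all_cuts:
        add_integer_cut(model, y_vars, cut, W, u_vars=u_vars)

    model.set_objective({j: 1.0 for j in y_vars.values()})
    status, values = model.solve(time_limit if time_limit is not None else config.time_limit)
    if status == "infeasible":
        return None
    if status in ("timeout", "error") or values is None:
        raise SolveTimeout("minOrderRules hit the time limit")

    selection = _selection_from_values(rules, y_vars, values)
    sequence = []
    for k in range(K):
        for r in rules:
            if values[z[(k, r.rule_id)]] > 0.5:
                sequence.append(r.rule_id)
    return OrderedMechanism(sequence=tuple(sequence), selection=selection)


# ---------------------------------------------------------------------------
# Ranked enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnumerationResult:
    mechanisms: tuple[OrderedMechanism, ...]
    outcome: Literal["complete", "timeout", "infeasible"]


def enumerate_mechanisms(
    problem: ReactionProblem, config: SolverConfig
) -> EnumerationResult:
    """Ranked list of the top-N most parsimonious ordered mechanisms.

    Iterates minRules → OrderRules.  Found solutions are excluded with
    ``config.cut_style`` cuts; selections whose ordering is infeasible are
    excluded with an exact count-vector cut (they consume enumeration budget
    but produce no candidate and never block other selections).  Stops at
    ``top_n`` mechanisms, proven infeasibility, or the global time budget.
    Ranks are 1-based in discovery order, so step counts are non-decreasing
    with rank.
    """
    start = time.monotonic()
    found: list[OrderedMechanism] = []
    cuts: list[Cut] = []

    def remaining() -> float:
        return config.time_limit - (time.monotonic() - start)

    if remaining() <= 0:
        return EnumerationResult(mechanisms=(), outcome="timeout")

    outcome: str = "complete"
    while len(found) < config.top_n:
        budget = remaining()
        if budget <= 0:
            outcome = "timeout"
            break
        try:
            selection = solve_min_rules(problem, config, cuts=cuts, time_limit=budget)
        except SolveTimeout:
            outcome = "timeout"
            break
        if selection is None:
            outcome = "infeasible" if not found else "complete"
            break
        if selection.total_steps == 0:
            # Zero target: the trivial empty mechanism is the unique optimum.
            found.append(
                OrderedMechanism(sequence=(), selection=selection, parsimony_rank=1)
            )
            break
        order_budget = min(remaining(), config.order_limit)
        if order_budget <= 0:
            outcome = "timeout"
            break
        try:
            ordered = solve_order_rules(
                problem, selection, config, time_limit=order_budget
            )
        except SolveTimeout:
            ordered = None  # undecided ordering: skip it, keep enumerating
            if remaining() <= 0:
                outcome = "timeout"
                break
        if ordered is not None:
            found.append(replace(ordered, parsimony_rank=len(found) + 1))
            cuts.append(Cut(style=config.cut_style, counts=dict(selection.counts)))
        else:
            cuts.append(Cut(style="count_exact", counts=dict(selection.counts)))

    if outcome == "infeasible" and found:
        outcome = "complete"
    return EnumerationResult(mechanisms=tuple(found), outcome=outcome)  # type: ignore[arg-type]
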