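"""End-to-end mechanism prediction: parse → screen → solve → re-rank.

A reaction is screened for elemental/charge balance and for a non-zero
moiety delta, checked for compatibility with the rule set (every target
moiety must appear in some rule), solved for the top-N most parsimonious
ordered mechanisms, and re-ranked by similarity to known mechanisms.  Each
reaction receives exactly one outcome status; batch summaries report counts
and percentages per status.  Candidate mechanisms for one reaction can be
compiled into a step network whose nodes are intermediate chemical states
and whose edges are elementary rules (general acid/base variants merged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .moieties import (
    MoietyError,
    MoietyId,
    MoietyVector,
    Species,
    check_balance,
    moiety_counts,
    parse_reaction_smiles,
    reaction_delta,
)
from .rerank import MechanismRecord, RankedCandidate, rerank
from .rules import RuleMatrix
from .solver import (
    EnumerationResult,
    OrderedMechanism,
    ReactionProblem,
    SolverConfig,
    enumerate_mechanisms,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionOutcome",
    "StepNetwork",
    "Status",
    "compatibility_check",
    "build_problem",
    "predict",
    "batch_predict",
    "build_step_network",
    "summarize",
]


class Status:
    PREDICTED = "predicted"
    TIMEOUT = "timeout"
    INCOMPATIBLE = "incompatible"
    UNBALANCED = "unbalanced"
    NO_NET_CHANGE = "no_net_change"
    INFEASIBLE = "infeasible"  # moiety screen passed, but no rule combination within W
    ERROR = "error"

    ALL = (PREDICTED, TIMEOUT, INCOMPATIBLE, UNBALANCED, NO_NET_CHANGE, INFEASIBLE, ERROR)


@dataclass(frozen=True)
class ReactionOutcome:
    reaction_id: str
    status: str
    candidates: tuple[RankedCandidate, ...] = ()
    incompatible_moieties: tuple[MoietyId, ...] = ()
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.status == Status.PREDICTED) != bool(self.candidates):
            raise ValueError("status=predicted iff candidates non-empty")
        if (self.status == Status.INCOMPATIBLE) != bool(self.incompatible_moieties):
            raise ValueError("status=incompatible iff incompatible_moieties non-empty")


def compatibility_check(problem: ReactionProblem, strict: bool = False) -> list[MoietyId]:
    """Moieties of the target (and of C° in strict mode) absent from the rule set.

    An empty list means the reaction is expressible in the rule set's
    chemistry; a non-empty list is the "incompatible" outcome.
    """
    index = set(problem.rule_matrix.moiety_index)
    missing = [m for m in sorted(problem.target.support) if m not in index]
    if strict:
        missing += [
            m
            for m in sorted(problem.initial_counts.support)
            if m not in index and m not in missing
        ]
    return missing


def build_problem(
    substrates: Sequence[Species],
    products: Sequence[Species],
    rule_matrix: RuleMatrix,
) -> ReactionProblem:
    """Assemble target T° and substrate counts C° for a parsed reaction."""
    target = reaction_delta(substrates, products)
    c0 = MoietyVector()
    for mol, coeff in substrates:
        c0 = c0 + moiety_counts(mol) * coeff
    return ReactionProblem(target=target, initial_counts=c0, rule_matrix=rule_matrix)


def predict(
    reaction: str | tuple[Sequence[Species], Sequence[Species]],
    rule_matrix: RuleMatrix,
    mechanism_db: Sequence[MechanismRecord] = (),
    config: Optional[SolverConfig] = None,
    reaction_id: str = "reaction",
) -> ReactionOutcome:
    """Predict ranked mechanisms for one reaction.

    Screening order: balance → zero-delta → rule-set compatibility →
    enumeration → similarity re-ranking.  With an empty mechanism database
    the parsimony order is kept (scores 0, rank preserved).
    """
    config = config or SolverConfig()
    try:
        if isinstance(reaction, str):
            substrates, products = parse_reaction_smiles(reaction)
        else:
            substrates, products = reaction

        report = check_balance(substrates, products)
        if not report.balanced:
            return ReactionOutcome(
                reaction_id=reaction_id,
                status=Status.UNBALANCED,
                detail=f"element deficits {dict(report.element_deficits)}, "
                f"charge deficit {report.charge_deficit}",
            )
        problem = build_problem(substrates, products, rule_matrix)
    except MoietyError as exc:
        return ReactionOutcome(reaction_id=reaction_id, status=Status.ERROR, detail=str(exc))

    return predict_problem(problem, rule_matrix, mechanism_db, config, reaction_id)


def predict_problem(
    problem: ReactionProblem,
    rule_matrix: RuleMatrix,
    mechanism_db: Sequence[MechanismRecord] = (),
    config: Optional[SolverConfig] = None,
    reaction_id: str = "reaction",
) -> ReactionOutcome:
    """Screen, enumerate and re-rank an already-built :class:`ReactionProblem`."""
    config = config or SolverConfig()
    if not problem.target:
        return ReactionOutcome(reaction_id=reaction_id, status=Status.NO_NET_CHANGE)

    missing = compatibility_check(problem)
    if missing:
        return ReactionOutcome(
            reaction_id=reaction_id,
            status=Status.INCOMPATIBLE,
            incompatible_moieties=tuple(missing),
        )

    result: EnumerationResult = enumerate_mechanisms(problem, config)
    if not result.mechanisms:
        status = Status.TIMEOUT if result.outcome == "timeout" else Status.INFEASIBLE
        return ReactionOutcome(reaction_id=reaction_id, status=status, detail=result.outcome)

    if mechanism_db:
        ranked = rerank(result.mechanisms, mechanism_db, rule_matrix=rule_matrix)
    else:
        ranked = [
            RankedCandidate(
                mechanism=m,
                parsimony_rank=m.parsimony_rank,
                similarity_rank=m.parsimony_rank,
                score=0.0,
                best_match="",
            )
            for m in result.mechanisms
        ]
    return ReactionOutcome(
        reaction_id=reaction_id,
        status=Status.PREDICTED,
        candidates=tuple(ranked),
        detail=result.outcome,
    )


# ---------------------------------------------------------------------------
# Batch mode
# ---------------------------------------------------------------------------


def read_reaction_file(path: str | Path) -> list[tuple[str, str]]:
    """Two-column delimited file (id, reaction-SMILES); '#' comments allowed."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",", 1)
        if len(parts) != 2:
            raise MoietyError(f"{path}:{ln}: expected 'id<TAB>reaction-SMILES'")
        out.append((parts[0].strip(), parts[1].strip()))
    return out


def summarize(outcomes: Sequence[ReactionOutcome]) -> dict:
    """Counts and percentages per status (the outcome-taxonomy table layout)."""
    n = len(outcomes)
    counts = {status: 0 for status in Status.ALL}
    for o in outcomes:
        counts[o.status] += 1
    return {
        "reactions_tested": n,
        "counts": counts,
        "percent": {
            s: (round(100.0 * c / n, 1) if n else 0.0) for s, c in counts.items()
        },
    }


def outcome_to_dict(outcome: ReactionOutcome) -> dict:
    return {
        "reaction_id": outcome.reaction_id,
        "status": outcome.status,
        "detail": outcome.detail,
        "incompatible_moieties": [m.serialize() for m in outcome.incompatible_moieties],
        "candidates": [
            {
                "parsimony_rank": c.parsimony_rank,
                "similarity_rank": c.similarity_rank,
                "score": c.score,
                "best_match": c.best_match,
                "total_steps": c.mechanism.total_steps,
                "sequence": list(c.mechanism.sequence),
            }
            for c in outcome.candidates
        ],
    }


def batch_predict(
    reactions: Iterable[tuple[str, str]] | str | Path,
    rule_matrix: RuleMatrix,
    mechanism_db: Sequence[MechanismRecord] = (),
    config: Optional[SolverConfig] = None,
    out_path: Optional[str | Path] = None,
) -> tuple[list[ReactionOutcome], dict]:
    """Predict every reaction in a batch; never aborts on a single failure.

    Returns (outcomes, summary); with ``out_path`` also writes a
    deterministic JSON document (sorted keys, no timestamps) so re-runs
    with the same inputs are byte-identical.
    """
    if isinstance(reactions, (str, Path)):
        reactions = read_reaction_file(reactions)
    config = config or SolverConfig()
    outcomes = []
    for rid, rxn in reactions:
        try:
            outcomes.append(
                predict(rxn, rule_matrix, mechanism_db, config, reaction_id=rid)
            )
        except Exception as exc:  # per-row errors logged, run continues
            logger.exception("reaction %s failed", rid)
            outcomes.append(
                ReactionOutcome(reaction_id=rid, status=Status.ERROR, detail=str(exc))
            )
    summary = summarize(outcomes)
    if out_path is not None:
        doc = {
            "outcomes": [outcome_to_dict(o) for o in outcomes],
            "summary": summary,
        }
        Path(out_path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return outcomes, summary


# ---------------------------------------------------------------------------
# Step network (mechanistic-diversity compilation)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepNetwork:
    """Chemical states reachable along candidate mechanisms.

    Nodes are cumulative moiety-state vectors (projected onto non-generic
    moieties so that general acid/base variants of the same transformation
    collapse); edges carry the set of rule ids observed for that
    transition.  ``source`` is the substrate state C°, ``sink`` the product
    state C° + T°.
    """

    graph: nx.DiGraph
    source: tuple
    sink: tuple
    states: dict  # node key -> MoietyVector

    @property
    def branch_points(self) -> list:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) > 1]

    def to_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        for n in self.graph.nodes:
            g.add_node(str(n))
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(str(u), str(v), rules=",".join(map(str, sorted(data["rules"]))))
        nx.write_graphml(g, str(path))

    def to_dot(self, path: str | Path) -> None:
        lines = ["digraph mechanism {"]
        index = {n: i for i, n in enumerate(self.graph.nodes)}
        for n, i in index.items():
            shape = "doublecircle" if n in (self.source, self.sink) else "circle"
            lines.append(f'  n{i} [label="s{i}", shape={shape}];')
        for u, v, data in self.graph.edges(data=True):
            label = ",".join(map(str, sorted(data["rules"])))
            lines.append(f'  n{index[u]} -> n{index[v]} [label="{label}"];')
        lines.append("}")
        Path(path).write_text("\n".join(lines))


def build_step_network(
    candidates: Sequence[OrderedMechanism],
    problem: ReactionProblem,
    generic_moieties: Iterable[MoietyId] = (),
) -> StepNetwork:
    """Compile candidate mechanisms into one branching step network.

    Every candidate's prefix states are walked from C°; states are keyed by
    their moiety vector with the configured generic-exchange moieties
    (interchangeable proton donors/acceptors) projected out, which merges
    parallel edges that differ only in the choice of general acid/base —
    their rule ids are combined on the shared edge.
    """
    if not candidates:
        raise ValueError("no candidates to compile")
    generic = frozenset(generic_moieties)
    matrix = problem.rule_matrix

    def project(vec: MoietyVector) -> MoietyVector:
        return vec.without(generic)

    graph = nx.DiGraph()
    states: dict[tuple, MoietyVector] = {}

    def node_key(vec: MoietyVector) -> tuple:
        proj = project(vec)
        key = proj.signature()
        states[key] = proj
        if key not in graph:
            graph.add_node(key)
        return key

    source = node_key(problem.initial_counts)
    sink = node_key(problem.initial_counts + problem.target)
    for mech in candidates:
        state = problem.initial_counts
        prev = node_key(state)
        for rid in mech.sequence:
            state = state + matrix.rule_by_id(rid).delta
            cur = node_key(state)
            if graph.has_edge(prev, cur):
                graph[prev][cur]["rules"].add(rid)
            else:
                graph.add_edge(prev, cur, rules={rid})
            prev = cur
        if prev != sink:
            raise ValueError(
                "candidate does not terminate at the product state "
                "(its generic moieties do not cancel in the target)"
            )
    return StepNetwork(graph=graph, source=source, sink=sink, states=states)
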