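"""Similarity-based re-ranking of candidate mechanisms.

Each candidate mechanism (a multiset of elementary steps) is compared
against every validated mechanism in a reference database with an unordered
similarity score in [0, 1] (0 = no shared steps, 1 = identical step
multisets).  A candidate's score is its maximum over the database — the
similarity to its closest known analog — and candidates are re-ranked in
descending score order, ties broken by the original parsimony rank.

Step identity is whatever hashable key the records carry: rule ids for
within-database comparison, or canonical serialized rule deltas so that
candidates built from one rule file can be compared against mechanism
records from another.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Literal, Optional, Sequence

from .rules import RuleMatrix
from .solver import OrderedMechanism

__all__ = [
    "MechanismRecord",
    "SimilarityScore",
    "RankedCandidate",
    "unordered_similarity",
    "max_similarity",
    "rerank",
    "candidate_record",
    "read_mechanism_db",
    "write_mechanism_db",
]

SimilarityMethod = Literal["multiset_jaccard", "jaccard", "dice"]


@dataclass(frozen=True)
class MechanismRecord:
    """A known (or candidate) mechanism as a multiset of step identities."""

    mechanism_id: str
    steps: tuple[Hashable, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"mechanism {self.mechanism_id!r} has no steps")

    @property
    def step_counts(self) -> Counter:
        return Counter(self.steps)


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    best_match: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"similarity out of [0,1]: {self.value}")


def unordered_similarity(
    a: MechanismRecord,
    b: MechanismRecord,
    method: SimilarityMethod = "multiset_jaccard",
) -> float:
    """Unordered step-set similarity in [0, 1].

    Default is the multiset Jaccard index: intersection/union by
    minimum/maximum multiplicities.  ``jaccard`` and ``dice`` operate on the
    step sets ignoring multiplicity.
    """
    ca, cb = a.step_counts, b.step_counts
    if method == "multiset_jaccard":
        keys = set(ca) | set(cb)
        inter = sum(min(ca[k], cb[k]) for k in keys)
        union = sum(max(ca[k], cb[k]) for k in keys)
        return inter / union
    sa, sb = set(ca), set(cb)
    inter_n = len(sa & sb)
    if method == "jaccard":
        return inter_n / len(sa | sb)
    if method == "dice":
        return 2.0 * inter_n / (len(sa) + len(sb))
    raise ValueError(f"unknown similarity method {method!r}")


def max_similarity(
    candidate: MechanismRecord,
    db: Sequence[MechanismRecord],
    method: SimilarityMethod = "multiset_jaccard",
) -> SimilarityScore:
    """Similarity to the closest known analog (first record wins ties)."""
    if not db:
        raise ValueError("mechanism database is empty")
    best_value, best_id = -1.0, ""
    for record in db:
        v = unordered_similarity(candidate, record, method=method)
        if v > best_value:
            best_value, best_id = v, record.mechanism_id
    return SimilarityScore(value=best_value, best_match=best_id)


@dataclass(frozen=True)
class RankedCandidate:
    mechanism: OrderedMechanism
    parsimony_rank: int
    similarity_rank: int
    score: float
    best_match: str


def candidate_record(
    mechanism: OrderedMechanism,
    rule_matrix: Optional[RuleMatrix] = None,
    by: Literal["rule_id", "delta"] = "rule_id",
    mechanism_id: str = "candidate",
) -> MechanismRecord:
    """Express a solver candidate as a comparable mechanism record.

    ``by="delta"`` keys steps by the canonical serialized rule delta, which
    is stable across differently numbered rule files.
    """
    if by == "rule_id":
        steps: tuple[Hashable, ...] = tuple(str(r) for r in mechanism.sequence)
    elif by == "delta":
        if rule_matrix is None:
            raise ValueError("delta-keyed records need the rule matrix")
        steps = tuple(
            json.dumps(rule_matrix.rule_by_id(r).delta.signature())
            for r in mechanism.sequence
        )
    else:
        raise ValueError(f"unknown step key mode {by!r}")
    return MechanismRecord(mechanism_id=mechanism_id, steps=steps)


def rerank(
    candidates: Sequence[OrderedMechanism],
    db: Sequence[MechanismRecord],
    rule_matrix: Optional[RuleMatrix] = None,
    by: Literal["rule_id", "delta"] = "rule_id",
    method: SimilarityMethod = "multiset_jaccard",
) -> list[RankedCandidate]:
    """Re-rank parsimony-ordered candidates by descending similarity score.

    A stable sort: equal scores keep the original parsimony order, so
    re-ranking never performs worse than the parsimony baseline when all
    scores tie.  Output is a permutation of the input with both ranks kept.
    """
    if not candidates:
        raise ValueError("no candidates to rerank")
    scored = []
    for mech in candidates:
        record = candidate_record(mech, rule_matrix=rule_matrix, by=by)
        s = max_similarity(record, db, method=method)
        scored.append((mech, s))
    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i][1].value, scored[i][0].parsimony_rank),
    )
    out = []
    for pos, i in enumerate(order, start=1):
        mech, s = scored[i]
        out.append(
            RankedCandidate(
                mechanism=mech,
                parsimony_rank=mech.parsimony_rank,
                similarity_rank=pos,
                score=s.value,
                best_match=s.best_match,
            )
        )
    return out


def read_mechanism_db(path: str | Path) -> list[MechanismRecord]:
    """JSON list of {mechanism_id, steps, metadata}."""
    doc = json.loads(Path(path).read_text())
    records = []
    for entry in doc:
        records.append(
            MechanismRecord(
                mechanism_id=str(entry["mechanism_id"]),
                steps=tuple(str(s) for s in entry["steps"]),
                metadata=dict(entry.get("metadata", {})),
            )
        )
    return records


def write_mechanism_db(records: Sequence[MechanismRecord], path: str | Path) -> None:
    doc = [
        {
            "mechanism_id": r.mechanism_id,
            "steps": list(r.steps),
            "metadata": r.metadata,
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
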