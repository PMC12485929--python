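"""Elementary-rule database: build, deduplicate, and persist the rule matrix.

An elementary rule abstracts one mechanistic step as signed gains/losses of
moieties (a column of the matrix T).  Steps curated from mechanism databases
are ingested as balanced mini-reactions, deduplicated by exact delta
equality, optionally closed under reversal ("each step treated as
reversible"), and combined with protonation/deprotonation rules for common
proton-carrier moieties.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .moieties import (
    BalanceReport,
    MoietyError,
    MoietyId,
    MoietyVector,
    Molecule,
    Species,
    check_balance,
    reaction_delta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ElementaryRule",
    "RuleMatrix",
    "ElementaryStep",
    "RuleBuildError",
    "rule_from_step",
    "reverse_rule",
    "protonation_rules",
    "build_rule_matrix",
    "read_rules",
    "write_rules",
    "DEFAULT_PROTON_CARRIERS",
]


class RuleBuildError(ValueError):
    """Raised when a step or file cannot be turned into valid rules."""

    def __init__(self, message: str, balance: Optional[BalanceReport] = None):
        super().__init__(message)
        self.balance = balance


@dataclass(frozen=True)
class ElementaryRule:
    """One elementary mechanistic rule: a non-zero moiety delta plus metadata."""

    rule_id: int
    delta: MoietyVector
    direction: str = "forward"  # forward | backward
    provenance: str = ""
    is_protonation: bool = False

    def __post_init__(self) -> None:
        if not self.delta:
            raise RuleBuildError(f"rule {self.rule_id}: delta must be non-zero")
        if self.direction not in ("forward", "backward"):
            raise RuleBuildError(f"rule {self.rule_id}: bad direction {self.direction!r}")


@dataclass(frozen=True)
class ElementaryStep:
    """A balanced elementary-step reaction awaiting conversion into a rule."""

    substrates: Sequence[Species]
    products: Sequence[Species]
    labels: Mapping[Molecule, str] = field(default_factory=dict)
    provenance: str = ""


def rule_from_step(
    step_substrates: Sequence[Species],
    step_products: Sequence[Species],
    labels: Optional[Mapping[Molecule, str]] = None,
    provenance: str = "",
    rule_id: int = 0,
) -> ElementaryRule:
    """Encode one elementary step as a rule delta.

    The step must be elementally and charge balanced (labeled catalytic
    species participate in the balance like any other molecule).  Moieties
    of molecules present in ``labels`` are tagged as catalytic (M*).
    """
    labels = labels or {}
    report = check_balance(step_substrates, step_products)
    if not report.balanced:
        raise RuleBuildError(
            f"step is not balanced (element deficits {dict(report.element_deficits)}, "
            f"charge deficit {report.charge_deficit})",
            balance=report,
        )
    delta = reaction_delta(
        step_substrates, step_products, substrate_labels=labels, product_labels=labels
    )
    if not delta:
        raise RuleBuildError("step has a zero moiety delta (identical on both sides)")
    return ElementaryRule(rule_id=rule_id, delta=delta, provenance=provenance)


def reverse_rule(rule: ElementaryRule, rule_id: Optional[int] = None) -> ElementaryRule:
    """The backward version of a rule: negated delta, flipped direction."""
    return replace(
        rule,
        rule_id=rule.rule_id + 1 if rule_id is None else rule_id,
        delta=-rule.delta,
        direction="backward" if rule.direction == "forward" else "forward",
    )


# Common proton carriers: (protonated key, deprotonated key) environment
# pairs.  Defaults cover the water family (oxonium/water, water/hydroxide);
# charged side-chain carriers are supplied per run as labeled moieties.
DEFAULT_PROTON_CARRIERS: tuple[tuple[MoietyId, MoietyId], ...] = (
    (MoietyId("O+1H3()"), MoietyId("O+0H2()")),  # H3O+ / H2O
    (MoietyId("O+0H2()"), MoietyId("O-1H1()")),  # H2O / OH-
)


def _check_protonation_pair(protonated: MoietyId, deprotonated: MoietyId) -> None:
    pf, df = protonated.key_fields(), deprotonated.key_fields()
    if pf is None or df is None:
        raise RuleBuildError(
            f"protonation pair ({protonated}, {deprotonated}) has non-chemical keys"
        )
    p_el, p_chg, p_h, p_nbr = pf
    d_el, d_chg, d_h, d_nbr = df
    if p_el != d_el or p_h != d_h + 1 or p_chg != d_chg + 1:
        raise RuleBuildError(
            f"pair ({protonated}, {deprotonated}) must differ by exactly one "
            "hydrogen and one unit of charge on the same element"
        )


def protonation_rules(
    moiety_pairs: Sequence[tuple[MoietyId, MoietyId]],
    carriers: Sequence[tuple[MoietyId, MoietyId]] = DEFAULT_PROTON_CARRIERS,
    start_id: int = 0,
) -> list[ElementaryRule]:
    """Protonation/deprotonation rule pairs for the given moieties.

    Each (protonated, deprotonated) target pair must differ by exactly one
    hydrogen and one unit of charge.  For every configured proton carrier a
    mutually inverse rule pair is produced whose delta also adjusts the
    carrier moieties (the proton has to come from somewhere).
    """
    rules: list[ElementaryRule] = []
    rid = start_id
    for prot, deprot in moiety_pairs:
        _check_protonation_pair(prot, deprot)
        for c_prot, c_deprot in carriers:
            _check_protonation_pair(c_prot, c_deprot)
            delta = MoietyVector({deprot: -1, prot: 1}) + MoietyVector(
                {c_prot: -1, c_deprot: 1}
            )
            if not delta:  # target pair == carrier pair: null exchange
                continue
            fwd = ElementaryRule(
                rule_id=rid,
                delta=delta,
                direction="forward",
                provenance=f"protonation via {c_prot.serialize()}",
                is_protonation=True,
            )
            rules.append(fwd)
            rules.append(reverse_rule(fwd, rule_id=rid + 1))
            rid += 2
    return rules


class RuleMatrix:
    """The rule matrix T: unique elementary rules over an indexed moiety set.

    ``moiety_index`` is the sorted union of the support of all rule deltas
    (set M); ``labeled_set`` is the catalytic subset M*.  Rule ids are unique
    and no two rules share an identical delta.
    """

    def __init__(
        self,
        rules: Sequence[ElementaryRule],
        labeled_set: Optional[Iterable[MoietyId]] = None,
    ):
        seen_ids: set[int] = set()
        seen_deltas: set[MoietyVector] = set()
        for r in rules:
            if r.rule_id in seen_ids:
                raise RuleBuildError(f"duplicate rule_id {r.rule_id}")
            seen_ids.add(r.rule_id)
            if r.delta in seen_deltas:
                raise RuleBuildError(f"rule {r.rule_id} duplicates another rule's delta")
            seen_deltas.add(r.delta)
        self.rules: tuple[ElementaryRule, ...] = tuple(rules)
        index: set[MoietyId] = set()
        inferred_labeled: set[MoietyId] = set()
        for r in self.rules:
            for m in r.delta:
                index.add(m)
                if m.labeled:
                    inferred_labeled.add(m)
        self.moiety_index: tuple[MoietyId, ...] = tuple(sorted(index))
        labeled = inferred_labeled | set(labeled_set or ())
        self.labeled_set: frozenset[MoietyId] = frozenset(labeled)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleMatrix):
            return NotImplemented
        return (
            self.rules == other.rules
            and self.labeled_set == other.labeled_set
        )

    def rule_by_id(self, rule_id: int) -> ElementaryRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)


def build_rule_matrix(
    steps: Sequence[ElementaryStep],
    reversible: bool = True,
    protonation_pairs: Sequence[tuple[MoietyId, MoietyId]] = (),
    carriers: Sequence[tuple[MoietyId, MoietyId]] = DEFAULT_PROTON_CARRIERS,
    labeled_set: Optional[Iterable[MoietyId]] = None,
) -> RuleMatrix:
    """Assemble the unique-rule matrix from elementary steps.

    Unbalanced or zero-delta steps are logged and skipped (the curation
    criterion); deltas are deduplicated by exact vector equality.  With
    ``reversible`` each surviving step also contributes its negation.
    """
    deltas_seen: dict[MoietyVector, int] = {}
    rules: list[ElementaryRule] = []
    rid = 0

    def _add(delta: MoietyVector, direction: str, provenance: str, is_prot: bool) -> None:
        nonlocal rid
        if delta in deltas_seen:
            logger.info("duplicate delta skipped (first seen as rule %d)", deltas_seen[delta])
            return
        rules.append(
            ElementaryRule(
                rule_id=rid,
                delta=delta,
                direction=direction,
                provenance=provenance,
                is_protonation=is_prot,
            )
        )
        deltas_seen[delta] = rid
        rid += 1

    for i, step in enumerate(steps):
        try:
            base = rule_from_step(
                step.substrates, step.products, step.labels, step.provenance, rule_id=0
            )
        except RuleBuildError as exc:
            logger.warning("step %d rejected: %s", i, exc)
            continue
        _add(base.delta, "forward", step.provenance, False)
        if reversible:
            _add(-base.delta, "backward", step.provenance, False)

    for rule in protonation_rules(protonation_pairs, carriers=carriers):
        _add(rule.delta, rule.direction, rule.provenance, True)

    return RuleMatrix(rules, labeled_set=labeled_set)


# ---------------------------------------------------------------------------
# Persistence.  Two dialects:
#   * JSON: one document {"rules": [...], "labeled": [...]}.
#   * CSV: one file of typed rows — "meta" rows carry rule metadata,
#     "delta" rows carry sparse (rule_id, moiety_key, count) triplets and
#     "labeled" rows list the M* keys.
# ---------------------------------------------------------------------------

_CSV_HEADER = ["record", "rule_id", "direction", "is_protonation", "provenance", "moiety_key", "count"]


def write_rules(matrix: RuleMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "rules": [
                {
                    "rule_id": r.rule_id,
                    "direction": r.direction,
                    "is_protonation": r.is_protonation,
                    "provenance": r.provenance,
                    "delta": {k: v for k, v in r.delta.signature()},
                }
                for r in matrix.rules
            ],
            "labeled": sorted(m.serialize() for m in matrix.labeled_set),
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        return
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for r in matrix.rules:
            w.writerow(["meta", r.rule_id, r.direction, int(r.is_protonation), r.provenance, "", ""])
            for key, count in r.delta.signature():
                w.writerow(["delta", r.rule_id, "", "", "", key, count])
        for m in sorted(matrix.labeled_set):
            w.writerow(["labeled", "", "", "", "", m.serialize(), ""])


def _rules_from_parts(
    meta: dict[int, dict], deltas: dict[int, dict[MoietyId, int]], labeled: set[MoietyId]
) -> RuleMatrix:
    rules = []
    for rid in sorted(meta):
        if rid not in deltas:
            raise RuleBuildError(f"rule {rid} has metadata but no delta rows")
        m = meta[rid]
        rules.append(
            ElementaryRule(
                rule_id=rid,
                delta=MoietyVector(deltas[rid]),
                direction=m["direction"],
                provenance=m["provenance"],
                is_protonation=m["is_protonation"],
            )
        )
    orphans = set(deltas) - set(meta)
    if orphans:
        raise RuleBuildError(f"delta rows reference unknown rule_ids: {sorted(orphans)}")
    return RuleMatrix(rules, labeled_set=labeled)


def read_rules(path: str | Path) -> RuleMatrix:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        meta: dict[int, dict] = {}
        deltas: dict[int, dict[MoietyId, int]] = {}
        for entry in doc.get("rules", []):
            rid = int(entry["rule_id"])
            if rid in meta:
                raise RuleBuildError(f"duplicate rule_id {rid} in {path}")
            meta[rid] = {
                "direction": entry.get("direction", "forward"),
                "provenance": entry.get("provenance", ""),
                "is_protonation": bool(entry.get("is_protonation", False)),
            }
            deltas[rid] = {
                MoietyId.parse(k): int(v) for k, v in entry["delta"].items()
            }
        labeled = {MoietyId.parse(k) for k in doc.get("labeled", [])}
        return _rules_from_parts(meta, deltas, labeled)

    meta = {}
    deltas = {}
    labeled = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_HEADER:
            raise RuleBuildError(f"{path}: unexpected CSV header {header!r}")
        for ln, row in enumerate(reader, 2):
            if not row or not row[0].strip():
                continue
            kind = row[0]
            try:
                if kind == "meta":
                    rid = int(row[1])
                    if rid in meta:
                        raise RuleBuildError(f"{path}:{ln}: duplicate rule_id {rid}")
                    meta[rid] = {
                        "direction": row[2],
                        "is_protonation": bool(int(row[3])),
                        "provenance": row[4],
                    }
                elif kind == "delta":
                    rid = int(row[1])
                    key = MoietyId.parse(row[5])
                    deltas.setdefault(rid, {})[key] = int(row[6])
                elif kind == "labeled":
                    labeled.add(MoietyId.parse(row[5]))
                else:
                    raise RuleBuildError(f"{path}:{ln}: unknown record type {kind!r}")
            except (ValueError, MoietyError) as exc:
                raise RuleBuildError(f"{path}:{ln}: malformed row {row!r}: {exc}") from exc
    return _rules_from_parts(meta, deltas, labeled)
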