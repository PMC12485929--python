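"""Synthetic instances and brute-force oracles for the solver stack.

Abstract (opaque-id) moieties decouple MILP correctness from the chemistry
encoding: an instance is a random sparse rule matrix plus a planted feasible
rule sequence whose summed delta becomes the target.  Initial counts are set
to the running minimum of the planted prefix sums, which *guarantees* the
planted sequence is feasible — a recovery failure therefore always indicts
the solver, never the generator.  A miniature esterase chemistry bridges the
abstract layer and the pipeline (two catalytic strategies: a covalent
enzyme intermediate versus direct attack by water).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .moieties import MoietyId, MoietyVector
from .rules import ElementaryRule, RuleMatrix
from .solver import ReactionProblem

__all__ = [
    "SyntheticInstance",
    "abstract_moiety",
    "generate_instance",
    "validate_planted",
    "brute_force_min_mechanism",
    "toy_esterase",
    "random_smiles_pool",
]


def abstract_moiety(name: str, labeled: bool = False, tag: str = "cat") -> MoietyId:
    """An opaque moiety id for solver-level tests (no chemistry attached)."""
    return MoietyId(
        environment_key=f"abstract:{name}",
        labeled=labeled,
        label_tag=tag if labeled else None,
    )


@dataclass(frozen=True)
class SyntheticInstance:
    rule_matrix: RuleMatrix
    problem: ReactionProblem
    planted_sequence: tuple[int, ...]
    planted_length: int
    generator_seed: int


def validate_planted(instance: SyntheticInstance) -> bool:
    """Independent prefix-sum check of the planted sequence.

    Walks the sequence with plain integer arithmetic: every prefix must keep
    all unlabeled moieties non-negative and the final state must equal
    C° + T°.
    """
    problem = instance.problem
    state = dict(problem.initial_counts)
    exempt = problem.exempt
    for rid in instance.planted_sequence:
        rule = problem.rule_matrix.rule_by_id(rid)
        for m, t in rule.delta.items():
            state[m] = state.get(m, 0) + t
        for m, v in state.items():
            if v < 0 and m not in exempt:
                return False
    final = MoietyVector({m: v for m, v in state.items()})
    return final == problem.initial_counts + problem.target


def generate_instance(
    n_moieties: int = 5,
    n_rules: int = 6,
    planted_length: int = 3,
    labeled_fraction: float = 0.2,
    seed: int = 0,
    max_retries: int = 50,
) -> SyntheticInstance:
    """Random solvable instance with a planted feasible mechanism.

    Rule deltas are sparse (2–3 moieties, entries in ±{1,2}) and pairwise
    distinct.  A ``labeled_fraction`` of moieties is marked catalytic (M*).
    Draws whose planted sequence sums to a zero target are resampled up to
    ``max_retries`` times.  Generation is a pure function of its parameters
    and seed.
    """
    if min(n_moieties, n_rules, planted_length) < 1:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)

    n_labeled = int(round(labeled_fraction * n_moieties))
    for _attempt in range(max_retries):
        labeled_idx = set(
            rng.choice(n_moieties, size=n_labeled, replace=False).tolist()
        ) if n_labeled else set()
        moieties = [
            abstract_moiety(f"m{i}", labeled=(i in labeled_idx)) for i in range(n_moieties)
        ]

        deltas: list[MoietyVector] = []
        seen: set[MoietyVector] = set()
        guard = 0
        while len(deltas) < n_rules and guard < 200 * n_rules:
            guard += 1
            k = int(rng.integers(2, min(3, n_moieties) + 1))
            idx = rng.choice(n_moieties, size=k, replace=False)
            entries = {
                moieties[i]: int(rng.choice([-2, -1, 1, 2])) for i in idx
            }
            vec = MoietyVector(entries)
            if vec and vec not in seen:
                seen.add(vec)
                deltas.append(vec)
        if len(deltas) < n_rules:
            continue
        rules = [
            ElementaryRule(rule_id=i, delta=d, provenance=f"synthetic seed={seed}")
            for i, d in enumerate(deltas)
        ]
        matrix = RuleMatrix(rules)

        sequence = tuple(int(r) for r in rng.integers(0, n_rules, size=planted_length))
        total = MoietyVector()
        prefix_min: dict[MoietyId, int] = {}
        state: dict[MoietyId, int] = {}
        for rid in sequence:
            for m, t in rules[rid].delta.items():
                state[m] = state.get(m, 0) + t
            for m, v in state.items():
                prefix_min[m] = min(prefix_min.get(m, 0), v)
            total = total + rules[rid].delta
        if not total:
            continue  # degenerate: planted walk returns to the origin

        exempt_keys = {m for m in moieties if m.labeled}
        c0 = MoietyVector(
            {
                m: -v
                for m, v in prefix_min.items()
                if v < 0 and m not in exempt_keys
            }
        )
        problem = ReactionProblem(
            target=total,
            initial_counts=c0,
            rule_matrix=matrix,
        )
        return SyntheticInstance(
            rule_matrix=matrix,
            problem=problem,
            planted_sequence=sequence,
            planted_length=planted_length,
            generator_seed=seed,
        )
    raise RuntimeError(
        f"could not generate a non-degenerate instance in {max_retries} tries (seed={seed})"
    )


def brute_force_min_mechanism(
    problem: ReactionProblem, max_len: int, guard: int = 1_000_000
) -> Optional[list[int]]:
    """Exhaustive shortest feasible ordered mechanism, or None.

    Enumerates every rule sequence of length 1..max_len, checking balance
    against the target and prefix non-negativity of unlabeled moieties.
    Ground truth for solver equivalence; refuses to run when the sequence
    count exceeds ``guard``.
    """
    rules = problem.rule_matrix.rules
    n = len(rules)
    total_seqs = sum(n**L for L in range(1, max_len + 1))
    if total_seqs > guard:
        raise ValueError(f"{total_seqs} sequences exceeds the enumeration guard {guard}")
    if not problem.target:
        return []
    exempt = problem.exempt
    c0 = problem.initial_counts
    for L in range(1, max_len + 1):
        for combo in itertools.product(range(n), repeat=L):
            state: dict[MoietyId, int] = dict(c0)
            ok = True
            for ri in combo:
                for m, t in rules[ri].delta.items():
                    v = state.get(m, 0) + t
                    state[m] = v
                    if v < 0 and m not in exempt:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            if MoietyVector(state) == c0 + problem.target:
                return [rules[ri].rule_id for ri in combo]
    return None


def toy_esterase() -> tuple[RuleMatrix, ReactionProblem, dict]:
    """Miniature ester-hydrolysis chemistry with two catalytic strategies.

    Overall reaction: ester + water → acid + alcohol.  Strategy A forms a
    covalent acyl-enzyme intermediate on a serine, assisted by a general
    base (histidine or aspartate variants); strategy B is a direct
    nucleophilic attack by water through a tetrahedral intermediate.  All
    strategies take two steps, so enumeration must surface ≥ 3 distinct
    supports and the compiled step network branches at the initial state.
    """
    est = abstract_moiety("ester")
    wat = abstract_moiety("water")
    acid = abstract_moiety("acid")
    alc = abstract_moiety("alcohol")
    tet = abstract_moiety("tetrahedral")
    ser = abstract_moiety("ser-OH", labeled=True, tag="Ser")
    acyl = abstract_moiety("acyl-enzyme", labeled=True, tag="Ser")
    his0 = abstract_moiety("his", labeled=True, tag="His")
    hisH = abstract_moiety("his-H+", labeled=True, tag="His")
    asp0 = abstract_moiety("asp-O-", labeled=True, tag="Asp")
    aspH = abstract_moiety("asp-OH", labeled=True, tag="Asp")

    rules = [
        # Strategy A, histidine as general base
        ElementaryRule(0, MoietyVector({est: -1, ser: -1, his0: -1, acyl: 1, alc: 1, hisH: 1}),
                       provenance="acylation (His base)"),
        ElementaryRule(1, MoietyVector({wat: -1, acyl: -1, hisH: -1, acid: 1, ser: 1, his0: 1}),
                       provenance="deacylation (His acid)"),
        # Strategy A, aspartate as general base
        ElementaryRule(2, MoietyVector({est: -1, ser: -1, asp0: -1, acyl: 1, alc: 1, aspH: 1}),
                       provenance="acylation (Asp base)"),
        ElementaryRule(3, MoietyVector({wat: -1, acyl: -1, aspH: -1, acid: 1, ser: 1, asp0: 1}),
                       provenance="deacylation (Asp acid)"),
        # Strategy B: direct attack by water
        ElementaryRule(4, MoietyVector({est: -1, wat: -1, tet: 1}),
                       provenance="direct water attack"),
        ElementaryRule(5, MoietyVector({tet: -1, acid: 1, alc: 1}),
                       provenance="tetrahedral collapse"),
    ]
    matrix = RuleMatrix(rules)
    target = MoietyVector({est: -1, wat: -1, acid: 1, alc: 1})
    problem = ReactionProblem(
        target=target,
        initial_counts=MoietyVector({est: 1, wat: 1}),
        rule_matrix=matrix,
    )
    expected = {
        "strategies": [(0, 1), (2, 3), (4, 5)],
        "generic_moieties": frozenset({his0, hisH, asp0, aspH}),
        "n_supports": 3,
        "planted_length": 2,
    }
    return matrix, problem, expected


def random_smiles_pool() -> list[str]:
    """Small, diverse SMILES set for encoding-invariance tests."""
    return [
        "C", "O", "N", "CO", "CC", "CCO", "CC=O", "CC(=O)O", "CC(=O)[O-]",
        "c1ccccc1", "c1ccccc1O", "c1ccc(cc1)C(=O)O", "C1CCCCC1", "C1CCOC1",
        "OCC(O)CO", "NCC(=O)O", "N[C@@H](C)C(=O)O", "CC(C)CC(N)C(=O)O",
        "C(=O)(O)O", "OC(=O)CC(=O)O", "CSC", "CS", "CCS", "OP(=O)(O)O",
        "COP(=O)(O)O", "NC(=N)N", "Nc1ncnc2[nH]cnc12", "OCC1OC(O)C(O)C(O)C1O",
        "CC(=O)SC", "OO", "[OH-]", "[NH4+]", "CC[NH3+]", "CC(=O)NC",
        "C#N", "CC#N", "OC=O", "C=C", "C=CC=C", "CC(C)=O", "CNC", "CN(C)C",
        "O=C1CCCCC1", "OC1CCCCC1", "N#C[O-]", "S=C=N", "FC(F)F", "ClCCl",
        "BrCC", "IC",
    ]
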