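"""MILP formulations: selection, ordering, monolithic, cuts, enumeration."""

import pytest

from enzymech import (
    Cut,
    ElementaryRule,
    MoietyVector,
    ReactionProblem,
    RuleMatrix,
    RuleSelection,
    SolverConfig,
    enumerate_mechanisms,
    solve_min_order_rules,
    solve_min_rules,
    solve_order_rules,
)
from enzymech.fixtures import (
    abstract_moiety,
    brute_force_min_mechanism,
    generate_instance,
)

CFG = SolverConfig(max_rules=5, max_steps=5, time_limit=60.0)


def mechanism_is_valid(problem, mech):
    """Independent check: balance, multiset consistency, prefix feasibility."""
    total = MoietyVector()
    state = dict(problem.initial_counts)
    counts = {}
    for rid in mech.sequence:
        counts[rid] = counts.get(rid, 0) + 1
        delta = problem.rule_matrix.rule_by_id(rid).delta
        total = total + delta
        for m, t in delta.items():
            state[m] = state.get(m, 0) + t
        if any(v < 0 for m, v in state.items() if m not in problem.exempt):
            return False
    return total == problem.target and counts == mech.selection.counts


class TestMinRules:
    def test_two_step_optimum(self, abc_instance):
        matrix, problem, ids = abc_instance
        # without rule C the only balancing multiset is {A, B}
        reduced = RuleMatrix(matrix.rules[:2])
        prob2 = ReactionProblem(
            target=problem.target,
            initial_counts=problem.initial_counts,
            rule_matrix=reduced,
        )
        sel = solve_min_rules(prob2, CFG)
        assert sel.counts == {ids["A"]: 1, ids["B"]: 1}

    def test_shortcut_rule_wins_then_cut_reveals_pair(self, abc_instance):
        _, problem, ids = abc_instance
        first = solve_min_rules(problem, CFG)
        assert first.counts == {ids["C"]: 1}
        second = solve_min_rules(problem, CFG, prior_solutions=[first])
        assert second.counts == {ids["A"]: 1, ids["B"]: 1}

    def test_zero_target_trivial_optimum(self, abc_instance):
        matrix, problem, _ = abc_instance
        prob0 = ReactionProblem(
            target=MoietyVector(),
            initial_counts=problem.initial_counts,
            rule_matrix=matrix,
        )
        sel = solve_min_rules(prob0, CFG)
        assert sel.total_steps == 0

    def test_infeasible_target(self):
        m1 = abstract_moiety("m1")
        matrix = RuleMatrix([ElementaryRule(0, MoietyVector({m1: 2}))])
        prob = ReactionProblem(
            target=MoietyVector({m1: 1}),
            initial_counts=MoietyVector(),
            rule_matrix=matrix,
        )
        assert solve_min_rules(prob, CFG) is None


class TestOrderRules:
    def test_only_feasible_order_found(self, abc_instance):
        _, problem, ids = abc_instance
        sel = RuleSelection(counts={ids["A"]: 1, ids["B"]: 1})
        mech = solve_order_rules(problem, sel, CFG)
        # B first would drive m2 to -1
        assert mech.sequence == (ids["A"], ids["B"])

    def test_single_rule_selection(self, abc_instance):
        _, problem, ids = abc_instance
        mech = solve_order_rules(problem, RuleSelection(counts={ids["C"]: 1}), CFG)
        assert mech.sequence == (ids["C"],)

    def test_labeled_exemption_enables_ordering(self, exemption_instance):
        with_exempt, without_exempt = exemption_instance
        sel = RuleSelection(counts={0: 1, 1: 1})
        mech = solve_order_rules(with_exempt, sel, CFG)
        assert mech is not None and mech.sequence == (0, 1)
        assert solve_order_rules(without_exempt, sel, CFG) is None

    def test_exemption_agrees_with_brute_force(self, exemption_instance):
        with_exempt, without_exempt = exemption_instance
        assert brute_force_min_mechanism(with_exempt, 2) == [0, 1]
        assert brute_force_min_mechanism(without_exempt, 2) is None


class TestMinOrderRules:
    def test_matches_decomposed_on_worked_instance(self, abc_instance):
        _, problem, ids = abc_instance
        mech = solve_min_order_rules(problem, CFG)
        assert mech.sequence == (ids["C"],)

    def test_infeasible_instance(self):
        m1 = abstract_moiety("m1")
        matrix = RuleMatrix([ElementaryRule(0, MoietyVector({m1: 2}))])
        prob = ReactionProblem(
            target=MoietyVector({m1: 1}),
            initial_counts=MoietyVector(),
            rule_matrix=matrix,
        )
        assert solve_min_order_rules(prob, CFG) is None

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_instances(self, seed):
        inst = generate_instance(
            n_moieties=5, n_rules=6, planted_length=3, seed=seed
        )
        cfg = SolverConfig(max_rules=4, max_steps=4, top_n=1, time_limit=60)
        bf = brute_force_min_mechanism(inst.problem, max_len=4)
        mono = solve_min_order_rules(inst.problem, cfg)
        dec = enumerate_mechanisms(inst.problem, cfg)
        assert bf is not None
        assert mono is not None and mono.total_steps == len(bf)
        assert dec.mechanisms and dec.mechanisms[0].total_steps == len(bf)


class TestIntegerCuts:
    @pytest.fixture()
    def multiplicity_instance(self):
        """y_A=2 balances the same target as {A,B,C}; supports diverge under cuts."""
        m1, m2 = abstract_moiety("m1"), abstract_moiety("m2")
        rules = [
            ElementaryRule(0, MoietyVector({m1: 2})),        # A
            ElementaryRule(1, MoietyVector({m1: 1, m2: 1})),  # B
            ElementaryRule(2, MoietyVector({m1: 1, m2: -1})),  # C
        ]
        return ReactionProblem(
            target=MoietyVector({m1: 4}),
            initial_counts=MoietyVector({m2: 1}),
            rule_matrix=RuleMatrix(rules),
        )

    def test_as_printed_also_kills_higher_multiplicity(self, multiplicity_instance):
        cut = Cut(style="as_printed", counts={0: 1, 1: 1})
        cfg = SolverConfig(max_rules=6, time_limit=60, cut_style="as_printed")
        # sum over {A,B} of y <= 1 eliminates {A:2}, {A,B,C} and {B:2,C:2}
        assert solve_min_rules(multiplicity_instance, cfg, cuts=[cut]) is None

    def test_support_exact_keeps_reuse_solutions(self, multiplicity_instance):
        cut = Cut(style="support_exact", counts={0: 1, 1: 1})
        cfg = SolverConfig(max_rules=6, time_limit=60, cut_style="support_exact")
        sel = solve_min_rules(multiplicity_instance, cfg, cuts=[cut])
        assert sel is not None and sel.counts == {0: 2}

    def test_cut_excludes_prior_but_not_other_support(self, abc_instance):
        _, problem, ids = abc_instance
        for style in ("as_printed", "support_exact"):
            cut = Cut(style=style, counts={ids["C"]: 1})
            cfg = SolverConfig(max_rules=5, time_limit=60, cut_style=style)
            sel = solve_min_rules(problem, cfg, cuts=[cut])
            assert sel.counts == {ids["A"]: 1, ids["B"]: 1}

    def test_cutting_all_supports_proves_infeasible(self, abc_instance):
        _, problem, ids = abc_instance
        cuts = [
            Cut(style="as_printed", counts={ids["C"]: 1}),
            Cut(style="as_printed", counts={ids["A"]: 1, ids["B"]: 1}),
        ]
        assert solve_min_rules(problem, CFG, cuts=cuts) is None

    def test_count_exact_excludes_only_that_count_vector(self, multiplicity_instance):
        cfg = SolverConfig(max_rules=6, time_limit=60)
        first = solve_min_rules(multiplicity_instance, cfg)
        assert first.counts == {0: 2}
        cut = Cut(style="count_exact", counts=dict(first.counts))
        nxt = solve_min_rules(multiplicity_instance, cfg, cuts=[cut])
        assert nxt is not None and nxt.counts != first.counts
        assert nxt.total_steps == 3  # {A,B,C} is next-most parsimonious


class TestEnumeration:
    def test_ranked_worked_instance(self, abc_instance):
        _, problem, ids = abc_instance
        res = enumerate_mechanisms(problem, SolverConfig(max_rules=5, top_n=2, time_limit=60))
        assert res.outcome == "complete"
        assert [m.selection.support for m in res.mechanisms] == [
            frozenset({ids["C"]}),
            frozenset({ids["A"], ids["B"]}),
        ]
        assert [m.total_steps for m in res.mechanisms] == [1, 2]
        assert [m.parsimony_rank for m in res.mechanisms] == [1, 2]

    def test_exhausts_supports_before_top_n(self, abc_instance):
        _, problem, _ = abc_instance
        res = enumerate_mechanisms(problem, SolverConfig(max_rules=5, top_n=10, time_limit=60))
        assert res.outcome == "complete"
        assert len(res.mechanisms) == 2

    def test_zero_time_limit_is_timeout(self, abc_instance):
        _, problem, _ = abc_instance
        res = enumerate_mechanisms(problem, SolverConfig(time_limit=0.0))
        assert res.mechanisms == () and res.outcome == "timeout"

    def test_infeasible_flag(self):
        m1 = abstract_moiety("m1")
        matrix = RuleMatrix([ElementaryRule(0, MoietyVector({m1: 2}))])
        prob = ReactionProblem(
            target=MoietyVector({m1: 1}),
            initial_counts=MoietyVector(),
            rule_matrix=matrix,
        )
        res = enumerate_mechanisms(prob, CFG)
        assert res.outcome == "infeasible" and not res.mechanisms

    @pytest.mark.parametrize("seed", range(10))
    def test_returned_mechanisms_are_valid_and_monotone(self, seed):
        inst = generate_instance(n_moieties=5, n_rules=6, planted_length=3, seed=100 + seed)
        res = enumerate_mechanisms(
            inst.problem, SolverConfig(max_rules=4, top_n=5, time_limit=60)
        )
        assert res.mechanisms
        supports = [m.selection for m in res.mechanisms]
        assert len(set(supports)) == len(supports)  # pairwise distinct selections
        steps = [m.total_steps for m in res.mechanisms]
        assert steps == sorted(steps)  # parsimony rank monotone in length
        for mech in res.mechanisms:
            assert mechanism_is_valid(inst.problem, mech)


class TestConfigValidation:
    def test_bad_w(self):
        with pytest.raises(ValueError):
            SolverConfig(max_rules=0)

    def test_k_smaller_than_w(self):
        with pytest.raises(ValueError):
            SolverConfig(max_rules=10, max_steps=5)

    def test_default_k_equals_w(self):
        assert SolverConfig(max_rules=7).horizon == 7
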