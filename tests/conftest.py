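import pytest

from enzymech import ElementaryRule, MoietyVector, ReactionProblem, RuleMatrix
from enzymech.fixtures import abstract_moiety


@pytest.fixture()
def abc_instance():
    """The three-rule worked instance: C does in one step what A+B do in two.

    Rules A: m1→m2, B: m2→m3, C: m1→m3 with target m1→m3 starting from one
    unit of m1.
    """
    m1, m2, m3 = (abstract_moiety(n) for n in ("m1", "m2", "m3"))
    rules = [
        ElementaryRule(0, MoietyVector({m1: -1, m2: 1})),
        ElementaryRule(1, MoietyVector({m2: -1, m3: 1})),
        ElementaryRule(2, MoietyVector({m1: -1, m3: 1})),
    ]
    matrix = RuleMatrix(rules)
    problem = ReactionProblem(
        target=MoietyVector({m1: -1, m3: 1}),
        initial_counts=MoietyVector({m1: 1}),
        rule_matrix=matrix,
    )
    return matrix, problem, {"A": 0, "B": 1, "C": 2}


@pytest.fixture()
def exemption_instance():
    """Two-rule instance orderable only because M* moieties may dip negative.

    R1 consumes the catalytic moiety h before R2 regenerates it, and R2
    consumes an unlabeled intermediate that only R1 produces — so [R1, R2]
    is the unique order and it requires the catalytic exemption.
    """

    def build(labeled: bool):
        h = abstract_moiety("h", labeled=labeled, tag="His")
        s, p, i, q = (abstract_moiety(n) for n in ("s", "p", "i", "q"))
        rules = [
            ElementaryRule(0, MoietyVector({h: -1, s: -1, p: 1, i: 1})),
            ElementaryRule(1, MoietyVector({h: 1, i: -1, q: 1})),
        ]
        matrix = RuleMatrix(rules)
        return ReactionProblem(
            target=MoietyVector({s: -1, p: 1, q: 1}),
            initial_counts=MoietyVector({s: 1}),
            rule_matrix=matrix,
        )

    return build(True), build(False)
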