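"""Rule construction, reversibility, protonation rules, persistence."""

import json

import pytest

from enzymech.moieties import MoietyId, MoietyVector, Molecule
from enzymech.rules import (
    DEFAULT_PROTON_CARRIERS,
    ElementaryRule,
    ElementaryStep,
    RuleBuildError,
    RuleMatrix,
    build_rule_matrix,
    protonation_rules,
    read_rules,
    reverse_rule,
    rule_from_step,
    write_rules,
)
from enzymech.fixtures import abstract_moiety


def _mols(*smiles):
    return [(Molecule.from_smiles(s), 1) for s in smiles]


class TestRuleFromStep:
    def test_proton_transfer_step(self):
        """Protonated methylammonium + methoxide -> methylamine + methanol.

        The delta must flip the N-H3+/N-H2 and O-/O-H environments; under
        the committed key the methyl carbons neighboring the charged atoms
        flip too (neighbor charge is part of the key).
        """
        subs = _mols("C[NH3+]", "[O-]C")
        prods = _mols("CN", "CO")
        rule = rule_from_step(subs, prods, provenance="toy proton transfer")
        d = rule.delta
        assert d[MoietyId("N+1H3(-C+0)")] == -1
        assert d[MoietyId("N+0H2(-C+0)")] == 1
        assert d[MoietyId("O-1H0(-C+0)")] == -1
        assert d[MoietyId("O+0H1(-C+0)")] == 1
        assert sum(d.values()) == 0

    def test_labeled_catalytic_species(self):
        """Histidine-style base: its moieties enter the delta labeled."""
        imidazolium = Molecule.from_smiles("c1c[nH+]c[nH]1")
        imidazole = Molecule.from_smiles("c1cnc[nH]1")
        subs = [(imidazolium, 1)] + _mols("[O-]C")
        prods = [(imidazole, 1)] + _mols("CO")
        rule = rule_from_step(
            subs, prods, labels={imidazolium: "His", imidazole: "His"}
        )
        labeled = [m for m in rule.delta if m.labeled]
        assert labeled and all(m.label_tag == "His" for m in labeled)

    def test_unbalanced_step_rejected_with_report(self):
        with pytest.raises(RuleBuildError) as exc:
            rule_from_step(_mols("O", "O"), _mols("OO"))
        assert exc.value.balance is not None
        assert exc.value.balance.element_deficits == {"H": -2}

    def test_zero_delta_step_rejected(self):
        with pytest.raises(RuleBuildError):
            rule_from_step(_mols("CCO"), _mols("OCC"))


class TestReverseRule:
    def test_negation_and_direction(self):
        m1, m2 = abstract_moiety("m1"), abstract_moiety("m2")
        r = ElementaryRule(0, MoietyVector({m1: -1, m2: 1}))
        rev = reverse_rule(r)
        assert rev.delta == -r.delta
        assert rev.direction == "backward"

    def test_involution(self):
        m1, m2 = abstract_moiety("m1"), abstract_moiety("m2")
        r = ElementaryRule(0, MoietyVector({m1: -1, m2: 1}))
        assert reverse_rule(reverse_rule(r)).delta == r.delta


class TestProtonationRules:
    CARBOX = (MoietyId("O+0H1(-C+0)"), MoietyId("O-1H0(-C+0)"))

    def test_pair_yields_mutually_inverse_rules(self):
        rules = protonation_rules([self.CARBOX], carriers=DEFAULT_PROTON_CARRIERS[:1])
        assert len(rules) == 2
        assert rules[1].delta == -rules[0].delta
        assert all(r.is_protonation for r in rules)

    def test_deltas_adjust_the_carrier(self):
        (rule, _) = protonation_rules([self.CARBOX], carriers=DEFAULT_PROTON_CARRIERS[:1])
        oxonium, water = DEFAULT_PROTON_CARRIERS[0]
        assert rule.delta[oxonium] == -1
        assert rule.delta[water] == 1

    def test_cancellation_on_any_vector(self):
        fwd, back = protonation_rules([self.CARBOX], carriers=DEFAULT_PROTON_CARRIERS[:1])
        v = MoietyVector({self.CARBOX[0]: 3, MoietyId("C+0H4()"): 1})
        assert v + fwd.delta + back.delta == v

    def test_empty_pair_list(self):
        assert protonation_rules([]) == []

    def test_bad_pair_rejected(self):
        # differs by two hydrogens
        with pytest.raises(RuleBuildError):
            protonation_rules([(MoietyId("O+0H2()"), MoietyId("O-1H0(-C+0)"))])
        # abstract keys carry no H/charge information
        with pytest.raises(RuleBuildError):
            protonation_rules([(abstract_moiety("a"), abstract_moiety("b"))])


def _toy_steps():
    s1 = ElementaryStep(_mols("CC(=O)OC", "O"), _mols("CC(O)(O)OC"), provenance="hydration")
    s2 = ElementaryStep(_mols("CC(O)(O)OC"), _mols("CC(=O)O", "CO"), provenance="collapse")
    return [s1, s2]


class TestBuildRuleMatrix:
    def test_reversibility_closure(self):
        matrix = build_rule_matrix(_toy_steps(), reversible=True)
        deltas = {r.delta for r in matrix}
        assert all(-d in deltas for d in deltas)
        assert len(matrix) == 4

    def test_duplicate_steps_deduplicated(self):
        matrix = build_rule_matrix(_toy_steps() + _toy_steps(), reversible=False)
        assert len(matrix) == 2

    def test_unbalanced_step_skipped_not_fatal(self):
        bad = ElementaryStep(_mols("O", "O"), _mols("OO"))
        matrix = build_rule_matrix(_toy_steps() + [bad], reversible=False)
        assert len(matrix) == 2

    def test_empty_step_list(self):
        matrix = build_rule_matrix([])
        assert len(matrix) == 0 and matrix.moiety_index == ()

    def test_rule_count_bound(self):
        steps = _toy_steps()
        matrix = build_rule_matrix(
            steps,
            reversible=True,
            protonation_pairs=[TestProtonationRules.CARBOX],
        )
        assert len(matrix) <= 2 * len(steps) + 2 * 2  # pairs x carriers

    def test_labeled_set_collected_from_deltas(self):
        his = abstract_moiety("his", labeled=True, tag="His")
        x = abstract_moiety("x")
        matrix = RuleMatrix([ElementaryRule(0, MoietyVector({his: -1, x: 1}))])
        assert his in matrix.labeled_set

    def test_duplicate_delta_rejected_at_matrix_level(self):
        m = abstract_moiety("m")
        with pytest.raises(RuleBuildError):
            RuleMatrix(
                [
                    ElementaryRule(0, MoietyVector({m: 1})),
                    ElementaryRule(1, MoietyVector({m: 1})),
                ]
            )


class TestPersistence:
    @pytest.fixture()
    def matrix(self):
        his = abstract_moiety("his", labeled=True, tag="His")
        a, b = abstract_moiety("a"), abstract_moiety("b")
        return RuleMatrix(
            [
                ElementaryRule(0, MoietyVector({a: -1, b: 1}), provenance="step one"),
                ElementaryRule(1, MoietyVector({a: 1, b: -1}), direction="backward"),
                ElementaryRule(2, MoietyVector({his: -1, b: 2}), is_protonation=True),
            ]
        )

    @pytest.mark.parametrize("suffix", [".json", ".csv"])
    def test_roundtrip(self, matrix, tmp_path, suffix):
        path = tmp_path / f"rules{suffix}"
        write_rules(matrix, path)
        assert read_rules(path) == matrix

    def test_csv_and_json_agree(self, matrix, tmp_path):
        write_rules(matrix, tmp_path / "rules.json")
        write_rules(matrix, tmp_path / "rules.csv")
        assert read_rules(tmp_path / "rules.json") == read_rules(tmp_path / "rules.csv")

    def test_duplicate_rule_id_rejected(self, tmp_path):
        doc = {
            "rules": [
                {"rule_id": 0, "delta": {"abstract:a": 1}},
                {"rule_id": 0, "delta": {"abstract:b": 1}},
            ],
            "labeled": [],
        }
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(RuleBuildError):
            read_rules(path)

    def test_malformed_row_names_line(self, matrix, tmp_path):
        path = tmp_path / "rules.csv"
        write_rules(matrix, path)
        lines = path.read_text().splitlines()
        lines.insert(3, "delta,notanint,,,,abstract:a,1")
        path.write_text("\n".join(lines))
        with pytest.raises(RuleBuildError, match=":4"):
            read_rules(path)

    def test_labeled_set_roundtrips(self, matrix, tmp_path):
        path = tmp_path / "rules.json"
        write_rules(matrix, path)
        assert read_rules(path).labeled_set == matrix.labeled_set
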