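"""Rule evaluation against gene presence, and substrate-class complex counts."""

import numpy as np
import pandas as pd
import pytest

from genotrait.detect import GeneCountTable
from genotrait.engine import (
    assert_matrix,
    count_expression,
    count_substrate_class,
    evaluate_rules,
)
from genotrait.schema import (
    And,
    HmmVariable,
    Not,
    Or,
    Ref,
    Rule,
    SchemaError,
    compile_ruleset,
    serialize_expression,
)

from .conftest import random_ruleset

DEN_VARS = [
    "narG", "narH", "narI", "napA", "napB", "nirS", "nirK",
    "norB", "norC", "norV", "norW", "nosZ",
]


def oracle_eval(ruleset, presence):
    """Truth-table substitution oracle: textual expansion + Python eval.

    Expands rule references into a pure-variable Boolean expression string
    and lets Python's own parser evaluate it — an independent path from the
    engine's AST walker.
    """
    by_name = {r.name: r for r in ruleset.rules}

    def expand(expr):
        if isinstance(expr, Ref):
            if expr.name in by_name:
                return "(" + expand(by_name[expr.name].expression) + ")"
            return f"bool({int(bool(presence.get(expr.name, False)))})"
        if isinstance(expr, Not):
            return "(not " + expand(expr.operand) + ")"
        joiner = " and " if isinstance(expr, And) else " or "
        return "(" + joiner.join(expand(op) for op in expr.operands) + ")"

    return {name: bool(eval(expand(Ref(name)))) for name in by_name}


@pytest.fixture(scope="module")
def den_ruleset(core_ruleset=None):
    from genotrait.schema import load_packaged_schema

    manifest, rules, _ = load_packaged_schema("core")
    return compile_ruleset(rules, manifest)


class TestEvaluateRules:
    def test_nosZ_alone_asserts_only_step4(self, den_ruleset):
        presence = {v: (v == "nosZ") for v in DEN_VARS}
        values = evaluate_rules(den_ruleset, presence, warn_missing=False)
        assert values["den_step4"]
        assert not any(values[f"den_step{i}"] for i in (1, 2, 3))

    def test_all_denitrification_genes_assert_all_steps(self, den_ruleset):
        presence = {v: True for v in DEN_VARS}
        values = evaluate_rules(den_ruleset, presence, warn_missing=False)
        assert all(values[f"den_step{i}"] for i in (1, 2, 3, 4))
        assert values["denitrification_complete"]

    def test_incomplete_complex_is_false(self, den_ruleset):
        presence = {"narG": True, "narH": True, "narI": False, "napA": False, "napB": False}
        values = evaluate_rules(den_ruleset, presence, warn_missing=False)
        assert not values["den_step1"]

    def test_missing_variables_warn_and_default_false(self, den_ruleset):
        with pytest.warns(UserWarning, match="missing"):
            values = evaluate_rules(den_ruleset, {"nosZ": True})
        assert values["den_step4"] and not values["den_step2"]

    def test_equals_truth_table_oracle(self):
        """Engine vs textual-expansion oracle: 200 random rulesets × 50
        presence vectors = 10⁴ evaluations over ≤12 variables."""
        rng = np.random.default_rng(55)
        for _ in range(200):
            rules, manifest = random_ruleset(rng, n_vars=12, n_rules=5)
            ruleset = compile_ruleset(rules, manifest)
            for _ in range(50):
                presence = {f"v{i}": bool(rng.integers(2)) for i in range(12)}
                got = evaluate_rules(ruleset, presence, warn_missing=False)
                assert got == oracle_eval(ruleset, presence)

    def test_negation_free_monotonicity(self):
        """Adding a present gene never flips a negation-free rule TRUE→FALSE."""
        rng = np.random.default_rng(56)
        for _ in range(50):
            rules, manifest = random_ruleset(rng, n_vars=10, n_rules=4, allow_not=False)
            ruleset = compile_ruleset(rules, manifest)
            presence = {f"v{i}": bool(rng.integers(2)) for i in range(10)}
            base = evaluate_rules(ruleset, presence, warn_missing=False)
            absent = [v for v, on in presence.items() if not on]
            if not absent:
                continue
            presence[str(rng.choice(absent))] = True
            more = evaluate_rules(ruleset, presence, warn_missing=False)
            for name in base:
                assert not (base[name] and not more[name])

    def test_idempotent(self, den_ruleset):
        presence = {v: True for v in DEN_VARS[:6]}
        first = evaluate_rules(den_ruleset, presence, warn_missing=False)
        second = evaluate_rules(den_ruleset, presence, warn_missing=False)
        assert first == second


class TestAssertMatrix:
    def _table(self, counts, columns):
        return GeneCountTable(pd.DataFrame(counts, columns=columns,
                                           index=[f"g{i}" for i in range(len(counts))]))

    def test_all_present_and_all_absent_rows(self, den_ruleset):
        table = self._table(
            [[1] * len(DEN_VARS), [0] * len(DEN_VARS)], DEN_VARS
        )
        with pytest.warns(UserWarning):  # non-denitrification closure vars absent
            matrix = assert_matrix(den_ruleset, table)
        steps = [f"den_step{i}" for i in (1, 2, 3, 4)]
        assert matrix.loc["g0", steps].all()
        assert not matrix.loc["g1"].any()

    def test_equals_per_cell_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(57)
        rules, manifest = random_ruleset(rng, n_vars=12, n_rules=6)
        ruleset = compile_ruleset(rules, manifest)
        counts = rng.integers(0, 3, size=(50, 12))
        table = self._table(counts, [f"v{i}" for i in range(12)])
        matrix = assert_matrix(ruleset, table)
        for genome_id, row in table.presence.iterrows():
            expected = oracle_eval(ruleset, row.to_dict())
            for rule_name, value in expected.items():
                assert matrix.loc[genome_id, rule_name] == value

    def test_rerun_identical(self, den_ruleset):
        table = self._table([[1] * len(DEN_VARS)], DEN_VARS)
        with pytest.warns(UserWarning):
            first = assert_matrix(den_ruleset, table)
        with pytest.warns(UserWarning):
            second = assert_matrix(den_ruleset, table)
        assert first.equals(second)


class TestSubstrateClassCounts:
    MANIFEST = [
        HmmVariable("A", 10.0),
        HmmVariable("B", 10.0),
        HmmVariable("enz", 10.0, substrates=(("glucose", "monosaccharides"),)),
        HmmVariable("x", 10.0),
    ]

    def _table(self, **counts):
        return GeneCountTable(pd.DataFrame([counts], index=["g1"]))

    def test_complex_limited_by_scarcest_subunit(self):
        table = self._table(A=3, B=2, enz=0, x=0)
        complexes = [Rule("uptakeAB", And((Ref("A"), Ref("B"))), "monosaccharides")]
        out = count_substrate_class(table, self.MANIFEST, complexes, "monosaccharides")
        assert out["g1"] == 2  # min(3, 2) from the complex, enz count 0

    def test_standalone_enzyme_counts_directly(self):
        table = self._table(A=0, B=0, enz=5, x=0)
        out = count_substrate_class(table, self.MANIFEST, [], "monosaccharides")
        assert out["g1"] == 5

    def test_alternative_forms_count_max(self):
        table = self._table(A=3, B=0, enz=0, x=2)
        complexes = [
            Rule("alt", Or((And((Ref("A"), Ref("B"))), Ref("x"))), "monosaccharides")
        ]
        out = count_substrate_class(table, self.MANIFEST, complexes, "monosaccharides")
        assert out["g1"] == 2  # max(min(3,0)=0, 2)

    def test_unknown_class_rejected(self):
        table = self._table(A=1, B=1, enz=1, x=1)
        with pytest.raises(SchemaError, match="polyphenols"):
            count_substrate_class(table, self.MANIFEST, [], "polyphenols")

    def test_negation_has_no_count_semantics(self):
        with pytest.raises(SchemaError, match="negation"):
            count_expression(Not(Ref("A")), {"A": 1})

    def test_class_with_no_hits_is_zero(self):
        table = self._table(A=0, B=0, enz=0, x=0)
        complexes = [Rule("uptakeAB", And((Ref("A"), Ref("B"))), "monosaccharides")]
        out = count_substrate_class(table, self.MANIFEST, complexes, "monosaccharides")
        assert out["g1"] == 0
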