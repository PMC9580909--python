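"""Rule evaluation: Boolean assertion of compiled rulesets over gene presence,
and substrate-class-resolved complex counting.

Rules are evaluated in the compiled topological order, so a rule referencing
other rules sees their already-computed values. Missing HMM variables
default to absent (FALSE) with a warning, which keeps the engine usable on
provisional genomes whose annotations are incomplete.

Complex counting follows the subunit-limited interpretation: a multi-subunit
complex is countable as many times as its scarcest required subunit (min
over AND members), while alternative forms of the same function contribute
the best alternative (max over OR members).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detect import GeneCountTable
from .schema import (
    And,
    CompiledRuleset,
    HmmVariable,
    Not,
    Or,
    Ref,
    Rule,
    RuleExpression,
    SchemaError,
)

__all__ = [
    "evaluate_rules",
    "assert_matrix",
    "count_substrate_class",
    "count_expression",
]


def _eval(expr: RuleExpression, values: Mapping[str, bool]) -> bool:
    if isinstance(expr, Ref):
        return values[expr.name]
    if isinstance(expr, Not):
        return not _eval(expr.operand, values)
    if isinstance(expr, And):
        return all(_eval(op, values) for op in expr.operands)
    if isinstance(expr, Or):
        return any(_eval(op, values) for op in expr.operands)
    raise TypeError(f"not a rule expression: {expr!r}")


def evaluate_rules(
    ruleset: CompiledRuleset,
    presence: Mapping[str, bool],
    warn_missing: bool = True,
) -> dict[str, bool]:
    """Evaluate every rule against one genome's variable presence.

    ``presence`` maps HMM-variable names to detection state; variables in the
    ruleset closure missing from it default to FALSE (warning once).
    """
    values: dict[str, bool] = {}
    missing = sorted(set(ruleset.closure) - set(presence))
    if missing and warn_missing:
        warnings.warn(
            f"{len(missing)} HMM variables missing from presence vector, "
            f"defaulting to absent: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    for var in ruleset.closure:
        values[var] = bool(presence.get(var, False))
    for rule in ruleset.rules:  # topological order
        values[rule.name] = _eval(rule.expression, values)
    return {r.name: values[r.name] for r in ruleset.rules}


def assert_matrix(ruleset: CompiledRuleset, table: GeneCountTable) -> pd.DataFrame:
    """Genomes × rules Boolean assertion matrix from a gene count table."""
    presence = table.presence
    extra_missing = sorted(set(ruleset.closure) - set(presence.columns))
    if extra_missing:
        warnings.warn(
            f"count table lacks {len(extra_missing)} ruleset variables "
            f"(treated as absent): {', '.join(extra_missing[:5])}"
            + ("..." if len(extra_missing) > 5 else "")
        )
    rows = {}
    for genome_id, row in presence.iterrows():
        rows[genome_id] = evaluate_rules(ruleset, row.to_dict(), warn_missing=False)
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(index=table.genome_ids)
    return out[list(ruleset.rule_names)].astype(bool)


def count_expression(expr: RuleExpression, counts: Mapping[str, int | float],
                     rules_by_name: Mapping[str, Rule] | None = None) -> float:
    """Complex count of an expression: leaf = gene count, AND = min (all
    subunits required), OR = max (best alternative form). NOT has no count
    semantics and is rejected."""
    rules_by_name = rules_by_name or {}
    if isinstance(expr, Ref):
        if expr.name in rules_by_name:
            return count_expression(rules_by_name[expr.name].expression, counts, rules_by_name)
        return float(counts.get(expr.name, 0))
    if isinstance(expr, And):
        return min(count_expression(op, counts, rules_by_name) for op in expr.operands)
    if isinstance(expr, Or):
        return max(count_expression(op, counts, rules_by_name) for op in expr.operands)
    if isinstance(expr, Not):
        raise SchemaError("negation has no complex-count semantics")
    raise TypeError(f"not a rule expression: {expr!r}")


def count_substrate_class(
    table: GeneCountTable,
    manifest: Iterable[HmmVariable] | Mapping[str, HmmVariable],
    complex_defs: Sequence[Rule],
    class_name: str,
) -> pd.Series:
    """Per-genome number of transporter/enzyme complexes serving a substrate class.

    Contributions are summed over (a) complex rules annotated with
    ``class_name`` (counted via :func:`count_expression`) and (b) manifest
    variables annotated with the class that no annotated complex rule already
    references (standalone enzymes count as 1-subunit complexes).
    """
    if not isinstance(manifest, Mapping):
        manifest = {v.name: v for v in manifest}
    rules_by_name = {r.name: r for r in complex_defs}
    annotated_rules = [r for r in complex_defs if r.substrate_class == class_name]
    annotated_vars = {
        name for name, v in manifest.items() if class_name in v.substrate_classes
    }
    if not annotated_rules and not annotated_vars:
        known = sorted(
            {r.substrate_class for r in complex_defs if r.substrate_class}
            | {c for v in manifest.values() for c in v.substrate_classes}
        )
        raise SchemaError(
            f"substrate class {class_name!r} has no annotated rules or variables "
            f"(known classes: {', '.join(known) or 'none'})"
        )
    from .schema import expression_refs

    covered = set()
    for r in annotated_rules:
        covered |= expression_refs(r.expression)
    standalone = sorted(annotated_vars - covered)

    out = pd.Series(0.0, index=table.counts.index, name=class_name)
    for genome_id, row in table.counts.iterrows():
        counts = row.to_dict()
        total = sum(
            count_expression(r.expression, counts, rules_by_name) for r in annotated_rules
        )
        total += sum(counts.get(v, 0) for v in standalone)
        out[genome_id] = total
    return out
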