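"""Independent oracles used by the acceptance script.

Kept separate from the package: the truth-table oracle expands rules into a
pure-variable Boolean expression string evaluated by Python itself, an
implementation path disjoint from the engine's AST walker.
"""

from __future__ import annotations

import numpy as np

from genotrait.schema import And, HmmVariable, Not, Or, Ref, Rule


def random_ruleset(rng: np.random.Generator, n_vars: int = 12, n_rules: int = 6,
                   max_depth: int = 3, allow_not: bool = True):
    """Random acyclic ruleset over at most ``n_vars`` variables."""
    var_names = [f"v{i}" for i in range(n_vars)]

    def expr(depth, rule_pool):
        leaves = var_names + rule_pool
        if depth >= max_depth or rng.random() < 0.3:
            return Ref(str(rng.choice(leaves)))
        op = rng.choice(["and", "or", "not"] if allow_not else ["and", "or"])
        if op == "not":
            return Not(expr(depth + 1, rule_pool))
        n = int(rng.integers(2, 4))
        children = tuple(expr(depth + 1, rule_pool) for _ in range(n))
        return And(children) if op == "and" else Or(children)

    rules = []
    for i in range(n_rules):
        pool = [r.name for r in rules]
        rules.append(Rule(f"r{i}", expr(0, pool)))
    manifest = [HmmVariable(n, trusted_cutoff=25.0) for n in var_names]
    return rules, manifest


def oracle_eval(ruleset, presence):
    """Truth-table substitution oracle via textual expansion + Python eval."""
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
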