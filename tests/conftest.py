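import numpy as np
import pytest

from genotrait.schema import compile_ruleset, load_packaged_schema


@pytest.fixture(scope="session")
def core_schema():
    """Packaged core schema: (manifest, rules, trait definitions)."""
    return load_packaged_schema("core")


@pytest.fixture(scope="session")
def core_ruleset(core_schema):
    manifest, rules, _ = core_schema
    return compile_ruleset(rules, manifest)


@pytest.fixture(scope="session")
def detection_fixture(tmp_path_factory, core_schema):
    """End-to-end synthetic detection fixture written to disk (built once:
    HMM training and gene calling dominate test runtime)."""
    from genotrait.synthetic import make_detection_fixture

    manifest, _, _ = core_schema
    families = ["narG", "narH", "narI", "nirK", "nosZ", "glcA", "glcB", "katE"]
    fixture = make_detection_fixture(
        families, n_genomes=5, seed=7, extra_variables=manifest
    )
    outdir = tmp_path_factory.mktemp("detection_fixture")
    fixture.write(outdir)
    return fixture, outdir


def random_ruleset(rng: np.random.Generator, n_vars: int = 12, n_rules: int = 6,
                   max_depth: int = 3, allow_not: bool = True):
    """Random acyclic ruleset over at most ``n_vars`` variables.

    Later rules may reference earlier rules, which exercises rule-to-rule
    substitution during evaluation.
    """
    from genotrait.schema import And, HmmVariable, Not, Or, Ref, Rule

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
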