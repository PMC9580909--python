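"""Trait schema: the Boolean rule language, the trait hierarchy, and the HMM manifest.

A schema has three parts:

* a **manifest** of HMM variables — one per profile HMM in the library, each
  carrying its trusted bit-score cutoff and optional cross-references and
  substrate annotations;
* a set of named **rules**, Boolean expressions over HMM variables and other
  rules (``&`` and, ``|`` or, ``!`` not, parentheses; ``!`` binds tightest,
  then ``&``, then ``|``);
* **trait definitions** binding rules (binary traits) or sets of
  rules/variables (count traits) to a three-level hierarchy path and an
  ecological strategy.

Rules may reference other rules; the reference graph must be acyclic and is
compiled into a topological evaluation order before use.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

try:  # py>=3.9 importlib.resources.files
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    _resource_files = None

__all__ = [
    "HmmVariable",
    "Ref",
    "Not",
    "And",
    "Or",
    "RuleExpression",
    "Rule",
    "TraitDefinition",
    "CompiledRuleset",
    "RuleSyntaxError",
    "SchemaError",
    "parse_rule_expression",
    "serialize_expression",
    "compile_ruleset",
    "validate_schema",
    "read_manifest",
    "write_manifest",
    "read_rules",
    "read_hierarchy",
    "load_packaged_schema",
]

STRATEGIES = (
    "resource acquisition",
    "resource use",
    "stress tolerance",
    "life history",
)


class SchemaError(ValueError):
    """Raised for unresolved references, cycles, or malformed schema files."""


class RuleSyntaxError(SchemaError):
    """Syntax error in a rule expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class HmmVariable:
    """One profile HMM treated as a Boolean variable.

    ``trusted_cutoff`` is the bit-score threshold in bits above which a hit
    is trusted; ``substrates`` are (substrate, substrate_class) annotations
    used by substrate-class count traits.
    """

    name: str
    trusted_cutoff: float | None = None
    cross_refs: frozenset[str] = frozenset()
    substrates: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.trusted_cutoff is not None:
            c = float(self.trusted_cutoff)
            if not (c > 0.0) or c != c or c in (float("inf"),):
                raise SchemaError(
                    f"HMM variable {self.name!r}: trusted_cutoff must be finite and > 0, "
                    f"got {self.trusted_cutoff!r}"
                )

    @property
    def substrate_classes(self) -> frozenset[str]:
        return frozenset(cls for _, cls in self.substrates)


# --- rule expression AST -------------------------------------------------

@dataclass(frozen=True)
class Ref:
    """Leaf: a reference to an HMM variable or another rule (resolved at compile time)."""

    name: str


@dataclass(frozen=True)
class Not:
    operand: "RuleExpression"


@dataclass(frozen=True)
class And:
    operands: tuple["RuleExpression", ...]


@dataclass(frozen=True)
class Or:
    operands: tuple["RuleExpression", ...]


RuleExpression = Union[Ref, Not, And, Or]

_IDENT = re.compile(r"[A-Za-z0-9_][A-Za-z0-9_.\-]*")
_TOKEN = re.compile(r"\s*(?:(?P<ident>[A-Za-z0-9_][A-Za-z0-9_.\-]*)|(?P<op>[&|!()]))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise RuleSyntaxError(
                f"unexpected character {stripped[0]!r}", pos + (len(text[pos:]) - len(stripped))
            )
        if m.group("ident") is not None:
            tokens.append(("ident", m.group("ident"), m.start("ident")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; precedence ``!`` > ``&`` > ``|``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> RuleExpression:
        if not self.tokens:
            raise RuleSyntaxError("empty expression", 0)
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise RuleSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> RuleExpression:
        operands = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[1] == "|":
            self.next()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def parse_and(self) -> RuleExpression:
        operands = [self.parse_unary()]
        while (tok := self.peek()) is not None and tok[1] == "&":
            self.next()
            operands.append(self.parse_unary())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def parse_unary(self) -> RuleExpression:
        tok = self.next()
        kind, value, pos = tok
        if value == "!":
            return Not(self.parse_unary())
        if value == "(":
            inner = self.parse_or()
            closing = self.next()
            if closing[1] != ")":
                raise RuleSyntaxError("expected ')'", closing[2])
            return inner
        if kind == "ident":
            return Ref(value)
        raise RuleSyntaxError(f"unexpected token {value!r}", pos)


def parse_rule_expression(text: str) -> RuleExpression:
    """Parse a rule expression string into its AST.

    ``"narG & narH | napA"`` parses as ``Or(And(narG, narH), napA)``;
    redundant parentheses collapse. Raises :class:`RuleSyntaxError` with the
    offending character position on malformed input.
    """
    if not text or not text.strip():
        raise RuleSyntaxError("empty expression", 0)
    return _Parser(text).parse()


def serialize_expression(expr: RuleExpression) -> str:
    """Render an AST back to rule-language text (minimal parentheses)."""
    if isinstance(expr, Ref):
        return expr.name
    if isinstance(expr, Not):
        inner = serialize_expression(expr.operand)
        if isinstance(expr.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"
    if isinstance(expr, And):
        parts = [
            f"({serialize_expression(op)})" if isinstance(op, Or) else serialize_expression(op)
            for op in expr.operands
        ]
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(serialize_expression(op) for op in expr.operands)
    raise TypeError(f"not a rule expression: {expr!r}")


def expression_refs(expr: RuleExpression) -> set[str]:
    """All leaf reference names in an expression."""
    if isinstance(expr, Ref):
        return {expr.name}
    if isinstance(expr, Not):
        return expression_refs(expr.operand)
    return set().union(*(expression_refs(op) for op in expr.operands))


@dataclass(frozen=True)
class Rule:
    """A named Boolean rule. ``substrate_class`` annotates transporter/enzyme
    complex rules for substrate-class counting."""

    name: str
    expression: RuleExpression
    substrate_class: str | None = None


@dataclass(frozen=True)
class TraitDefinition:
    """Binds a rule (binary) or a set of rules/variables (count) to a trait.

    ``path`` is the three-level hierarchy address (coarse → fine); the trait
    name identifies the granularity-3 column.
    """

    name: str
    path: tuple[str, str, str]
    strategy: str
    value_type: str  # "binary" | "count"
    binding: tuple[str, ...]  # one rule for binary; rules/variables for count
    substrate_class: str | None = None

    def __post_init__(self) -> None:
        if self.value_type not in ("binary", "count"):
            raise SchemaError(f"trait {self.name!r}: unknown value_type {self.value_type!r}")
        if self.strategy not in STRATEGIES:
            raise SchemaError(f"trait {self.name!r}: unknown strategy {self.strategy!r}")
        if len(self.path) != 3:
            raise SchemaError(f"trait {self.name!r}: path must have three levels")


@dataclass(frozen=True)
class CompiledRuleset:
    """Rules in topological evaluation order plus the closure of HMM variables."""

    rules: tuple[Rule, ...]
    index: Mapping[str, int]
    closure: frozenset[str]
    manifest: Mapping[str, HmmVariable]

    @property
    def rule_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rules)

    def __getitem__(self, name: str) -> Rule:
        return self.rules[self.index[name]]


def compile_ruleset(
    rules: Sequence[Rule], manifest: Iterable[HmmVariable]
) -> CompiledRuleset:
    """Resolve references, order rules topologically, and compute the HMM closure.

    Leaf names resolve to a rule when one with that name exists, otherwise to
    a manifest variable. Raises :class:`SchemaError` naming the offender on
    unresolved references or dependency cycles.
    """
    by_name: dict[str, Rule] = {}
    for r in rules:
        if r.name in by_name:
            raise SchemaError(f"duplicate rule name {r.name!r}")
        by_name[r.name] = r
    variables = {v.name: v for v in manifest}

    deps: dict[str, set[str]] = {}
    closure: set[str] = set()
    for r in by_name.values():
        rule_deps = set()
        for ref in expression_refs(r.expression):
            if ref in by_name:
                rule_deps.add(ref)
            elif ref in variables:
                closure.add(ref)
            else:
                raise SchemaError(
                    f"rule {r.name!r} references {ref!r}, which is neither a rule "
                    f"nor a manifest variable"
                )
        deps[r.name] = rule_deps

    # Kahn's algorithm, preserving input order among ready rules for determinism.
    order: list[str] = []
    remaining = {n: set(d) for n, d in deps.items()}
    input_order = list(by_name)
    while remaining:
        ready = [n for n in input_order if n in remaining and not remaining[n]]
        if not ready:
            cycle = sorted(remaining)
            raise SchemaError(f"dependency cycle among rules: {', '.join(cycle)}")
        for n in ready:
            order.append(n)
            del remaining[n]
        for d in remaining.values():
            d.difference_update(ready)

    ordered = tuple(by_name[n] for n in order)
    return CompiledRuleset(
        rules=ordered,
        index={r.name: i for i, r in enumerate(ordered)},
        closure=frozenset(closure),
        manifest=variables,
    )


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    entity: str
    message: str


def validate_schema(
    traits: Sequence[TraitDefinition], ruleset: CompiledRuleset
) -> list[ValidationIssue]:
    """Check trait bindings against a compiled ruleset; empty report iff usable."""
    issues: list[ValidationIssue] = []
    seen_paths: dict[tuple[str, str, str], str] = {}
    seen_names: set[str] = set()
    for t in traits:
        if t.name in seen_names:
            issues.append(ValidationIssue("error", t.name, "duplicate trait name"))
        seen_names.add(t.name)
        if t.path in seen_paths:
            issues.append(
                ValidationIssue(
                    "error", t.name, f"duplicate path {'>'.join(t.path)} (also {seen_paths[t.path]})"
                )
            )
        else:
            seen_paths[t.path] = t.name
        if t.value_type == "binary":
            if len(t.binding) != 1:
                issues.append(
                    ValidationIssue(
                        "error", t.name,
                        f"binary trait must bind exactly one rule, got {len(t.binding)}",
                    )
                )
            for ref in t.binding:
                if ref not in ruleset.index:
                    issues.append(
                        ValidationIssue("error", t.name, f"unresolved rule binding {ref!r}")
                    )
        else:  # count
            if not t.binding:
                issues.append(ValidationIssue("error", t.name, "count trait has empty binding"))
            for ref in t.binding:
                if ref not in ruleset.index and ref not in ruleset.manifest:
                    issues.append(
                        ValidationIssue("error", t.name, f"unresolved binding {ref!r}")
                    )
    return issues


def write_validation_report(issues: Sequence[ValidationIssue], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("severity\tentity\tmessage\n")
        for issue in issues:
            fh.write(f"{issue.severity}\t{issue.entity}\t{issue.message}\n")


# --- plain-text schema files ---------------------------------------------
#
# All three files are tab-separated with a versioned "#genotrait-<kind> v1"
# first line; further '#' lines are comments. Empty trailing columns may be
# omitted.

def _read_table(path: str | Path, kind: str) -> list[list[str]]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(f"#genotrait-{kind}"):
        raise SchemaError(f"{path}: missing '#genotrait-{kind}' header line")
    rows = []
    for ln in lines[1:]:
        if not ln.strip() or ln.startswith("#"):
            continue
        rows.append(ln.rstrip("\n").split("\t"))
    return rows


def _get(row: list[str], i: int) -> str:
    return row[i].strip() if i < len(row) else ""


def read_manifest(path: str | Path) -> list[HmmVariable]:
    """Read an HMM manifest: hmm_name, trusted_cutoff, cross_refs, substrates.

    ``cross_refs`` is comma-separated; ``substrates`` is a comma-separated
    list of ``substrate:class`` pairs. A missing/empty cutoff field means the
    model is uncalibrated.
    """
    out = []
    seen = set()
    for row in _read_table(path, "manifest"):
        name = _get(row, 0)
        if name in seen:
            raise SchemaError(f"{path}: duplicate manifest entry {name!r}")
        seen.add(name)
        cutoff_s = _get(row, 1)
        cutoff = float(cutoff_s) if cutoff_s else None
        refs = frozenset(x.strip() for x in _get(row, 2).split(",") if x.strip())
        substrates = []
        for pair in _get(row, 3).split(","):
            pair = pair.strip()
            if not pair:
                continue
            if ":" not in pair:
                raise SchemaError(f"{path}: malformed substrate annotation {pair!r} for {name!r}")
            sub, cls = pair.split(":", 1)
            substrates.append((sub.strip(), cls.strip()))
        out.append(HmmVariable(name, cutoff, refs, tuple(substrates)))
    return out


def write_manifest(variables: Iterable[HmmVariable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#genotrait-manifest\tv1\n")
        fh.write("#hmm_name\ttrusted_cutoff\tcross_refs\tsubstrates\n")
        for v in variables:
            cutoff = "" if v.trusted_cutoff is None else repr(float(v.trusted_cutoff))
            refs = ",".join(sorted(v.cross_refs))
            subs = ",".join(f"{s}:{c}" for s, c in v.substrates)
            fh.write(f"{v.name}\t{cutoff}\t{refs}\t{subs}\n")


def read_rules(path: str | Path) -> list[Rule]:
    """Read a rules file: name, expression, optional substrate_class."""
    out = []
    for row in _read_table(path, "rules"):
        name = _get(row, 0)
        expr_text = _get(row, 1)
        if not expr_text:
            raise SchemaError(f"{path}: rule {name!r} has no expression")
        cls = _get(row, 2) or None
        out.append(Rule(name, parse_rule_expression(expr_text), cls))
    return out


def read_hierarchy(path: str | Path) -> list[TraitDefinition]:
    """Read a trait-hierarchy file: name, level1..3, strategy, value_type,
    binding (comma-separated), optional substrate_class."""
    out = []
    for row in _read_table(path, "hierarchy"):
        binding = tuple(x.strip() for x in _get(row, 6).split(",") if x.strip())
        out.append(
            TraitDefinition(
                name=_get(row, 0),
                path=(_get(row, 1), _get(row, 2), _get(row, 3)),
                strategy=_get(row, 4),
                value_type=_get(row, 5),
                binding=binding,
                substrate_class=_get(row, 7) or None,
            )
        )
    return out


def load_packaged_schema(
    name: str = "core",
) -> tuple[list[HmmVariable], list[Rule], list[TraitDefinition]]:
    """Load a schema shipped with the package (manifest, rules, hierarchy).

    The ``core`` schema covers denitrification, a small substrate-uptake set,
    and a stress-tolerance set.
    """
    base = _resource_files("genotrait") / "data"
    return (
        read_manifest(str(base / f"{name}.manifest.tsv")),
        read_rules(str(base / f"{name}.rules.tsv")),
        read_hierarchy(str(base / f"{name}.hierarchy.tsv")),
    )
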