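"""Trait matrices: binary and genome-size-normalized count traits at three
hierarchy granularities.

A :class:`TraitMatrix` holds a genomes × traits DataFrame plus per-column
metadata (value_type, strategy, hierarchy path). Binary columns are 0/1;
count columns store per-base-pair genomic investments (raw complex count
divided by genome size in bp). Granularity-3 matrices roll up to coarser
levels by OR (binary) and sum (count) over children sharing a parent path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import GenomeRecord
from .engine import count_substrate_class
from .schema import CompiledRuleset, SchemaError, TraitDefinition

__all__ = [
    "TraitMatrix",
    "binary_traits",
    "count_traits",
    "build_trait_matrix",
    "rollup",
    "read_trait_matrix",
]


@dataclass
class TraitMatrix:
    """Genomes × traits with column metadata.

    ``var`` is indexed by trait name with columns ``value_type``
    ("binary" | "count"), ``strategy``, and hierarchy levels ``level1..3``
    (coarser levels carry their own path prefix only).
    """

    data: pd.DataFrame
    var: pd.DataFrame
    granularity: int = 3

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.var.index):
            raise ValueError("trait matrix columns and metadata rows differ")
        if self.data.isna().any().any():
            raise ValueError("trait matrix must not contain missing values")
        binary = self.var.index[self.var["value_type"] == "binary"]
        bad = [
            c for c in binary if not self.data[c].isin([0, 1, True, False]).all()
        ]
        if bad:
            raise ValueError(f"binary traits with non-0/1 values: {bad}")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    def columns_of_type(self, value_type: str) -> list[str]:
        return list(self.var.index[self.var["value_type"] == value_type])

    def write_tsv(self, path: str | Path) -> None:
        """TSV with three metadata header rows: strategy, value_type, then data."""
        with open(path, "w") as fh:
            fh.write("#genotrait-traitmatrix\tv1\tgranularity=%d\n" % self.granularity)
            fh.write("#strategy\t" + "\t".join(self.var["strategy"]) + "\n")
            fh.write("#value_type\t" + "\t".join(self.var["value_type"]) + "\n")
            self.data.to_csv(fh, sep="\t", index_label="genome")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TraitMatrix":
        return read_trait_matrix(path)


def read_trait_matrix(path: str | Path) -> TraitMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#genotrait-traitmatrix"):
        raise SchemaError(f"{path}: not a trait-matrix file")
    granularity = 3
    for tok in lines[0].split("\t"):
        if tok.startswith("granularity="):
            granularity = int(tok.split("=", 1)[1])
    strategies = lines[1].split("\t")[1:]
    value_types = lines[2].split("\t")[1:]
    from io import StringIO

    data = pd.read_csv(StringIO("\n".join(lines[3:])), sep="\t", index_col="genome")
    var = pd.DataFrame(
        {"value_type": value_types, "strategy": strategies}, index=data.columns
    )
    for c in var.index[var["value_type"] == "binary"]:
        data[c] = data[c].astype(int)
    return TraitMatrix(data=data, var=var, granularity=granularity)


def binary_traits(
    assertions: pd.DataFrame, traits: Sequence[TraitDefinition]
) -> pd.DataFrame:
    """Binary trait columns: each trait takes its bound rule's assertion (0/1)."""
    cols = {}
    for t in traits:
        if t.value_type != "binary":
            continue
        (rule_name,) = t.binding
        if rule_name not in assertions.columns:
            raise SchemaError(f"trait {t.name!r}: rule {rule_name!r} not in assertion matrix")
        cols[t.name] = assertions[rule_name].astype(int)
    return pd.DataFrame(cols, index=assertions.index)


def count_traits(
    class_counts: pd.DataFrame,
    genomes: Sequence[GenomeRecord] | Mapping[str, int],
    on_unknown_size: str = "error",
) -> pd.DataFrame:
    """Normalize raw complex counts by genome size (per-bp investments).

    ``class_counts``: genomes × count-trait raw counts. ``genomes`` supplies
    ``size_bp`` per genome. ``on_unknown_size``: "error" (default) or "raw"
    (keep unnormalized counts with a warning).
    """
    if not isinstance(genomes, Mapping):
        genomes = {g.genome_id: g.size_bp for g in genomes}
    out = class_counts.astype(float).copy()
    for genome_id in out.index:
        size = genomes.get(genome_id)
        if size is None or (size is not None and size <= 0):
            if on_unknown_size == "raw":
                warnings.warn(
                    f"genome {genome_id!r}: unknown size, keeping raw counts"
                )
                continue
            raise ValueError(
                f"genome {genome_id!r}: genome size unknown; per-bp normalization "
                f"impossible (policy: error)"
            )
        out.loc[genome_id] = out.loc[genome_id] / float(size)
    return out


def build_trait_matrix(
    assertions: pd.DataFrame,
    table,
    genomes: Sequence[GenomeRecord],
    traits: Sequence[TraitDefinition],
    ruleset: CompiledRuleset,
    on_unknown_size: str = "error",
) -> TraitMatrix:
    """Assemble the granularity-3 trait matrix from rule assertions and counts.

    Binary traits read their bound rule's assertion; count traits are
    substrate-class complex counts normalized per bp.
    """
    binary_defs = [t for t in traits if t.value_type == "binary"]
    count_defs = [t for t in traits if t.value_type == "count"]
    pieces = [binary_traits(assertions, binary_defs)] if binary_defs else []

    if count_defs:
        raw = {}
        for t in count_defs:
            if t.substrate_class is None:
                raise SchemaError(
                    f"count trait {t.name!r}: no substrate_class; cannot count complexes"
                )
            complex_defs = [ruleset[name] for name in t.binding if name in ruleset.index]
            raw[t.name] = count_substrate_class(
                table, ruleset.manifest, complex_defs, t.substrate_class
            )
        raw_df = pd.DataFrame(raw, index=assertions.index)
        pieces.append(count_traits(raw_df, genomes, on_unknown_size=on_unknown_size))

    data = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=assertions.index)
    order = [t.name for t in traits if t.name in data.columns]
    data = data[order]
    var = pd.DataFrame(
        {
            "value_type": [t.value_type for t in traits if t.name in data.columns],
            "strategy": [t.strategy for t in traits if t.name in data.columns],
            "level1": [t.path[0] for t in traits if t.name in data.columns],
            "level2": [t.path[1] for t in traits if t.name in data.columns],
            "level3": [t.path[2] for t in traits if t.name in data.columns],
        },
        index=order,
    )
    return TraitMatrix(data=data, var=var, granularity=3)


def rollup(matrix: TraitMatrix, to_level: int) -> TraitMatrix:
    """Aggregate a granularity-3 matrix to level 2 or 1.

    Binary parents are the OR of their children; count parents the sum.
    Children of mixed value_type under one parent path are rejected. Parent
    columns are named by their path prefix joined with " > ".
    """
    if matrix.granularity != 3:
        raise ValueError("rollup starts from a granularity-3 matrix")
    if to_level not in (1, 2):
        raise ValueError("to_level must be 1 or 2")
    level_cols = ["level1", "level2"][:to_level]
    if any(c not in matrix.var.columns for c in level_cols):
        raise SchemaError("matrix metadata lacks hierarchy paths; cannot roll up")

    groups: dict[tuple, list[str]] = {}
    for trait in matrix.var.index:
        key = tuple(matrix.var.loc[trait, c] for c in level_cols)
        if any(not k for k in key):
            raise SchemaError(f"trait {trait!r}: empty hierarchy level; orphan trait")
        groups.setdefault(key, []).append(trait)

    data_cols = {}
    var_rows = []
    for key, children in groups.items():
        vtypes = set(matrix.var.loc[children, "value_type"])
        if len(vtypes) != 1:
            raise SchemaError(
                f"parent {' > '.join(key)}: children mix value types {sorted(vtypes)}"
            )
        (vtype,) = vtypes
        name = " > ".join(key)
        block = matrix.data[children]
        if vtype == "binary":
            data_cols[name] = block.any(axis=1).astype(int)
        else:
            data_cols[name] = block.sum(axis=1)
        strategies = matrix.var.loc[children, "strategy"]
        var_rows.append(
            {
                "trait": name,
                "value_type": vtype,
                "strategy": strategies.iloc[0],
                **{c: k for c, k in zip(level_cols, key)},
            }
        )
    data = pd.DataFrame(data_cols, index=matrix.data.index)
    var = pd.DataFrame(var_rows).set_index("trait").loc[data.columns]
    return TraitMatrix(data=data, var=var, granularity=to_level)
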