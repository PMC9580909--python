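"""Pipeline orchestration: genome FASTAs → count table → assertions → trait
matrices (extract), score files → cutoff manifest (calibrate), trait matrix →
guild outputs (guilds).

Per-genome work (gene calling + HMM scan) is mapped over a thread pool; the
gene finder runs as a subprocess and the search engine releases the GIL, so
threads parallelize cleanly. Results are keyed and sorted by genome id,
making outputs byte-identical for any worker count.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .calibrate import (
    TrustedCutoff,
    UncalibratableModelError,
    read_score_set,
    select_trusted_cutoff,
    summarize_performance,
    threshold_metrics,
)
from .detect import (
    GenomeRecord,
    ProteinSet,
    count_table,
    filter_hits,
    load_hmm_library,
    predict_orfs,
    read_genome_fasta,
    read_proteome_fasta,
    scan_proteins,
    write_hits_tsv,
)
from .engine import assert_matrix
from .guilds import (
    define_guilds,
    dendrogram_to_newick,
    guild_profiles,
    hierarchical_cluster,
    trait_correlations,
    variance_curve,
    wishart_distance,
)
from .schema import (
    compile_ruleset,
    read_hierarchy,
    read_manifest,
    read_rules,
    validate_schema,
    write_validation_report,
)
from .traits import TraitMatrix, build_trait_matrix, read_trait_matrix, rollup

__all__ = ["run_extract", "run_calibrate", "run_guilds"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _process_genome(
    genome_path: Path, library, is_proteome: bool
) -> tuple[GenomeRecord, ProteinSet, list]:
    if is_proteome:
        proteins = read_proteome_fasta(genome_path)
        genome = GenomeRecord(genome_id=proteins.genome_id)
    else:
        genome = read_genome_fasta(genome_path)
        proteins = predict_orfs(genome)
    hits = scan_proteins(proteins, library, cpus=1)
    return genome, proteins, hits


def run_extract(
    genome_paths: Sequence[str | Path],
    hmm_library_path: str | Path,
    manifest_path: str | Path,
    rules_path: str | Path,
    hierarchy_path: str | Path,
    outdir: str | Path,
    proteome_input: bool = False,
    granularities: Sequence[int] = (3, 2, 1),
    threads: int = 1,
    missing_cutoff: str = "reject",
    on_unknown_size: str = "error",
) -> dict[int, TraitMatrix]:
    """Run the full extraction pipeline and write all outputs.

    Writes the count table, rule assertion matrix, per-granularity trait
    matrices, the raw hit table, a schema validation report, and a run
    manifest (versions + input hashes). Returns the trait matrices by
    granularity.
    """
    genome_paths = sorted(Path(p) for p in genome_paths)
    if not genome_paths:
        raise ValueError("no genome inputs found")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(manifest_path)
    rules = read_rules(rules_path)
    traits = read_hierarchy(hierarchy_path)
    ruleset = compile_ruleset(rules, manifest)
    issues = validate_schema(traits, ruleset)
    write_validation_report(issues, outdir / "schema_report.tsv")
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ValueError(
            f"schema validation failed with {len(errors)} errors "
            f"(see {outdir / 'schema_report.tsv'})"
        )

    library = load_hmm_library(hmm_library_path)

    results = {}
    if threads <= 1:
        for path in genome_paths:
            genome, proteins, hits = _process_genome(path, library, proteome_input)
            results[genome.genome_id] = (genome, proteins, hits)
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            futures = {
                pool.submit(_process_genome, path, library, proteome_input): path
                for path in genome_paths
            }
            for fut in futures:
                genome, proteins, hits = fut.result()
                results[genome.genome_id] = (genome, proteins, hits)

    genome_ids = sorted(results)
    genomes = [results[g][0] for g in genome_ids]
    all_hits = [h for g in genome_ids for h in results[g][2]]
    filtered = filter_hits(all_hits, manifest, missing_cutoff=missing_cutoff)
    table = count_table(filtered, genomes, hmm_names=[v.name for v in manifest])

    write_hits_tsv(all_hits, outdir / "hits.tsv")
    table.write_tsv(outdir / "gene_counts.tsv")

    assertions = assert_matrix(ruleset, table)
    assertions.astype(int).to_csv(outdir / "rule_assertions.tsv", sep="\t", index_label="genome")

    if proteome_input and any(t.value_type == "count" for t in traits):
        sizes = {g.genome_id: g.size_bp for g in genomes}
        if any(s is None for s in sizes.values()) and on_unknown_size == "error":
            raise ValueError(
                "proteome-only input has unknown genome sizes; count traits need "
                "per-bp normalization (set on_unknown_size='raw' to keep raw counts)"
            )
    tm3 = build_trait_matrix(
        assertions, table, genomes, traits, ruleset, on_unknown_size=on_unknown_size
    )
    matrices = {3: tm3}
    for level in (2, 1):
        matrices[level] = rollup(tm3, level)
    for level in sorted(set(granularities)):
        matrices[level].write_tsv(outdir / f"trait_matrix_g{level}.tsv")

    run_manifest = {
        "tool": "genotrait",
        "version": __version__,
        "n_genomes": len(genomes),
        "inputs": {
            "hmm_library": _sha256(Path(hmm_library_path)),
            "manifest": _sha256(Path(manifest_path)),
            "rules": _sha256(Path(rules_path)),
            "hierarchy": _sha256(Path(hierarchy_path)),
        },
        "policies": {
            "missing_cutoff": missing_cutoff,
            "on_unknown_size": on_unknown_size,
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True) + "\n")
    return matrices


def run_calibrate(
    score_paths: Sequence[str | Path], outdir: str | Path
) -> pd.DataFrame:
    """Select a trusted cutoff per score file; write manifest + performance table.

    Uncalibratable models are listed in ``uncalibratable.tsv`` instead of
    the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not score_paths:
        raise ValueError("no score files given")
    cutoffs: list[TrustedCutoff] = []
    failures: list[tuple[str, str]] = []
    for path in sorted(Path(p) for p in score_paths):
        if not path.exists():
            raise FileNotFoundError(f"score file not found: {path}")
        scores = read_score_set(path)
        try:
            cutoffs.append(select_trusted_cutoff(threshold_metrics(scores)))
        except UncalibratableModelError as exc:
            failures.append((scores.model, str(exc)))
    table, aggregates = summarize_performance(cutoffs)
    table.to_csv(outdir / "performance.tsv", sep="\t", index=False)
    with open(outdir / "cutoff_manifest.tsv", "w") as fh:
        fh.write("#genotrait-manifest\tv1\n")
        fh.write("#hmm_name\ttrusted_cutoff\tcross_refs\tsubstrates\n")
        for c in cutoffs:
            fh.write(f"{c.model}\t{c.cutoff!r}\t\t\n")
    with open(outdir / "uncalibratable.tsv", "w") as fh:
        fh.write("model\treason\n")
        for model, reason in failures:
            fh.write(f"{model}\t{reason}\n")
    (outdir / "aggregates.json").write_text(json.dumps(aggregates, indent=2, sort_keys=True) + "\n")
    return table


def run_guilds(
    matrix_path: str | Path,
    outdir: str | Path,
    k: int | None = None,
    variance_target: float | None = None,
    min_guild_size: int = 1,
    life_history_path: str | Path | None = None,
    write_distance: bool = True,
    plot: bool = False,
) -> None:
    """Distance → tree → variance curve → guild assignment → profiles, on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = read_trait_matrix(matrix_path)
    if matrix.data.shape[0] < 2:
        raise ValueError("guild inference needs at least 2 genomes")

    d = wishart_distance(matrix)
    linkage = hierarchical_cluster(d)
    curve = variance_curve(d, linkage)
    if k is None and variance_target is None:
        variance_target = 0.7
    assignment = define_guilds(
        d, linkage, curve=curve, k=k, variance_target=variance_target,
        min_size=min_guild_size,
    )
    life_history = None
    if life_history_path is not None:
        life_history = pd.read_csv(life_history_path, sep="\t", index_col=0)
    profile = guild_profiles(assignment, matrix, life_history=life_history)
    correlations = trait_correlations(matrix) if matrix.data.shape[0] >= 3 else None

    if write_distance:
        d.write_tsv(outdir / "distance.tsv")
    (outdir / "dendrogram.nwk").write_text(dendrogram_to_newick(linkage, d.ids) + "\n")
    curve.to_csv(outdir / "variance_curve.tsv", sep="\t", index=False)
    out_assign = assignment.labels.to_frame()
    out_assign["flagged_small_guild"] = out_assign["guild"].isin(assignment.flagged_small)
    out_assign.to_csv(outdir / "guild_assignments.tsv", sep="\t", index_label="genome")
    profile.means.to_csv(outdir / "guild_profiles.tsv", sep="\t")
    pd.DataFrame({"pvalue": profile.pvalues, "qvalue": profile.qvalues}).to_csv(
        outdir / "trait_tests.tsv", sep="\t", index_label="trait"
    )
    if profile.life_history is not None:
        profile.life_history.to_csv(outdir / "guild_life_history.tsv", sep="\t")
    if correlations is not None:
        correlations.to_csv(outdir / "trait_correlations.tsv", sep="\t", index_label="trait")

    if plot:  # pragma: no cover - optional plotting
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            ax.plot(curve["k"], curve["r2"], marker="o", ms=3)
            ax.set_xlabel("number of guilds k")
            ax.set_ylabel("variance explained $R^2$")
            ax.axhline(variance_target or 0, ls="--", lw=0.8, color="grey")
            fig.tight_layout()
            fig.savefig(outdir / "variance_curve.png", dpi=150)
            plt.close(fig)
        except ImportError:
            warnings.warn("matplotlib not available; skipping plots")
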