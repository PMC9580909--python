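"""Life-history traits: minimum doubling time and optimal growth temperature
from genome-derived features via pluggable linear models.

Growth rate leaves a compositional signature: fast growers show strong codon
usage bias in highly expressed genes (ribosomal proteins) relative to the
genome-wide background. The bias statistic used here is the Karlin–Mrázek
codon usage bias B — the amino-acid-frequency-weighted L1 distance between
the synonymous-codon frequency distributions of a gene set and a background
set. B = 0 when the two usages coincide and grows with skew.

Optimal growth temperature correlates with nucleotide and proteome
composition; a documented feature vector (genome/ORF nucleotide fractions,
proteome amino-acid fractions, the IVYWREL fraction) feeds a multiple
linear regression whose coefficients ship as versioned plain-text model
files. The packaged model files are synthetic placeholders (marked in their
filenames and headers) so the pipeline runs end-to-end; real coefficient
sets drop in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detect import GenomeRecord, ProteinSet
from .schema import HmmVariable

try:
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    _resource_files = None

__all__ = [
    "CodonUsageFeatures",
    "LinearModelSpec",
    "codon_usage_bias",
    "codon_usage_bias_statistic",
    "extract_ogt_features",
    "predict_from_linear_model",
    "read_model_file",
    "load_packaged_model",
    "ribosomal_variable_names",
]

_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_STOPS = {"TAA", "TAG", "TGA"}
_AAS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CodonUsageFeatures:
    """Codon-usage-bias statistic of a highly-expressed gene set vs background."""

    bias: float
    n_highly_expressed: int
    low_confidence: bool


@dataclass(frozen=True)
class LinearModelSpec:
    """Named linear model: response = transform⁻¹(intercept + Σ wᵢ·fᵢ).

    ``transform`` is "identity" or "log" (log-linear model: the linear
    predictor is the natural log of the response). ``units`` documents the
    response scale (e.g. hours, degC).
    """

    name: str
    coefficients: Mapping[str, float]
    intercept: float
    transform: str = "identity"
    units: str = ""

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ValueError(f"model {self.name!r}: unknown transform {self.transform!r}")


def _codon_counts(genes: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    any_codon = False
    for gene in genes:
        gene = gene.upper().replace("U", "T")
        trimmed = gene[: len(gene) - len(gene) % 3]
        for i in range(0, len(trimmed), 3):
            codon = trimmed[i : i + 3]
            if codon in _STANDARD_TABLE:
                counts[codon] = counts.get(codon, 0) + 1
                any_codon = True
    if not any_codon:
        raise ValueError("no translatable codons in gene set")
    return counts


def codon_usage_bias_statistic(
    highly_expressed: Sequence[str], background: Sequence[str]
) -> float:
    """Karlin–Mrázek codon usage bias B of one gene set against another.

    B(H|B) = Σ_a p_a(H) · Σ_{c∈syn(a)} |f_c(H) − f_c(B)| where p_a is the
    amino-acid frequency in the highly expressed set and f_c the synonymous
    codon frequencies within amino acid a. Identical usage gives B = 0; the
    maximum over fully disjoint synonymous choices is 2.
    """
    if not highly_expressed or not background:
        raise ValueError("both gene sets must be non-empty")
    hi = _codon_counts(highly_expressed)
    bg = _codon_counts(background)

    by_aa: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.items():
        by_aa.setdefault(aa, []).append(codon)

    total_hi = sum(hi.values())
    b = 0.0
    for aa, codons in by_aa.items():
        n_hi = sum(hi.get(c, 0) for c in codons)
        n_bg = sum(bg.get(c, 0) for c in codons)
        if n_hi == 0 or n_bg == 0:
            continue
        p_aa = n_hi / total_hi
        l1 = sum(abs(hi.get(c, 0) / n_hi - bg.get(c, 0) / n_bg) for c in codons)
        b += p_aa * l1
    return b


def codon_usage_bias(
    highly_expressed: Sequence[str],
    background: Sequence[str],
    min_genes: int = 10,
) -> CodonUsageFeatures:
    """Bias of ribosomal-protein (highly expressed) genes vs genome background.

    Fewer than ``min_genes`` highly expressed genes flags the estimate as
    low-confidence rather than failing, matching the tolerance needed for
    incomplete genomes.
    """
    if not highly_expressed:
        raise ValueError("no highly expressed (ribosomal) genes found")
    if not background:
        raise ValueError("empty background gene set")
    bias = codon_usage_bias_statistic(highly_expressed, background)
    return CodonUsageFeatures(
        bias=bias,
        n_highly_expressed=len(highly_expressed),
        low_confidence=len(highly_expressed) < min_genes,
    )


def ribosomal_variable_names(manifest: Iterable[HmmVariable]) -> set[str]:
    """Manifest variables tagged as ribosomal proteins (cross-ref ``RIBO``)."""
    return {v.name for v in manifest if "RIBO" in v.cross_refs}


def extract_ogt_features(
    genome: GenomeRecord | None, proteins: ProteinSet
) -> dict[str, float]:
    """Compositional feature vector for growth-temperature regression.

    Genome-level features (``nt_*``, ``genome_gc``) require the nucleotide
    sequence and are omitted for proteome-only input; models must then
    restrict themselves to protein-derived features. Protein features are
    the 20 amino-acid fractions (``aa_*``), the thermophily-associated
    IVYWREL fraction, and mean protein length.
    """
    if len(proteins) == 0:
        raise ValueError("empty protein set")
    features: dict[str, float] = {}
    if genome is not None and genome.sequence:
        seq = genome.sequence.upper()
        n = sum(seq.count(b) for b in "ACGT")
        if n == 0:
            raise ValueError(f"genome {genome.genome_id!r}: no unambiguous nucleotides")
        for b in "ACGT":
            features[f"nt_{b.lower()}"] = seq.count(b) / n
        features["genome_gc"] = features["nt_g"] + features["nt_c"]

    aa_counts = {a: 0 for a in _AAS}
    total = 0
    lengths = []
    for _, pseq in proteins.proteins:
        pseq = pseq.upper().rstrip("*")
        lengths.append(len(pseq))
        for a in pseq:
            if a in aa_counts:
                aa_counts[a] += 1
                total += 1
    if total == 0:
        raise ValueError("proteins contain no standard amino acids")
    for a in _AAS:
        features[f"aa_{a.lower()}"] = aa_counts[a] / total
    features["ivywrel"] = sum(aa_counts[a] for a in "IVYWREL") / total
    features["mean_protein_length"] = float(np.mean(lengths))
    features["n_proteins"] = float(len(proteins))
    return features


def predict_from_linear_model(
    features: Mapping[str, float], model: LinearModelSpec
) -> float:
    """Apply a linear model to a feature vector.

    Raises ``KeyError`` naming the first missing feature. For the "log"
    transform the returned value is exp(linear predictor).
    """
    total = float(model.intercept)
    for name, weight in model.coefficients.items():
        if name not in features:
            raise KeyError(
                f"model {model.name!r}: feature {name!r} missing from input"
            )
        total += float(weight) * float(features[name])
    if model.transform == "log":
        return math.exp(total)
    return total


def read_model_file(path: str | Path) -> LinearModelSpec:
    """Read a plain-text linear model: '# key: value' metadata then
    'feature<tab>weight' rows; the 'intercept' row is the constant term."""
    meta: dict[str, str] = {}
    coefficients: dict[str, float] = {}
    intercept = 0.0
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        name, value = ln.split("\t")
        if name == "intercept":
            intercept = float(value)
        else:
            coefficients[name] = float(value)
    return LinearModelSpec(
        name=meta.get("name", Path(path).stem),
        coefficients=coefficients,
        intercept=intercept,
        transform=meta.get("transform", "identity"),
        units=meta.get("units", ""),
    )


def load_packaged_model(name: str) -> LinearModelSpec:
    """Load a model file shipped with the package (``data/models/``).

    Available: ``doubling_time_synthetic`` (hours, log-linear in codon bias)
    and ``ogt_synthetic`` (degC, linear in composition). Both are synthetic
    placeholder coefficient sets, not fitted to any growth dataset.
    """
    base = _resource_files("genotrait") / "data" / "models"
    return read_model_file(str(base / f"{name}.tsv"))
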