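"""Profile-HMM calibration: build models from seed alignments and pick
trusted bit-score cutoffs by F-score maximization over labeled score sets.

For each model the benchmark is a set of positive (true member) and negative
(non-member) bitscores. Precision, recall, F and false-positive rate are
computed at every observed score, and the trusted cutoff is the smallest
score attaining the maximum F — so a score equal to the cutoff passes.
Negatives that the search engine never reported (below its reporting floor)
are accounted for through ``n_negatives_total``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyhmmer

from .schema import HmmVariable

__all__ = [
    "LabeledScoreSet",
    "ThresholdCurve",
    "TrustedCutoff",
    "build_hmm_from_seed_alignment",
    "threshold_metrics",
    "select_trusted_cutoff",
    "summarize_performance",
    "read_score_set",
    "write_cutoff_table",
]


@dataclass(frozen=True)
class LabeledScoreSet:
    """Labeled benchmark bitscores for one model.

    ``n_negatives_total`` counts every negative scanned, scored or not;
    unscored negatives sit below all candidate thresholds.
    """

    model: str
    positive_scores: tuple[float, ...]
    negative_scores: tuple[float, ...] = ()
    n_negatives_total: int | None = None

    def __post_init__(self) -> None:
        if not self.positive_scores:
            raise ValueError(f"model {self.model!r}: at least one positive score required")
        total = self.n_negatives_total
        if total is None:
            object.__setattr__(self, "n_negatives_total", len(self.negative_scores))
        elif total < len(self.negative_scores):
            raise ValueError(
                f"model {self.model!r}: n_negatives_total ({total}) < number of "
                f"scored negatives ({len(self.negative_scores)})"
            )


@dataclass(frozen=True)
class ThresholdCurve:
    """Per-candidate-threshold precision/recall/F/FPR for one model.

    Candidate thresholds are the observed score values; F is piecewise
    constant between them. ``precision`` is NaN where no sequence scores at
    or above the threshold (TP+FP = 0); such thresholds are excluded from
    cutoff selection.
    """

    model: str
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray
    fpr: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "precision": self.precision,
                "recall": self.recall,
                "f_score": self.f_score,
                "fpr": self.fpr,
            }
        )


@dataclass(frozen=True)
class TrustedCutoff:
    model: str
    cutoff: float
    f_score: float
    sensitivity: float
    fpr: float


class UncalibratableModelError(ValueError):
    """No threshold yields a defined, positive F-score."""


def build_hmm_from_seed_alignment(
    sequences: Sequence[tuple[str, str]], name: str
) -> pyhmmer.plan7.HMM:
    """Build a profile HMM from an aligned set of (id, aligned-seq) pairs.

    Delegates training to the HMMER builder; the returned profile is directly
    usable by :func:`genotrait.detect.scan_proteins` and writable to a
    HMMER3 ASCII library with ``hmm.write()``.
    """
    if len(sequences) < 2:
        raise ValueError("a seed alignment needs at least 2 sequences")
    lengths = {len(s) for _, s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=name.encode(),
        sequences=[
            pyhmmer.easel.TextSequence(name=sid.encode(), sequence=seq)
            for sid, seq in sequences
        ],
    )
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
    return hmm


def build_hmm_from_msa_file(path: str | Path) -> pyhmmer.plan7.HMM:
    """Build a profile from an aligned FASTA file; model name = file stem."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return build_hmm_from_seed_alignment(records, Path(path).stem)


def threshold_metrics(scores: LabeledScoreSet) -> ThresholdCurve:
    """Precision/recall/F/FPR at every observed score value.

    At threshold t: TP = #positives >= t, FP = #scored negatives >= t,
    FN = #positives < t, TN = n_negatives_total - FP. Precision is NaN when
    TP+FP = 0; F = 0 when TP = 0 (and some FP present); FPR uses
    n_negatives_total as denominator.
    """
    pos = np.asarray(scores.positive_scores, dtype=float)
    neg = np.asarray(scores.negative_scores, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))

    # counts >= t via searchsorted on sorted arrays
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tp = len(pos) - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = len(neg) - np.searchsorted(neg_sorted, thresholds, side="left")

    denom_p = tp + fp
    fn = len(pos) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(denom_p > 0, tp / np.maximum(denom_p, 1), np.nan)
        recall = tp / len(pos)
        # 2TP/(2TP+FP+FN) == 2PR/(P+R); the single-division form makes
        # mathematically tied F values bit-identical across thresholds
        f = np.where(denom_p > 0, 2 * tp / (2 * tp + fp + fn), np.nan)
    n_neg_total = scores.n_negatives_total or 0
    fpr = fp / n_neg_total if n_neg_total > 0 else np.zeros_like(fp, dtype=float)
    return ThresholdCurve(
        model=scores.model,
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        f_score=f,
        fpr=np.asarray(fpr, dtype=float),
    )


def select_trusted_cutoff(curve: ThresholdCurve) -> TrustedCutoff:
    """The smallest threshold attaining the maximum F-score.

    Thresholds with undefined precision (nothing scores above them) are
    excluded. Raises :class:`UncalibratableModelError` if no threshold has a
    defined, positive F.
    """
    if curve.thresholds.size == 0:
        raise UncalibratableModelError(f"model {curve.model!r}: empty threshold curve")
    defined = ~np.isnan(curve.f_score)
    if not defined.any() or np.nanmax(curve.f_score) <= 0.0:
        raise UncalibratableModelError(
            f"model {curve.model!r}: no threshold achieves a positive F-score"
        )
    fmax = np.nanmax(curve.f_score)
    candidates = np.flatnonzero(defined & (curve.f_score == fmax))
    i = candidates[np.argmin(curve.thresholds[candidates])]
    return TrustedCutoff(
        model=curve.model,
        cutoff=float(curve.thresholds[i]),
        f_score=float(curve.f_score[i]),
        sensitivity=float(curve.recall[i]),
        fpr=float(curve.fpr[i]),
    )


def summarize_performance(
    cutoffs: Iterable[TrustedCutoff],
    sensitivity_threshold: float = 0.75,
    f_threshold: float = 0.8,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-model performance table plus aggregate fractions.

    Aggregates report the fraction of models with sensitivity at or above
    ``sensitivity_threshold`` and with F at or above ``f_threshold``.
    """
    rows = [
        {
            "hmm_name": c.model,
            "trusted_cutoff": c.cutoff,
            "f_score": c.f_score,
            "sensitivity": c.sensitivity,
            "fpr": c.fpr,
        }
        for c in cutoffs
    ]
    table = pd.DataFrame(rows, columns=["hmm_name", "trusted_cutoff", "f_score", "sensitivity", "fpr"])
    if len(table):
        aggregates = {
            "n_models": float(len(table)),
            f"frac_sensitivity_ge_{sensitivity_threshold}": float(
                (table["sensitivity"] >= sensitivity_threshold).mean()
            ),
            f"frac_f_ge_{f_threshold}": float((table["f_score"] >= f_threshold).mean()),
        }
    else:
        aggregates = {"n_models": 0.0}
    return table, aggregates


def read_score_set(path: str | Path, model: str | None = None) -> LabeledScoreSet:
    """Read a labeled score file: sequence_id <tab> label(pos|neg) <tab> bitscore.

    A negative row with an empty bitscore field counts toward
    ``n_negatives_total`` without contributing a scored negative.
    """
    if model is None:
        model = Path(path).stem
    pos: list[float] = []
    neg: list[float] = []
    n_neg_total = 0
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed line {ln!r}")
        label = parts[1].strip().lower()
        score_s = parts[2].strip() if len(parts) > 2 else ""
        if label == "pos":
            pos.append(float(score_s))
        elif label == "neg":
            n_neg_total += 1
            if score_s:
                neg.append(float(score_s))
        else:
            raise ValueError(f"{path}: unknown label {parts[1]!r}")
    return LabeledScoreSet(
        model=model,
        positive_scores=tuple(pos),
        negative_scores=tuple(neg),
        n_negatives_total=n_neg_total,
    )


def write_cutoff_table(cutoffs: Iterable[TrustedCutoff], path: str | Path) -> None:
    """Manifest-compatible cutoff table (extra performance columns are comments)."""
    with open(path, "w") as fh:
        fh.write("#genotrait-manifest\tv1\n")
        fh.write("#hmm_name\ttrusted_cutoff\tcross_refs\tsubstrates\n")
        for c in cutoffs:
            fh.write(f"{c.model}\t{c.cutoff!r}\t\t\n")


def cutoffs_to_manifest(cutoffs: Iterable[TrustedCutoff]) -> list[HmmVariable]:
    return [HmmVariable(name=c.model, trusted_cutoff=c.cutoff) for c in cutoffs]
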