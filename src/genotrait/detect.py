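"""Gene detection: genome → proteins → profile-HMM hits → gene-family count table.

ORF prediction is delegated to the Prodigal executable (anonymous/meta mode,
suitable for short and provisional genomes alike) and homology search to
HMMER via pyhmmer. Hits are filtered at each model's trusted bit-score
cutoff (full-sequence score, ``>=`` comparison) and collapsed to one best
hit per (protein, model) pair before counting distinct proteins per model.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyhmmer
from Bio import SeqIO

from .schema import HmmVariable, SchemaError

__all__ = [
    "GenomeRecord",
    "ProteinSet",
    "HmmHit",
    "GeneCountTable",
    "predict_orfs",
    "scan_proteins",
    "load_hmm_library",
    "filter_hits",
    "count_table",
    "read_genome_fasta",
    "read_proteome_fasta",
]

_NT = set("ACGTNacgtn")


@dataclass(frozen=True)
class GenomeRecord:
    """A genome: id, optional nucleotide sequence, and size in bp.

    ``size_bp`` backs per-base-pair normalization of count traits; it equals
    the sequence length when the sequence is present.
    """

    genome_id: str
    sequence: str | None = None
    size_bp: int | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if self.size_bp is None:
                object.__setattr__(self, "size_bp", len(self.sequence))
            elif self.size_bp != len(self.sequence):
                raise ValueError(
                    f"genome {self.genome_id!r}: size_bp {self.size_bp} != "
                    f"sequence length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class ProteinSet:
    genome_id: str
    proteins: tuple[tuple[str, str], ...]  # (protein_id, amino-acid sequence)

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.proteins]
        if len(ids) != len(set(ids)):
            raise ValueError(f"genome {self.genome_id!r}: duplicate protein ids")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class HmmHit:
    genome_id: str
    protein_id: str
    hmm_name: str
    bitscore: float
    evalue: float


@dataclass
class GeneCountTable:
    """Genomes × HMM-variables integer count matrix with a derived presence view."""

    counts: pd.DataFrame  # rows: genome ids, columns: hmm names, dtype int

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="genome")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneCountTable":
        return cls(pd.read_csv(path, sep="\t", index_col="genome"))


def read_genome_fasta(path: str | Path) -> GenomeRecord:
    """One genome per file; multi-record files are concatenated as contigs."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    genome_id = Path(path).name
    for suffix in (".fa", ".fna", ".fasta"):
        if genome_id.endswith(suffix):
            genome_id = genome_id[: -len(suffix)]
            break
    seq = "".join(str(r.seq) for r in records)
    return GenomeRecord(genome_id=genome_id, sequence=seq)


def read_proteome_fasta(path: str | Path, genome_id: str | None = None) -> ProteinSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    if genome_id is None:
        genome_id = Path(path).name
        for suffix in (".faa", ".fasta"):
            if genome_id.endswith(suffix):
                genome_id = genome_id[: -len(suffix)]
                break
    proteins = tuple((r.id, str(r.seq).rstrip("*")) for r in records)
    return ProteinSet(genome_id=genome_id, proteins=proteins)


def predict_orfs(
    genome: GenomeRecord, prodigal_bin: str = "prodigal", procedure: str = "meta"
) -> ProteinSet:
    """Predict protein-coding ORFs with Prodigal.

    Protein ids are rewritten to the stable form ``<genome_id>|<n>`` in order
    of appearance so repeated runs give identical ids.
    """
    if genome.sequence is None or not genome.sequence:
        raise ValueError(f"genome {genome.genome_id!r}: empty or missing nucleotide sequence")
    if not set(genome.sequence) <= _NT:
        bad = sorted(set(genome.sequence) - _NT)
        raise ValueError(
            f"genome {genome.genome_id!r}: non-nucleotide characters {bad[:5]!r}"
        )
    if shutil.which(prodigal_bin) is None:
        raise RuntimeError(f"gene finder executable {prodigal_bin!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "genome.fa"
        faa = Path(tmp) / "proteins.faa"
        fa.write_text(f">{genome.genome_id}\n{genome.sequence}\n")
        subprocess.run(
            [prodigal_bin, "-i", str(fa), "-a", str(faa), "-p", procedure,
             "-q", "-o", str(Path(tmp) / "genes.out")],
            check=True,
            capture_output=True,
        )
        proteins = tuple(
            (f"{genome.genome_id}|{i + 1}", str(rec.seq).rstrip("*"))
            for i, rec in enumerate(SeqIO.parse(str(faa), "fasta"))
        )
    return ProteinSet(genome_id=genome.genome_id, proteins=proteins)


def load_hmm_library(path: str | Path) -> list[pyhmmer.plan7.HMM]:
    """Load all profiles from a HMMER3 ASCII library file."""
    with pyhmmer.plan7.HMMFile(str(path)) as fh:
        hmms = list(fh)
    if not hmms:
        raise ValueError(f"{path}: empty HMM library")
    return hmms


def scan_proteins(
    proteins: ProteinSet,
    library: Sequence[pyhmmer.plan7.HMM] | str | Path,
    cpus: int = 1,
) -> list[HmmHit]:
    """Scan a protein set against a profile-HMM library with hmmsearch.

    Returns every reported hit (engine reporting thresholds) with its
    full-sequence bitscore and e-value; trusted-cutoff filtering is a
    separate step (:func:`filter_hits`).
    """
    if isinstance(library, (str, Path)):
        library = load_hmm_library(library)
    if not library:
        raise ValueError("empty HMM library")
    if len(proteins) == 0:
        raise ValueError(f"genome {proteins.genome_id!r}: empty protein set")
    def _text(name) -> str:
        return name.decode() if isinstance(name, bytes) else str(name)

    alphabet = pyhmmer.easel.Alphabet.amino()
    targets = [
        pyhmmer.easel.TextSequence(name=pid.encode(), sequence=seq).digitize(alphabet)
        for pid, seq in proteins.proteins
    ]
    hits: list[HmmHit] = []
    for top_hits in pyhmmer.hmmsearch(library, targets, cpus=cpus):
        hmm_name = _text(top_hits.query.name)
        for hit in top_hits:
            if not hit.included:
                continue
            hits.append(
                HmmHit(
                    genome_id=proteins.genome_id,
                    protein_id=_text(hit.name),
                    hmm_name=hmm_name,
                    bitscore=float(hit.score),
                    evalue=float(hit.evalue),
                )
            )
    hits.sort(key=lambda h: (h.genome_id, h.hmm_name, h.protein_id))
    return hits


def filter_hits(
    hits: Iterable[HmmHit],
    manifest: Iterable[HmmVariable] | Mapping[str, HmmVariable],
    missing_cutoff: str = "reject",
) -> list[HmmHit]:
    """Keep hits at or above their model's trusted cutoff; best hit per
    (genome, protein, model).

    ``missing_cutoff``: "reject" raises on a model without a cutoff;
    "pass" keeps such hits unfiltered with a warning.
    """
    if not isinstance(manifest, Mapping):
        manifest = {v.name: v for v in manifest}
    best: dict[tuple[str, str, str], HmmHit] = {}
    warned: set[str] = set()
    for hit in hits:
        if hit.hmm_name not in manifest:
            raise SchemaError(f"hit to unknown model {hit.hmm_name!r}")
        cutoff = manifest[hit.hmm_name].trusted_cutoff
        if cutoff is None:
            if missing_cutoff == "reject":
                raise SchemaError(
                    f"model {hit.hmm_name!r} has no trusted cutoff "
                    f"(missing_cutoff policy: reject)"
                )
            if hit.hmm_name not in warned:
                warnings.warn(f"model {hit.hmm_name!r} has no trusted cutoff; passing all hits")
                warned.add(hit.hmm_name)
        elif hit.bitscore < cutoff:
            continue
        key = (hit.genome_id, hit.protein_id, hit.hmm_name)
        if key not in best or hit.bitscore > best[key].bitscore:
            best[key] = hit
    return sorted(best.values(), key=lambda h: (h.genome_id, h.hmm_name, h.protein_id))


def count_table(
    filtered: Iterable[HmmHit],
    genomes: Sequence[GenomeRecord | str],
    hmm_names: Sequence[str] | None = None,
) -> GeneCountTable:
    """Count distinct proteins per (genome, model) among filtered hits.

    Genomes without hits get all-zero rows; a protein hitting several models
    contributes one to each.
    """
    genome_ids = [g.genome_id if isinstance(g, GenomeRecord) else g for g in genomes]
    filtered = list(filtered)
    if hmm_names is None:
        hmm_names = sorted({h.hmm_name for h in filtered})
    counts = pd.DataFrame(0, index=list(genome_ids), columns=list(hmm_names), dtype=int)
    seen: set[tuple[str, str, str]] = set()
    for hit in filtered:
        key = (hit.genome_id, hit.protein_id, hit.hmm_name)
        if key in seen:
            continue
        seen.add(key)
        if hit.genome_id in counts.index and hit.hmm_name in counts.columns:
            counts.loc[hit.genome_id, hit.hmm_name] += 1
    return GeneCountTable(counts)


def write_hits_tsv(hits: Iterable[HmmHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tprotein\thmm_name\tbitscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.protein_id}\t{h.hmm_name}\t{h.bitscore:.2f}\t{h.evalue:.3g}\n")
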