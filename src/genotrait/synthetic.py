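"""Synthetic inputs for every pipeline stage: labeled score sets, planted-guild
trait matrices, toy genomes with planted ORFs, and end-to-end detection
fixtures (protein families, seed alignments, HMM libraries, genomes).

All generators draw from numpy's PCG64 generator; per-purpose sub-seeds are
derived by mixing the user seed with a CRC32 of a purpose string, so stages
are decoupled (changing one fixture does not shift another's stream) while
a single seed still determines everything.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import LabeledScoreSet
from .detect import GenomeRecord, ProteinSet
from .traits import TraitMatrix

__all__ = [
    "subseed_rng",
    "make_score_set",
    "make_planted_guild_matrix",
    "make_toy_genome",
    "make_protein_family",
    "random_protein",
]

_AAS = "ARNDCQEGHILKMFPSTWYV"

# Codon choices for back-translation (standard table, no stops).
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "N": ("AAT", "AAC"), "D": ("GAT", "GAC"), "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"), "E": ("GAA", "GAG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC", "ATA"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "K": ("AAA", "AAG"), "M": ("ATG",), "F": ("TTT", "TTC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "W": ("TGG",),
    "Y": ("TAT", "TAC"), "V": ("GTT", "GTC", "GTA", "GTG"),
}


def subseed_rng(seed: int, purpose: str) -> np.random.Generator:
    """PCG64 generator sub-seeded from (seed, CRC32(purpose))."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(purpose.encode())])


def make_score_set(
    model: str = "toy",
    n_pos: int = 50,
    n_neg: int = 200,
    mu_pos: float = 60.0,
    mu_neg: float = 20.0,
    sigma: float = 4.0,
    n_unscored_neg: int = 0,
    seed: int = 0,
    allow_overlap: bool = False,
) -> LabeledScoreSet:
    """Gaussian positive/negative bitscore sets for calibration tests.

    Defaults give a 10σ separation (μ_pos − μ_neg = 40, σ = 4), for which
    cutoff selection should reach F = 1. Overlapping distributions must be
    requested explicitly with ``allow_overlap``.
    """
    if mu_pos <= mu_neg and not allow_overlap:
        raise ValueError("mu_pos must exceed mu_neg unless allow_overlap is set")
    rng = subseed_rng(seed, f"score-set:{model}")
    pos = rng.normal(mu_pos, sigma, size=n_pos)
    neg = rng.normal(mu_neg, sigma, size=n_neg)
    return LabeledScoreSet(
        model=model,
        positive_scores=tuple(np.round(pos, 4)),
        negative_scores=tuple(np.round(neg, 4)),
        n_negatives_total=n_neg + n_unscored_neg,
    )


def make_planted_guild_matrix(
    n_genomes: int = 60,
    n_binary: int = 30,
    n_count: int = 6,
    n_guilds: int = 3,
    divergence: float = 0.8,
    noise: float = 0.05,
    count_rates: tuple[float, float] = (3.0, 30.0),
    size_range_bp: tuple[int, int] = (2_000_000, 6_000_000),
    seed: int = 0,
) -> tuple[TraitMatrix, np.ndarray]:
    """Trait matrix with planted guild structure plus the true labels.

    Each binary trait is characteristic of one guild (cycling one-hot over
    guilds): genomes of that guild carry it with probability
    ``noise + divergence`` and others with probability ``noise``, so the
    per-trait Bernoulli separation is ``divergence`` and any two guilds
    differ in expectation on ~2/3 of traits (for 3 guilds). Count traits are
    Poisson with a per-guild rate from ``count_rates`` (high for the guild
    whose index matches the trait modulo the guild count), normalized by a
    genome size drawn uniformly from ``size_range_bp``.
    """
    if not 0 <= noise <= 1 or not 0 < divergence <= 1 or noise + divergence > 1:
        raise ValueError("need 0 <= noise, 0 < divergence, noise + divergence <= 1")
    rng = subseed_rng(seed, "planted-guilds")
    labels = np.repeat(np.arange(n_guilds), int(np.ceil(n_genomes / n_guilds)))[:n_genomes]
    rng.shuffle(labels)

    p_on, p_off = noise + divergence, noise
    binary = np.empty((n_genomes, n_binary), dtype=int)
    for j in range(n_binary):
        owner = j % n_guilds
        probs = np.where(labels == owner, p_on, p_off)
        binary[:, j] = rng.random(n_genomes) < probs

    sizes = rng.integers(size_range_bp[0], size_range_bp[1] + 1, size=n_genomes)
    low, high = count_rates
    counts = np.empty((n_genomes, n_count), dtype=float)
    for j in range(n_count):
        owner = j % n_guilds
        lam = np.where(labels == owner, high, low)
        counts[:, j] = rng.poisson(lam) / sizes

    ids = [f"genome_{i + 1:03d}" for i in range(n_genomes)]
    data = pd.DataFrame(
        np.hstack([binary, counts]),
        index=ids,
        columns=[f"btrait_{j + 1:02d}" for j in range(n_binary)]
        + [f"ctrait_{j + 1:02d}" for j in range(n_count)],
    )
    for j in range(n_binary):
        data[f"btrait_{j + 1:02d}"] = data[f"btrait_{j + 1:02d}"].astype(int)
    var = pd.DataFrame(
        {
            "value_type": ["binary"] * n_binary + ["count"] * n_count,
            "strategy": ["resource use"] * n_binary + ["resource acquisition"] * n_count,
            "level1": ["Planted"] * (n_binary + n_count),
            "level2": ["Binary block"] * n_binary + ["Count block"] * n_count,
            "level3": list(data.columns),
        },
        index=data.columns,
    )
    return TraitMatrix(data=data, var=var, granularity=3), labels + 1


def random_protein(rng: np.random.Generator, length: int = 120) -> str:
    """Random amino-acid sequence starting with methionine."""
    return "M" + "".join(rng.choice(list(_AAS), size=length - 1))


def make_protein_family(
    seed_protein: str,
    n_members: int = 5,
    mutation_rate: float = 0.10,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    name: str = "family",
) -> list[tuple[str, str]]:
    """Point-mutated copies of a seed protein (equal length → pre-aligned).

    Suitable directly as a seed alignment for
    :func:`genotrait.calibrate.build_hmm_from_seed_alignment`.
    """
    if rng is None:
        rng = subseed_rng(seed, f"family:{name}")
    members = []
    for i in range(n_members):
        seq = [
            str(rng.choice(list(_AAS))) if rng.random() < mutation_rate else aa
            for aa in seed_protein
        ]
        seq[0] = "M"
        members.append((f"{name}_{i + 1}", "".join(seq)))
    return members


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(str(rng.choice(_CODONS[aa])) for aa in protein)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_toy_genome(
    genome_id: str,
    orfs: Sequence[str],
    spacer_bp: int = 150,
    seed: int = 0,
) -> tuple[GenomeRecord, ProteinSet]:
    """Nucleotide genome with the given proteins planted as real ORFs.

    Each ORF is back-translated with random synonymous codons and anchored
    with in-frame stops in all three frames plus a Shine–Dalgarno motif a
    few bases upstream of its ATG, so a prokaryotic gene finder recovers the
    planted start. Returns the genome and the expected protein set.
    """
    rng = subseed_rng(seed, f"genome:{genome_id}")
    parts = [_random_nt(rng, spacer_bp)]
    expected = []
    for i, protein in enumerate(orfs):
        if not protein or any(a not in _CODONS for a in protein.upper()):
            raise ValueError(f"ORF {i} is not a valid amino-acid sequence")
        protein = "M" + protein.upper()[1:]
        parts.append("TAAATAAATAA")  # stops in all three frames
        parts.append(_random_nt(rng, 20))
        parts.append("AGGAGG" + "AATTCA")  # ribosome binding site + spacer to ATG
        parts.append(_back_translate(protein, rng))
        parts.append("TAAATAAATAA")  # terminate and block read-through frames
        parts.append(_random_nt(rng, spacer_bp))
        expected.append((f"{genome_id}|planted_{i + 1}", protein))
    sequence = "".join(parts)
    return (
        GenomeRecord(genome_id=genome_id, sequence=sequence),
        ProteinSet(genome_id=genome_id, proteins=tuple(expected)),
    )


@dataclass
class DetectionFixture:
    """End-to-end fixture: HMM library + manifest + genomes with known counts."""

    hmms: list  # pyhmmer.plan7.HMM
    manifest: list  # HmmVariable
    genomes: list[GenomeRecord]
    planted_counts: pd.DataFrame  # genomes × family, expected count table

    def write(self, outdir: str | Path) -> None:
        """Write genomes (FASTA), HMM library and manifest in pipeline formats."""
        from .schema import write_manifest

        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        for g in self.genomes:
            (outdir / "genomes" / f"{g.genome_id}.fa").write_text(
                f">{g.genome_id}\n{g.sequence}\n"
            )
        with open(outdir / "library.hmm", "wb") as fh:
            for hmm in self.hmms:
                hmm.write(fh)
        write_manifest(self.manifest, outdir / "manifest.tsv")
        self.planted_counts.to_csv(outdir / "planted_counts.tsv", sep="\t", index_label="genome")


def make_detection_fixture(
    family_names: Sequence[str],
    n_genomes: int = 5,
    max_copies: int = 2,
    protein_length: int = 150,
    trusted_cutoff: float = 50.0,
    seed: int = 0,
    extra_variables: Sequence = (),
) -> DetectionFixture:
    """Build protein families, their HMMs, and genomes with planted copies.

    Per genome and family a copy number in 0..``max_copies`` is drawn; each
    planted copy is a fresh low-divergence mutant of the family seed protein,
    so it scores far above ``trusted_cutoff`` while unrelated proteins stay
    below the engine's reporting floor. ``extra_variables`` (HmmVariable)
    are appended to the manifest unchanged — use this to cover rule-set
    variables that have no simulated HMM (they simply never get hits).
    """
    from .calibrate import build_hmm_from_seed_alignment
    from .schema import HmmVariable

    rng = subseed_rng(seed, "detection-fixture")
    seeds_by_family = {
        name: random_protein(rng, protein_length) for name in family_names
    }
    hmms = []
    for name in family_names:
        members = make_protein_family(
            seeds_by_family[name], n_members=5, mutation_rate=0.10,
            rng=rng, name=name,
        )
        hmms.append(build_hmm_from_seed_alignment(members, name))
    manifest = [
        HmmVariable(name=name, trusted_cutoff=trusted_cutoff) for name in family_names
    ]
    manifest.extend(v for v in extra_variables if v.name not in set(family_names))

    genomes = []
    counts = np.zeros((n_genomes, len(family_names)), dtype=int)
    for i in range(n_genomes):
        genome_id = f"toy_{i + 1:02d}"
        orfs = []
        for j, name in enumerate(family_names):
            n_copies = int(rng.integers(0, max_copies + 1))
            counts[i, j] = n_copies
            for _ in range(n_copies):
                mutant = make_protein_family(
                    seeds_by_family[name], n_members=1, mutation_rate=0.05,
                    rng=rng, name=f"{name}_copy",
                )[0][1]
                orfs.append(mutant)
        # one unrelated protein per genome as a decoy
        orfs.append(random_protein(rng, protein_length))
        genome, _ = make_toy_genome(genome_id, orfs, seed=int(rng.integers(2**31)))
        genomes.append(genome)
    planted = pd.DataFrame(
        counts, index=[g.genome_id for g in genomes], columns=list(family_names)
    )
    return DetectionFixture(
        hmms=hmms, manifest=manifest, genomes=genomes, planted_counts=planted
    )
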