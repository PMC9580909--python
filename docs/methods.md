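# Methods

This note documents the models, parameters, numerical choices, and
limitations behind `genotrait`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Gene detection and the count table

Input genomes are nucleotide FASTA (one genome per file; multi-record
files are treated as contigs of one genome) or pre-called proteomes
(`.faa`). ORF prediction delegates to Prodigal in anonymous (`meta`) mode:
it needs no per-genome training and behaves identically for short
synthetic genomes, isolates, and provisional MAGs/SAGs. Protein ids are
rewritten to `<genome>|<n>` in order of appearance so repeated runs are
reproducible.

Homology search delegates to HMMER (pyhmmer `hmmsearch`). The quantity
thresholded is the **full-sequence bitscore**; the e-value is carried for
reporting only. A hit is retained when its bitscore is ≥ the model's
trusted cutoff (a score exactly at the cutoff passes, consistent with the
"smallest score that maximizes F" selection rule below). For one
(protein, model) pair only the best-scoring hit is kept; the count of a
model in a genome is the number of **distinct proteins** with a retained
hit. A protein may count toward several models — paralog and family
overlap is resolved downstream by the rules, not by forced best-model
assignment. Models without a cutoff abort the run by default
(`missing_cutoff="reject"`); the `"pass"` policy keeps their hits with a
warning.

## Trusted-cutoff calibration

Per model, the benchmark is a set of positive and negative bitscores plus
`n_negatives_total`, the number of negatives scanned. Negatives the engine
never reported are real negatives sitting below every threshold; counting
them only in the denominator of FPR (and in TN) avoids biasing precision
while keeping FPR meaningful. Candidate thresholds are the observed score
values — F is piecewise constant between them, so a grid adds nothing. At
threshold `t`: `TP = #pos ≥ t`, `FP = #scored neg ≥ t`, `FN = #pos < t`,
`TN = n_negatives_total − FP`. Thresholds with `TP+FP = 0` have undefined
precision and are excluded from the argmax. F is computed in the
single-division form `2·TP/(2·TP+FP+FN)` (algebraically equal to
`2PR/(P+R)`): correctly rounded division makes mathematically tied F
values bit-identical across thresholds, so the smallest-threshold tie rule
is exact rather than float-lucky. Profile construction from seed
alignments delegates to the HMMER builder.

## The rule language

Rules are Boolean expressions over gene-family variables and other rules:
`&` (AND), `|` (OR), `!` (NOT), parentheses; `!` binds tightest, then `&`,
then `|`. Identifiers are case-sensitive (gene symbols can differ only by
case). NOT is included even though presence/absence pathway logic rarely
needs it: exclusion-style guild definitions do. Rule references must form
a DAG; compilation topologically orders rules (Kahn's algorithm, input
order among ready nodes, so compilation is deterministic) and computes the
closure of referenced variables. Variables missing from a presence vector
default to FALSE with a warning rather than an error — provisional
genomes routinely lack annotations.

Schema files (manifest, rules, trait hierarchy) are tab-separated text
with a versioned `#genotrait-<kind> v1` header. The trait-matrix TSV
carries three metadata header rows (name, strategy, value_type);
value_type is needed to reconstruct the mixed-type matrix on read-back.

## Substrate-class complex counts

A transporter/enzyme complex is functional only with all required
subunits, so a complex's count is the **min** over its subunit gene
counts; alternative complex forms realizing the same function (OR
branches) contribute the **max**, not the sum. Standalone annotated
enzymes count as 1-subunit complexes. The aggregation choice (min/max
rather than e.g. sum) is a modeling decision documented here and fixed by
hand-computed tests; it is flagged for sensitivity analysis rather than
claimed to be the only defensible option. NOT has no count semantics and
is rejected in count expressions.

## Trait matrices and rollup

Binary traits take their bound rule's assertion. Count traits store
per-base-pair genomic investments, `count / size_bp`; per-Mbp display is a
presentation concern only. Genomes with unknown size error by default
(`on_unknown_size="raw"` keeps raw counts with a warning — used for
proteome-only input). Rollup from granularity 3 to 2/1: binary parents OR
their children, count parents sum them (presence vs investment
interpretations); children of mixed value type under one parent are
rejected rather than silently coerced. The packaged `core` schema (three
denitrification end-product traits, two substrate-uptake count traits,
two stress-tolerance traits over 34 manifest models) is a representative
schema for testing and a template for user-supplied ones, not a complete
trait catalog.

## Life-history predictions

Growth-rate and growth-temperature regressions are **pluggable**: the
coefficients live in versioned plain-text model files (`feature<TAB>weight`
rows, `# key: value` metadata, `transform: identity|log`), and the shipped
files are synthetic placeholders marked as such — the package makes no
claim about their predictive accuracy. The codon-usage-bias statistic is
fixed to the Karlin–Mrázek bias `B`: the amino-acid-frequency-weighted L1
distance between synonymous codon usage of a highly expressed gene set
(ribosomal proteins, identified via `RIBO`-tagged manifest models) and the
genome-wide background; `B = 0` at identical usage. Fewer than 10
ribosomal genes flags the estimate low-confidence instead of failing.
Growth-temperature features are restricted to compositional quantities
computable from the FASTA inputs alone — genome/ORF nucleotide fractions,
GC, the 20 proteome amino-acid fractions, the IVYWREL fraction, mean
protein length; tRNA- and rRNA-gene-derived features used by some
published OGT models are not computed (they would require an RNA-gene
detector outside this package's scope), so model files must reference
only available features. Doubling time is reported in hours.

## Distance, clustering, variance partitioning

The mixed-type distance is the Wishart/Gower-family form

    d_ij = sqrt( (1/p) [ Σ_numeric (x_ik − x_jk)² / s_k²
                       + Σ_binary 1[x_ik ≠ x_jk] ] )

with `s_k²` the sample variance (ddof = 1) and `p` the number of columns
entering the sum. Zero-variance numeric columns have an undefined weight
and are dropped with a warning; an all-constant matrix yields the zero
matrix. Because a 0/1 mismatch equals the squared difference of the
binary codes, `d²` is a scaled squared Euclidean distance; consequently
the within-cluster sum `Σ_g (1/n_g) Σ_{i<j∈g} d²_ij` equals a
sum of squared deviations from centroids and can only shrink under
refinement — which is why `R²(k) = 1 − SS_within/SS_total` is
non-decreasing over nested cuts, with `R²(1) = 0` and `R²(n) = 1`.

Clustering is complete-linkage agglomeration (scipy); cut labels are
relabeled 1..k by first appearance so outputs are deterministic. Guilds
are defined at a fixed `k` or at the smallest `k` with `R²(k)` ≥ a target
fraction (default 0.7 in the CLI). Guilds smaller than `min_size` are
flagged but retained — filtering happens after assignment, never before
variance accounting. Across-guild trait differences use Kruskal–Wallis
per trait with Benjamini–Hochberg adjustment across traits; constant
traits are untestable and get NaN. Trait–trait association is Spearman's
ρ, with constant traits returned as NaN rows/columns (computed on the
non-constant subset, since scipy collapses to a scalar when any input
column is constant).

## Synthetic data: what it emulates, what it does not

The generators draw from numpy's PCG64; per-purpose sub-seeds mix the user
seed with CRC32 of a purpose string so stages are decoupled under one
seed.

* **Score sets** are Gaussians (defaults `μ_pos = 60`, `μ_neg = 20`,
  `σ = 4`, 50 positives / 200 negatives): a 10σ separation that a sound
  calibrator must resolve at F = 1. Overlapping sets must be requested
  explicitly.
* **Planted-guild matrices** default to 60 genomes, 3 guilds, 30 binary +
  6 count traits, per-trait Bernoulli separation (`divergence`) 0.8 over a
  noise floor 0.05, Poisson count rates 3/30, genome sizes uniform in
  2–6 Mbp. `divergence` is the separation `p_on − p_off` per
  characteristic trait; characteristic traits cycle one-hot over guilds
  (all-pairs Hamming profile divergence ≥ 0.8 is impossible for ≥3 guilds
  by the triangle bound, so separation is the meaningful knob).
* **Toy genomes** back-translate planted proteins with random synonymous
  codons, anchored by stop codons in all frames on both sides and a
  Shine–Dalgarno motif upstream of the ATG, so the gene finder recovers
  the planted starts; 150-aa planted proteins are long enough for
  reliable calling in anonymous mode.

None of this emulates real evolutionary sequence divergence, base
composition bias, operon structure, genome incompleteness, or
contamination. Passing tests therefore demonstrate algorithmic
correctness (detection, logic, algebra, clustering) — not performance on
real genomes, which depends on the quality of the HMM library and
benchmark score sets supplied by the user.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale problems: 5-genome
extraction fixtures, 8 simulated gene families, 20–60-genome guild
matrices, 1000 random score sets, 10⁴ rule-engine oracle cases. These
sizes were chosen so the whole suite exercises every stage end to end in
seconds while keeping oracle comparisons exhaustive. Extraction outputs
are byte-identical across reruns and thread counts: per-genome work is
keyed and sorted by genome id, and all randomness flows from explicit
seeds.

## Known limitations

* No genome-completeness correction for MAGs/SAGs: per-bp investments on
  incomplete assemblies are underestimates.
* Domain-level thresholding is not offered; only full-sequence bitscores
  are filtered. Sensitivity of trait calls to this choice is untested.
* Substrate-class aggregation (min/max) is one defensible convention;
  sums would weight promiscuous transporter repertoires differently.
* The shipped life-history model files are placeholders; predictions are
  pipeline demonstrations until trained coefficients are supplied.
* Fragment-mode (metagenome read) gene calling is out of scope.
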