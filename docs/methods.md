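# Methods

This note documents the models, conventions, parameters and numerical
choices behind `regulonscope`, and what the synthetic benchmarks do and
do not demonstrate.

## Coordinate and track conventions

Genomic coordinates are 1-based inclusive (GFF convention). The
translation start is the first base of the start codon: `start` on the
plus strand, `end` on the minus strand. Density tracks are strandless,
binned vectors; bin *i* covers `[origin + i·w, origin + (i+1)·w − 1]`
for bin width *w* (default 10 bp, configurable — the binning of the
underlying data is not uniquely determined, so positions derived from
bins carry a ±w uncertainty and all positional tests allow it). Tracks
are treated as linear; the bacterial chromosome is circular, but with
peaks hundreds of kilobases from the origin-spanning join the
distinction is immaterial and no planted or observed feature spans it.
bedGraph I/O converts to that format's 0-based half-open convention.

## Peak calling

A peak is a maximal run of bins whose density stays **strictly above**
the threshold (default 10 density units). "Above" is read strictly:
boundary bins exactly at the threshold terminate a run; a `strict=False`
flag switches to ≥ for sensitivity analyses. The peak maximum is the
leftmost maximal bin (deterministic tie-break); `max_position` is that
bin's centre. Peak area is the plain sum of bin densities over the run,
so the areas of all peaks equal the total density above threshold (a
conservation law the tests check).

The promoter window — translation start within 200 bp upstream through
60 bp downstream of the peak maximum — is applied **strand-relatively**:
"upstream" is only meaningful along the direction of transcription. An
`strand_relative=False` compatibility mode applies plus-strand geometry
to every gene for comparison against analyses that ignored strand. A
peak may hit several genes and a gene may collect several peaks; the
largest-area peak is reported as primary, all are retained.

Operon propagation is **upstream-to-downstream only**: a gene is flagged
as a direct target if it has a window-assigned peak itself, or if any
gene *before* it in its operon's transcription order has one. A peak on
an internal member does not propagate back to the leader — a promoter
can only drive genes transcribed after it.

## Regulon classification

Fold changes are ratios of condition means on the linear scale with a
pseudocount (default 1) on normalized expression; the pseudocount
prevents division by zero and keeps zero-expression genes from crossing
thresholds spuriously. Replicates are averaged linearly before the
ratio. Where raw counts are supplied, `normalize_library` equalizes
column sums (CPM-style); pre-normalized input passes through with
`mode="identity"`.

The classifier is a pure fold-change filter with three conjunctive
conditions for direction *d* ∈ {up, down}:

1. ≥ `fold_threshold` (default 2) in direction *d* after **both** 6 h
   and 9 h of chaperone depletion;
2. ≥ `fold_threshold` in direction *d* upon active-sigma (V56A)
   overproduction;
3. a "milder or absent" response in the sigma-deletion background,
   implemented as a disjunction of two individually switchable arms:
   *absent* — |log₂ FC_Δ| < log₂ `absent_threshold` (default 2);
   *milder* — sign-concordant with *d* and
   |log₂ FC_dep| − |log₂ FC_Δ| ≥ log₂ `milder_factor` (default 2),
   anchored on the 6 h depletion contrast (configurable to 9 h).

`absent_threshold` is deliberately a constant of its own rather than an
alias of `fold_threshold`: the no-response bound describes the deletion
background, and tying it to the regulon threshold would make raising
the threshold *loosen* condition 3 — regulon membership would not be
monotone in `fold_threshold`. With the decoupled constant, raising the
threshold can only shrink the regulon (a property test enforces this).
The two arms are switchable because published phrasing of such "milder
or no response" filters is ambiguous; both arms on is the default.

Direct-target annotation intersects *upregulated* members with the
ChIP flags (own peak or inherited through the operon); binding evidence
models sigma-factor activation, so downregulated genes are never called
direct. The attenuated-mutant (D252G) contrasts are computed and
reported but never enter the regulon definition. Scatter statistics are
ordinary least squares of log₂ fold changes (y on x), reporting R² and
the slope *m*.

No dispersion-based differential-expression testing is performed; the
classification criterion is a fold-change filter by design, and
replacing it with a count-model test would change what is being
reproduced.

## Proteome quantification

Protein abundances are normalized to portions of 100 % per sample.
Fold change is the ratio of replicate means; significance is a
two-sample *t*-test on per-replicate log₂ abundances — pooled-variance
Student by default (Welch via `equal_var=False`; the choice matters
little at triplicate scale and both are exposed). **No multiple-testing
correction is applied**: calls use the raw p ≤ 0.05 with a 1.5-fold
threshold, so the resulting sets are descriptive screens, not
FDR-controlled discoveries. Zero-variance groups (possible only in
noiseless synthetic data) yield an undefined p-value and are excluded
from significance-gated calls. Proteins absent from all samples of a
group are reported as not-detected rather than erroring. Protein→gene
mapping is identity by default; a mapping series is accepted for data
where identifiers differ.

Note that sum-to-100 normalization is compositional: a large planted
up-regulation deflates every other protein's ratio by the factor
total_exp/total_ctrl. Recovery tests correct for this drift using the
null proteins' median ratio.

## Mass-fraction allocation

Molecular investment of protein *p* in a condition is
`mean relative abundance × sequence length` (residues), a proxy for the
amino acids invested; "relative molecular count" is taken as the
normalized TMT abundance, portions-of-100 scale. Investments are
renormalized to fractions summing to 100 % and aggregated over a
hierarchy in which each protein maps to exactly one leaf path; at every
level the fractions sum to 100 % and signed percentage-point changes
across categories sum to zero. Percent change is relative
(Δ/baseline × 100), matching "increased by 49 %"-style statements; the
absolute point change is reported alongside. Condition abundances are
replicate means. Statistically insignificant proteins remain in the
investment sums — significance affects only downstream colouring
metadata, not sizes. Treemap rendering itself is out of scope; the
nested export is renderer-agnostic JSON-able records.

## Half-life estimation

Single-exponential (first-order) decay is assumed — the standard model
for translation-shutoff chases. The fit is log-linear OLS with a
**shared slope and per-replicate intercepts** (each lane has its own
loading); intensities are normalized to each replicate's t = 0 value,
which only shifts intercepts. k = −slope, t½ = ln 2 / k. Log-linear OLS
was chosen over nonlinear least squares for determinism; the estimator
is exact on noiseless exponential input (relative error < 1e-9 in the
tests). Estimates with k ≤ 0 or t½ beyond the observation window are
reported censored ("t½ > t_max"); lengthening the window can only
uncensor, never the reverse. Fits need ≥3 distinct time points and
strictly positive intensities.

## Synthetic-data generator

The generator's defaults are the emulated study conditions: 3000 ORFs
in ~300 operons on a ~4 Mb genome (auto-sized to the packing), planted
regulon of 300 up / 80 down genes with 180 direct targets, planted
effects of |log₂ fold| = 3 (`effect_up=8`, `effect_down=0.125`),
multiplicative lognormal noise at CV 0.2, ChIP background mean 2 with
planted bump height 50 over a calling threshold of 10, biological
triplicates. All noise is mean-one lognormal: positivity and CV
parameterization match the ratio-based downstream analysis. Every
generator is a pure function of the seed (independent substreams per
stage), and outputs are bit-for-bit reproducible.

Layout choices that make the end-to-end identity property structurally
attainable rather than accidental: transcription units are separated by
450–800 bp of intergenic space and planted bumps sit 60–100 bp upstream
of their target's translation start, so no planted peak can fall inside
the −200/+60 window of a neighbouring unit's start and no two bumps can
merge. Operon members sit 20–120 bp apart. Direct targets are planted
as whole transcription units (the bump at the leader's promoter, all
members direct), which is exactly the closure the propagation rule
computes. Direct targets are planted only among upregulated genes,
mirroring binding evidence being used for activation only.

Condition structure: regulon genes carry their planted fold in the
depletion (6 h, 9 h) and V56A conditions, fold 1 in the deletion
background, and **half the log₂ fold** in the attenuated-mutant (D252G)
conditions — the attenuation factor is a modelling choice (the source
observation is only "similar but less pronounced"), not a measured
value. Protein-level responses are damped relative to transcripts:
protein log₂ fold = `protein_response_damping` × transcript log₂ fold
(default 0.5), reflecting translational and turnover buffering; without
damping, planting |log₂| = 3 folds directly into a sum-normalized
proteome creates a compositional shift large enough to push essentially
every null protein past the 1.5-fold down threshold — unlike any real
TMT dataset. A `proteome_concordance` fraction (default 0.7) of regulon
genes responds at the protein level at all. The synthetic functional
hierarchy assigns upregulated genes mostly to maintenance categories
(folding/export/degradation), downregulated ones to translation and
replication, the rest to metabolism and transport — enough correlation
structure for the allocation stage to show the expected reallocation
signature.

The ChIP background is clipped at 9.5 so that background alone can
never cross the default threshold; with the default CV the clip is
never reached in practice. Bumps are Gaussians with σ = 40 bp.

**What the synthetic benchmarks do not show.** The generator has no
read-level artifacts (mappability, duplicates, input bias), no
overdispersed counts, no batch effects, no missing values in the
proteome, no shared-promoter ambiguity beyond operons, and its noise is
exactly the lognormal the ratio analysis assumes. Passing recovery
tests therefore validates the *logic and numerics* of the pipeline —
window arithmetic, propagation closure, set logic, estimators — not its
robustness to real-data pathologies.

## Problem sizes and test design

The default test suite runs the full 3000-gene study (single runs take
well under a second), 20-seed recovery batteries, 1000 random tracks
against a naive peak-caller reference scan, and 10⁴ random fold-change
tuples against a brute-force classifier; the whole suite completes in
well under a minute. The proteome fold-recovery property keeps the
stated noise (CV 0.1) and fold (2) but uses 12 replicates per group,
because the sampling error of a ratio of triplicate means (~8 % CV)
would by itself exceed the ±10 % recovery band being checked.

Analyses of the published processed tables run through
`regulonscope.published`, which standardizes column aliases and applies
the identical classifier stack; the workbook is not redistributed with
the package.
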