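# Methods

## Scope and data model

The package consumes *called and annotated* variants, never reads. A
`VariantRecord` carries depths (DP/AD), a coding consequence, and boolean
annotation flags (polymorphism-database membership as the union of
dbSNP/1000G/ESP, COSMIC membership and confirmed-somatic status, ClinVar
membership, damaging prediction). Treating annotations as precomputed inputs
removes any dependence on database versions or network access; a user's
annotation pipeline fills the flags once. Variant coordinates are 1-based
(VCF convention); copy-number segments and gene models are 0-based half-open
(BED convention); the two meet only in `variant_overlaps_interval`, which
maps a variant position `pos` to half-open coordinate `pos − 1`.

## Filter cascade

Stages run in a fixed order — depth, non-silent selection, polymorphism
filter, control subtraction, sub-clonal labeling — because the first three
are independent predicates (their order cannot change the surviving set,
which the tests assert by permutation) while subtraction and labeling depend
on what reaches them.

*Depth.* DP ≥ 10, boundary inclusive, applied to tumor records and —
separately — to control evidence: a control call below 10x cannot veto a
tumor variant, since it could itself be a dropout.

*Polymorphism filter.* Database-present variants are discarded unless also
in COSMIC or ClinVar; any ClinVar membership rescues (the filter does not
distinguish benign entries — their somatic status is settled downstream by
control subtraction or the recurrent-variant flag).

*Control subtraction.* Matching is exact on (chrom, pos, ref, alt) after
indel left-normalization (shared trailing bases trimmed, then shared leading
bases with the position advanced, always keeping one base per allele), so
representation differences between callers cannot cause misses. Paired mode
subtracts only the matched normal; unpaired mode subtracts the pooled
normals.

*Sub-clonal labeling* (paired mode only). With purity ρ (default 0.9,
reflecting highly purified plasma-cell preparations) the clonal expectation
for a heterozygous diploid variant is VAF = ρ/2. A call is sub-clonal when
an exact one-sided binomial test of alt ~ Bin(DP, ρ/2) rejects low at
α = 0.05 *and* CCF = 2·VAF/ρ < 0.5. The two-part rule is this package's
declared surrogate for an unpublished procedure: the test controls false
sub-clonal labels on clonal variants at ≤ α (verified empirically at ≤ 2α),
and the CCF gate keeps borderline-significant near-clonal calls clonal. Both
α and the CCF threshold are parameters.

*Carry-over audit.* Each paired tumor is run paired (matched normal) and
unpaired (pool of the *other* samples' normals); calls unique to the
unpaired run estimate the private germline background that unpaired samples
cannot shed. With one normal the "other" pool is empty and the unpaired leg
runs without subtraction — the audit then measures the full
database-absent background.

*Recurrent-variant flag.* Identical variants in ≥ 2 unpaired samples that
are database-present and in COSMIC without confirmed somatic status are
flagged as possible residual germline; recurrence counting downstream counts
each such identity once per gene so genes are not over-scored.

## Mutational signatures

Spectra use the conventional 96-class order (substitutions C>A…T>G
alphabetical, flanks A,C,G,T), with purine-reference calls
reverse-complemented. SNVs lacking a resolvable context are reported in an
`n_no_context` tally rather than silently dropped. Spectra are built from
the germline-filtered, *pre*-non-silent variant set, because silent
substitutions carry the same mutational-process information; a different
cascade stage can be fed explicitly.

Decomposition solves min‖p − M·e‖₂, e ≥ 0, by NNLS on the normalized
spectrum and renormalizes e to sum 1. The test oracle is a brute-force grid
over the mixing weight with the closed-form optimal scale per grid point —
the same objective searched exhaustively. Attribution uses a declared
convention: one exposure ≥ 0.7 ⇒ "distinct" process, else admixture. The
built-in profile matrix places 0.97 of each signature's mass uniformly on
its characteristic contexts (4 NpCpG C>T classes for aging; 8 TpCpN C>T/C>G
classes for APOBEC) and the remainder uniformly elsewhere; canonical
reference matrices are deliberately not bundled (any user 96×K TSV is
accepted) to avoid version drift.

## Copy-number integration

One transcript per gene — the largest span, ties to the lexicographically
smallest transcript id. A gene's copy number is that of the overlapping
segment with the greatest overlap length (`mixed_flag` when distinct CNs
overlap); any overlapping CN = 0 segment forces the class to homozygous
deletion even when it is not the majority overlap, because a focal
homozygous loss inside a gene destroys it regardless of the rest of the
span. In that override the recorded `copy_number` remains the
greatest-overlap value while the class reports the deletion — the one place
class and number may disagree, by design. Per-sample ploidy baselines
shift the class thresholds (baseline 4 for a basally tetraploid sample maps
CN 2 → homozygous-equivalent, CN 3 → one-copy loss, etc.).

Two-hit calls are homozygous deletions, or ≥ 1 non-silent somatic call on a
hemizygous-deletion background. Two somatic mutations in one gene without
copy loss are *not* two-hit (phase unknown) and are reported separately as
multi-mutated.

## Recurrence, enrichment, FDR

The spurious-gene list (very long or late-replicating genes recurrently
mutated in cancer surveys without biological relevance) ships as an editable
text file; listed genes keep their recurrence rows but are excluded from
enrichment. The enrichment universe is all non-silent calls in genes after
spurious exclusion — variant-level, matching a damaging/total-variants
report shape; tests are one-sided (enrichment only). The Fisher p-value is
the hypergeometric upper tail computed by direct summation in log space
(scipy's distribution is the independent oracle in tests). The resampling
null draws B subsets of m calls without replacement and compares the
damaging fraction; since the damaging count of such a draw is exactly
Hypergeometric(n, d, m), the implementation samples that distribution
directly — the same null, vectorized. The add-one estimator
(1 + #{≥ obs})/(B + 1) keeps p ≥ 1/(B+1). BH step-up is implemented directly
(statsmodels is the test oracle).

## Expression integration

"Most variably expressed" means max |deviation from the gene's cross-sample
mean| ≥ log2(fold), fold = 2 by default. Clustering is average linkage on
1 − Pearson distances between sample profiles over the chosen gene subset
(declared conventions; scipy's deterministic linkage provides the
index-based tie-break). Group association avoids post-hoc cluster selection:
the statistic is the largest number of a group's samples in any one cluster,
referred to B permutations of the cluster labels. The clustering-replication
probability draws random gene sets of the focal size from the variable-gene
list and compares BHI (mean within-cluster fraction of annotated pairs
sharing a class, over clusters with ≥ 2 annotated members). Differential
expression is a Welch t-test per gene on log2 values with BH FDR; genes with
zero variance in both classes get p = 1 and a flag.

## Synthetic cohort

The generator emulates the target study design: 12 tumors, 5 with matched
normals, mean depth 42x (per-site depth Poisson, truncated at 1), ~1,500
germline variants per individual, 150 clonal non-silent somatic events plus
30 silent ones per tumor, 20 sub-clonal events (CCF 0.2) in paired samples,
7% of somatic events indels, ~20 CN segments per sample, and
translocation-group-linked signature weights (t(14;16) tumors
APOBEC-dominant at (0.1, 0.9); one t(11;14) tumor aging-driven at
(0.9, 0.1); the rest admixtures at (0.6, 0.4)). Germline sites come from a
shared population pool (each individual carries a pool site with
probability 0.6, topping up with private sites to the exact per-sample
count) and are database-present with probability 0.98 — the 2% absent
fraction exercises pool subtraction and the carry-over audit. Germline VAFs
are Bin(DP, 0.5) or Bin(DP, 1) (hom, probability 1/3); somatic clonal
Bin(DP, 0.5ρ); sub-clonal Bin(DP, 0.5ρ·CCF); alt depths are clamped to ≥ 1
because callers only emit observed variants. Six mutation + 1-copy-loss
genes are planted per tumor and three homozygous deletions cohort-wide, each
on its own chromosome so planted and random segments never overlap. A
25-gene "planted_enriched" set receives damaging variants at probability 0.8
versus 0.25 background. The expression matrix covers the toy genome's ~500
genes over the 12 tumors plus 24 background myeloma samples: 60
group-structured genes (per-group offsets, SD 2.0) and 40 disease-class DE
genes (±1.5 log2) are drawn from the mutated genes; 150 further genes get
extra SD-1.0 noise so the 2-fold variability cut is a real filter; baseline
noise SD is 0.35.

What the generator does *not* model: read-level artifacts, mapping bias,
linkage/haplotypes, mutation hotspots, signature strand bias, copy-number
effects on VAF, or realistic gene-length distributions. Passing tests
therefore demonstrate the correctness of the pipeline's logic and
statistics under the declared generative model, not robustness to real-data
artifacts. Desk scale also makes the mutated-gene set cover most of the toy
genome, so the default cohort's variable/mutated gene overlap is much denser
than in a real exome; the replication-probability test is exercised on
purpose-built matrices where the focal set is a small fraction of the pool.

## Numerical and testing choices

Problem sizes in the test suite are chosen for desk-scale determinism: the
cascade property sweep uses 50 three-tumor cohorts plus one full default
cohort; signature recovery uses 1,000-SNV spectra over 20 seeds per planted
mixture; Fisher is checked against the oracle on every admissible 2×2 table
with n ≤ 60; the permutation-test calibrations use 200 null repeats each,
with statistic granularities (600 calls / 60 in-set; 60 samples in 5
clusters with a 24-sample group; BHI over 24 samples) chosen so the discrete
null actually has achievable p-levels near 0.05 — with a coarser statistic a
valid permutation test is conservative at any fixed cut and a calibration
band check would be uninformative. All simulations are seeded
(`numpy.random.default_rng`); identical seeds give byte-identical emitted
files and pipeline bundles (the manifest records a SHA-256 per output).

## Known limitations

Unpaired-mode somatic status is never proven, only made likely; the
germline-risk flag and carry-over audit quantify, not eliminate, residual
background. The sub-clonal rule assumes diploidy at the variant locus and
ignores local copy number. Signature attribution with K = 2 cannot detect
processes outside the provided matrix (de novo extraction is out of scope).
Gene projection uses a single transcript and ignores partial-gene deletions
smaller than the overlap rule resolves. Enrichment treats calls as
exchangeable across genes, ignoring per-gene mutation-rate covariates —
driver discovery against background mutation rates is explicitly not
implemented (recurrence ranking stands in).
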