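# Methods

This note documents the models, defaults and design choices behind each
stage of the package, what the synthetic generators do and do not
emulate, and the numerical conventions used throughout.

## Single-cell quality control and selection

Per-cell metrics are detected-gene count, total UMI count, and
mitochondrial fraction (mito UMIs / total UMIs; a zero-total cell gets
fraction 0 and a degenerate flag). The three retention rules —
`min_genes_detected = 1500`, `max_mito_fraction = 0.15`,
`max_umi_total = 15 000` — treat removal conditions as **strict
inequalities**: a cell with exactly 1500 genes, 15 % mito or 15 000 UMIs
is kept. Whether the boundary should be kept or removed is genuinely
ambiguous in common practice; we pick the strict reading, document it,
and make all three thresholds configurable. The partition buckets are
`kept`, `removed_low_quality` (gene or mito rule) and `removed_doublet`
(UMI rule); a cell that violates the UMI cap *and* a low-quality rule is
classed as a doublet — doublets are a distinct artifact class, not merely
bad cells — but every violated rule is recorded per cell, so no
information is lost to the tie-break.

Mitochondrial genes are identified by an explicit list, a `var["is_mito"]`
flag, or an `mt-` symbol-prefix fallback, in that order of precedence.

Normalization is the conventional library-size scaling to 10 000 counts
followed by log1p. In-silico mesenchymal selection keeps cells with
normalized *Pdgfrb* expression strictly above a threshold (default 0,
i.e. any nonzero count — no principled expression cut exists for a gate
gene, so the most inclusive rule is the default). The purity check
reports, per absence marker, the fraction of cells with nonzero
expression and passes at ≤ 1 % positive cells.

## Differential expression and markers

The DE test is the two-sided Wilcoxon rank-sum on log-normalized values:
exact enumeration when both groups have ≤ 8 cells and no ties, otherwise
the tie-corrected normal approximation. log₂ fold changes are computed on
expm1-backtransformed group means with a pseudocount of 1; p-values are
Benjamini–Hochberg adjusted across all tested genes. A marker passes with
adjusted p ≤ 0.05, log₂FC ≥ 0.25 and ≥ 25 % detection in the foreground
group; candidates are ranked by adjusted p, then |log₂FC|, then gene
symbol (fully deterministic under ties) and capped at `top_k = 12`.

Cross-dataset replication retains a marker only if it passes the same
thresholds (no cap) in **every** additional dataset; a gene absent from a
dataset fails there. The all-datasets-AND rule is the strictest
reasonable replication criterion; the evidence table preserves the
per-dataset statistics so weaker rules can be applied post hoc.

## Module scores and trajectory origins

Signature scores use the binned-control scheme standard in the
single-cell ecosystem: genes are ranked by mean expression into
`n_bins = 25` equal-frequency bins; for each signature gene,
`controls_per_gene = 50` controls are sampled (seeded, without
replacement within the bin) from the gene's own bin; the score is the
mean expression of signature genes minus the mean over the pooled control
draws. Controls are sampled in symbol-sorted signature order, making
scores invariant to the order signature genes are listed in. For a random
gene set the score is centred at zero (a tested property), so scores are
comparable across clusters.

A trajectory is an *input* — an ordered cluster chain from candidate
origin to terminus; the package does no trajectory inference. The origin
call is operationalized as **monotone decay**: the candidate is
"supported" iff the mean score of its signature strictly decreases at
every step along the chain, and "ambiguous" otherwise. One-sided
rank-sum p-values for each consecutive pair are reported as evidence
rather than folded into a hard significance rule, because the biological
claim is about the ordering of cluster means, not any single pairwise
test.

## Ortholog mapping and enrichment

The ortholog table is static (two columns, mouse and human symbol). All
rows participating in one-to-many *or* many-to-one relations are dropped
— not resolved first-hit — so the resulting map is bijective and the
enrichment counts are well defined; dropped counts are reported. The
overlap test is the upper hypergeometric tail P(X ≥ k) (via the survival
function, evaluated in log space internally), with both query and target
restricted to an explicit universe before counting. The universe is a
choice the caller must make (typically all genes detected in the relevant
matrix); it is always echoed in the result for audit.

## Correlation skewness and its permutation test

Per-gene trait correlations are Pearson by default (Spearman available)
over complete segment pairs; pairs with a constant vector or < 3 complete
observations are flagged invalid and excluded everywhere downstream. The
gene-set statistic is S = Σ_{r>0} r − Σ_{r<0} |r|, computed literally;
algebraically S is the plain sum of the correlations, and that identity
is asserted by tests rather than assumed.

The null draws B random gene sets of exactly the observed size m
("similar number of genes" is read as *equal* — the only reproducible
choice) from the genes with valid correlations for that trait, so
observed and null statistics are comparable. p_upper is the frequency of
null sets with strictly higher S, with no +1 smoothing; the 1/B
resolution is carried on the result, and the lower tail is reported
symmetrically so negatively skewed sets are testable. Draws whose S ties
the observed value within a relative tolerance of 1e-9 (in practice, a
redraw of the observed set itself, whose floating-point sum can differ by
rounding) count toward neither tail; without this the estimator acquires
a small systematic bias of order 1/C(u, m). An exhaustive-enumeration
mode provides exact tails for small universes (≤ 10⁶ subsets) and serves
as the oracle for the Monte-Carlo path.

Across a set × trait grid, one master seed spawns an independent
substream per cell (`SeedSequence(entropy=seed, spawn_key=(i, j))`), so
any single cell is reproducible in isolation. Significance is flagged at
raw p < 0.05 on either tail by default — no multiplicity correction,
matching the practice of flagging raw-p violins — with an optional
Benjamini–Hochberg switch.

Note a real property of this test: it asks whether a gene set's S is
extreme relative to *random* gene sets, under the observed trait vector.
A coherent set whose members share latent variation can reach
significance on a trait it was not planted on when the two traits'
latent factors are correlated by sampling chance (unavoidable at ~43
segments). This is exchangeability of genes, not independence of traits.

## Synthetic data generators

Counts follow a negative binomial (gamma–Poisson) law per gene: base
means are log-normal draws (σ = 1) scaled to `nb_mean = 5`, with shared
dispersion θ = 2. With the default 2000 genes this puts singlet UMI
totals at ≈ 10 000 (sd ≈ 300), comfortably below the 15 000 doublet cut,
while doublets — flagged barcodes whose counts are the sum of their own
draw and a draw from a second uniformly sampled cell profile — land near
20 000, far above it. Mitochondrial content is planted by repartitioning
each cell's expected total between mito and non-mito genes (target
fraction 0.05 normally, 0.25 for designated outlier cells), so mito
outliers do not confound the UMI rule. With 10 mito genes and θ = 2 the
sampled mito fraction has sd ≈ 0.05, so a planted outlier occasionally
falls below the 0.15 threshold; exact-partition tests therefore use
constructed fixtures with analytically known metrics, while generator
tests assert the cleanly separated doublet rule.

Planted structure: a 12-gene fibroblast marker panel elevated by
2^`logfc_markers` (default 4×) in fibroblasts (optionally only the first
`n_active_markers`, which is how replication datasets with 7 of 12
active markers are built); three branch programs whose genes ramp
linearly in log-mean from base at position u = 0 to +`logfc_branch` at
u = 1; and a shared origin program decaying the same way, giving
trajectory-origin inference a recoverable signal. Default cell
composition is 2/3 fibroblast, 1/3 mural, ~3000 cells — a sorted
mesenchymal preparation at the scale of a typical droplet experiment.

The bulk generator uses one latent standard-normal factor per trait
across segments; the trait column *is* the factor, and a planted gene is
baseline + Σ_t λ_{s,t} z_t + σ ε, so the population correlation with
trait t is λ_t / sqrt(Σλ² + σ²) in closed form (`loading_for_target_r`
inverts it). Defaults emulate the validation cohort scale: 43 segments,
planted sets of 46/32/23 genes, the last loading negatively, each at
target |r| = 0.5.

Not emulated: ambient RNA, batch effects, spliced/unspliced layers,
cell-cycle structure, realistic gene-gene correlation beyond the planted
programs, or trait measurement error. Passing tests therefore show the
*procedures* behave correctly where truth is known; they do not certify
performance on tissue data with those additional noise sources.

## Problem sizes and determinism

Default analysis sizes — 3000 × 2000 single-cell, 500-gene bulk universe,
B = 10 000 in the pipeline and 100 000 in the acceptance script — were
chosen so a full run completes in seconds on one CPU while keeping every
planted effect comfortably detectable. All randomness flows from explicit
seeds (one master seed plus fixed offsets in the pipeline); reruns are
byte-identical in every stage output. The run manifest additionally
records wall-clock per stage, which is the one intentionally
non-reproducible field, so determinism checks compare all outputs except
the manifest.

## Known limitations

- The DE test is cell-level Wilcoxon; no pseudobulk or mixed models, so
  p-values on real multi-animal data would be anti-conservative.
- The origin rule is one formalization of "signature enrichment at the
  origin"; monotone decay can be ambiguous for shallow or noisy ramps
  even when the origin is correct.
- Ambiguous orthologs are discarded wholesale, which is conservative for
  enrichment (k can only shrink).
- The permutation test's gene-exchangeability null ignores gene-gene
  correlation within candidate sets; interpretation should account for
  it (see the trait-correlation note above).
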