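# Methods

## The measurement problem

Depth normalization makes ChIP-seq samples incomparable in absolute terms:
if a histone modification quadruples everywhere, per-sample scaling maps
both conditions onto the same profile and the change vanishes. Barcoded,
pooled immunoprecipitation (a RELACS-style design) removes this blind spot:
all samples share one IP reaction, so the post-demultiplexing read count of
each sample is proportional to the amount of immunoprecipitated chromatin.
The package's quantitative core is the pairwise global scaling factor

s(A→B) = (chip_B/input_B) / (chip_A/input_A)

computed on genome-wide totals of deduplicated fragments with mapping
quality strictly greater than 5. With n_A and n_B replicates, all
n_A x n_B cross-condition pairings contribute one ratio; the reported mean
is the geometric mean of the ratios, which makes the A→B and B→A estimates
exact reciprocals, and the standard deviation is reported on the linear
scale alongside. Genome-wide totals are large, so no pseudocount is used
there; a zero input total is an error, not a quantity to patch.

## Read handling

Reads carry a 4 bp UMI followed by an 8 bp sample barcode. Demultiplexing
assigns a read to the unique barcode within `max_mismatch` (default 1)
Hamming distance; the scheme validator enforces pairwise barcode distance
> 2·max_mismatch, so assignment is never ambiguous. The bundled default
barcode set doubles four GF(4) symbols with one parity symbol, giving up to
64 barcodes at pairwise distance ≥ 4. UMIs are grouped by exact match only
— a 4 bp UMI has too little redundancy for error correction — and one
representative survives per (UMI, chromosome, position, strand). Fragments
are assigned to disjoint bins by their midpoint, which is unambiguous.

## Local vs global fold changes, and the change decomposition

Per-bin fold changes come in two modes. *Traditional* mode depth-normalizes
each sample, then input-normalizes each bin: any genome-wide shift is
absorbed, and what remains is change relative to the sample's own global
level. *Quantitative* mode multiplies the condition-B enrichment by the
global scaling factor before the ratio, so a uniform shift reappears as a
constant log2(s) offset in every bin; the two modes differ by exactly that
constant when the ratio-space pseudocount is zero. A count-space
pseudocount (default 1) keeps empty bins finite without breaking the
identity.

A global change is classified from quantitative-mode fold changes using
the median over peak bins (m_p) and over background bins (m_b):

- none: |m_p| < τ and |m_b| < τ
- locally driven: |m_b| < τ ≤ |m_p|
- genome-wide driven: both ≥ τ, same sign, |m_p − m_b| < δ
- mixed: anything else

with defaults τ = 0.25 and δ = 0.5 in log2 units. The thresholds are
exposed in configuration; the dichotomy itself (change at enriched loci vs
uniform accumulation) is the scientific content, the numeric defaults are
the package's own choice of a quarter-fold "no change" band and a
half-fold tolerance for uniformity.

Gene stratification uses k-means (k = 5 by default, 50 restarts, squared
Euclidean) on per-gene log2(chip/input) enrichment in the two cell types,
with clusters relabeled 1..k by descending mean enrichment so the labels
are invariant to initialization permutations.

## Feature windows

Marks are quantified on windows anchored at the TSS or TTS, strand-aware.
The default preset (`quantify`) uses TSS ± 1 kb for H3K4me3/H3K27ac/
H3K4me1, TSS − 1 kb .. + 3 kb for H3K79me2/H3K27me3/H3K9me3, and
TTS − 3 kb .. + 0.5 kb for H3K36me3. A second preset (`ma_bins`) with
wider promoter windows (TSS ± 2 kb; TSS..+3 kb for H3K79me2; TTS − 3 kb)
is shipped for MA-style binned comparisons. Both presets are first-class
because reasonable window conventions differ between quantification and
visualization contexts; nothing downstream depends on which is chosen
beyond the window arithmetic itself.

## Mark → expression model

`MarkExpressionModel` regresses per-gene expression log2FC on the seven
mark log2FCs plus the H3K79me2·H3K27ac product term. The default penalty
is L1 (lasso) because the feature ranking is defined by the regularization
path: a feature's rank is the largest penalty at which its coefficient
first becomes nonzero, i.e. the order in which the path recruits
predictors. An elastic-net mixing parameter is exposed for users who want
correlated features to enter together. Features are standardized to unit
variance before fitting; coefficients are mapped back to the original
scale. The penalty is chosen by seeded 10-fold cross-validation, and both
the in-sample and the cross-validated R² are reported, since either can be
meant when a single number is quoted. In the vanishing-penalty limit the
fit reproduces ordinary least squares to numerical precision, which the
test suite checks against statsmodels.

DEG conventions: treatment-contrast DEGs are adjusted p < 0.05;
differentiation DEGs additionally require |log2FC| > 1 with adjusted
p < 0.01. Both are configuration constants, not magic numbers in code.

## Chromatin-state signatures and the varying-intercept model

Given a 15-state segmentation, each gene is summarized by 30 numbers: the
fraction of its promoter window (chosen TSS − 1000, + 500, strand-aware)
and of its full gene span covered by each state. The TSS is chosen by
intersecting transcript starts with H3K4me3 peaks; among several peaked
transcripts the 5′-most start on the gene strand wins, and genes with no
peaked transcript fall back to the full annotation (flagged). The dominant
promoter state is the argmax of the promoter fractions, ties broken toward
the lowest state index. Windows reaching outside segmentation coverage are
clipped and renormalized with a flag rather than silently mis-scaled.

Expression change by dominant promoter state is modeled hierarchically:

    Log2FC_g ~ N(α[i(g)], σ)
    α[i] ~ N(μ′, σ′),  μ′ ~ N(0, 1),  σ ~ Exp(1),  σ′ ~ Exp(1)

The sampler is Metropolis-free Gibbs with slice updates: α and μ′ have
conjugate normal full conditionals; σ and σ′ are updated by univariate
slice sampling on the log scale (stepping-out with shrinkage), which needs
no tuning and targets the exact joint density. Four chains of 2000 kept
draws after 1000 warm-up iterations are the default; chains are
initialized from jittered data summaries and seeded independently.
Convergence is gated on split-R̂ < 1.05 (computed with arviz, along with
effective sample sizes); a non-converged posterior is returned flagged,
never silently. Degenerate groupings (fewer than two groups with at least
two observations) are likewise flagged — a single-group fit is still a
well-defined shrinkage-free posterior. The g × 30 signature matrix can be
embedded in 2-D with a seeded stochastic-neighbor embedding for
visualization; no inference attaches to the coordinates.

## Accessibility analysis

ATAC counts are variance-stabilized as log2(CPM + 1) — a deliberately
simple, config-swappable stand-in for heavier transforms — and peaks are
ranked by the absolute loading of a chosen principal component of the
peak × sample matrix. The loading sign is arbitrary, so the Down/Up class
of a selected peak comes from the sign of its mean treatment-vs-control
fold change. Annotation precedence is promoter-TSS (TSS − 1 kb .. + 100 bp)
> TTS (± 1 kb) > exon > intron > intergenic, each peak receiving exactly
one category; enhancer status is ≥ 1 bp overlap with the supplied enhancer
intervals, with the class (intronic/intergenic) taken from gene overlap.
Mark co-occurrence is summarized as the fraction of genes with at least
one intronic peak of a class (accessibility-losing, -gaining, or
unchanged) that carry H3K79me2; a gene counts as marked above a
log2(chip/input) cutoff of 0.5 on the mark's window (config constant).

Mann–Whitney U comparisons use the exact null for group sizes ≤ 8 without
ties and the tie-corrected normal approximation otherwise; the exact
branch is validated against a full-enumeration permutation oracle in the
tests. The paired one-sided t-test operates on control − treatment
differences with df = n − 1; zero-variance differences yield p = 0/0.5/1
by the sign of the mean difference, flagged.

## The synthetic-data generator

The generator is first-class, tested code, and its defaults are the study
conditions: 2 cell types × 2 treatments × 2 replicates, 7 marks plus
input, 2 kb bins. True differentiation scale factors default to 3.9
(H3K79me2), 1/2.3 (H3K27ac), 1.2 (H3K36me3, H3K9me3) and 1.0 for the
rest; treatment retention of H3K79me2 defaults to 0.449 (mESC) and 0.642
(NPC48h). H3K36me3's change is configured as peak-confined, the others as
uniform, matching the two mechanisms the decomposition distinguishes.
Counts are negative binomial with dispersion 0.05 (Poisson at dispersion
0; a deterministic "expected" family exists for exactness tests), with
expected bin count = depth × base rate × peak enrichment × true scale.
Peak regions are the feature windows of a 60% random subset of genes at
log2 enrichment 3. Expression log2FC is Σ β_m·Δm + β_int·ΔH3K79me2·
ΔH3K27ac + N(0, 0.5) with β = (H3K27ac 0.8, H3K36me3 0.5, H3K79me2 0.4,
interaction 0.3); uncoupled genes draw adjusted p from a U(0,1) null so a
nominal fraction crosses any DEG cutoff, as in a real mild contrast.
Treatment shifts accessibility by −0.5 log2 on TF-bound enhancers and on
a 15% minority of intronic peaks (5% of peaks gain); sparse dynamics keep
the unselected background class clean, as in a mild perturbation. Where
no study value existed (sequencing depth 200k fragments/sample, background
ChIP rate, segment length distribution), values were fixed once at
desk-scale realism and are documented here rather than revisited.

One RNG stream is derived per (seed, stage, sample) via SeedSequence, so a
fixed seed gives byte-identical outputs and regenerating one stage does
not perturb another. Emitted reads reproduce the count tables exactly:
unique fragments get distinct in-bin midpoints, duplicates are added on
top at the configured rate, and the tagged-alignment TSV mirrors the
FASTQ record-for-record — which is what makes the demultiplex → dedup →
count round trip exactly testable.

What the generator does not emulate: base-call errors, adapter content,
mappability and GC biases, realistic genome sequence, spatial
autocorrelation of marks beyond the peak/background dichotomy, and
library-specific ATAC insert-size structure. Passing tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to alignment artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scale-recovery study at
20,000 bins (2 × 20 Mb chromosomes, 600 genes, depth 200k, NB dispersion
0.05), the decomposition at 100 seeded replicates per mechanism on 3,000
bins, the regression at 5,000 genes, and the hierarchical model at five
groups of 200 — sizes at which every recovery band (5% relative error on
scales, ±0.1 on coefficients, ±0.05 on posterior means) is comfortably
informative on a single CPU. The PCA-estimated accessibility classes are
attenuated toward the background marking rate by class misassignment;
the acceptance script therefore reports co-occurrence fractions both
conditioned on the true peak classes (the direct recovery) and on the
estimated classes, labeled as such.

## Known limitations

- The decomposition thresholds (τ, δ) are heuristics over medians; marks
  whose true uniform shift sits near τ (e.g. a 1.2-fold change, log2 ≈
  0.26) can legitimately classify as "none" at default settings.
- The lasso ranking is a relevance ordering under the model's linearity
  assumption, not a causal statement about chromatin writers.
- The hierarchical model assumes a shared residual σ across groups; very
  heteroscedastic groups would need a per-group scale extension.
- Slice sampling is serial per chain; at hundreds of thousands of genes a
  gradient-based sampler would be preferable. At the sizes used here the
  full posterior takes seconds.
- Interval operations assume disjoint bins and tiling segmentations (both
  validated on input); overlapping annotation would need an interval-tree
  backend.
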