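# quantchip

Quantitative analysis of barcode-multiplexed ChIP-seq (RELACS-style), built
around a study design in which mouse embryonic stem cells (mESC) and their
in vitro derived neural progenitors (NPC48h) are profiled for seven histone
modifications under control (DMSO) and DOT1L-inhibitor (EPZ5676) treatment,
together with expression and chromatin-accessibility readouts.

Classic ChIP-seq normalizes every sample to its own sequencing depth, which
silently erases genome-wide ("global") shifts of a histone mark. When
samples are barcoded and pooled into a single immunoprecipitation, the read
count allocated to each sample after demultiplexing is quantitative, and
the **global scaling factor** of mark *m* between conditions A and B is

```
s(A→B) = (chip_B / input_B) / (chip_A / input_A)
```

on genome-wide, deduplicated, mapq-filtered fragment totals, averaged
(geometrically) over all n_A x n_B replicate pairings. The package
implements, end to end and on synthetic data with known ground truth:

- **`quantchip.simulate`** — a generator for the full study: genome layout,
  per-bin negative binomial ChIP/input counts carrying configurable true
  global scale factors, barcoded reads (4 bp UMI + 8 bp sample barcode),
  expression tables linearly coupled to mark changes, a 15-state chromatin
  segmentation, and ATAC peak counts with seeded treatment effects.
- **`quantchip.relacs`** — demultiplexing, UMI deduplication, midpoint
  counting, global scaling factors and treatment retention, and per-bin
  log2 fold changes in *traditional* (depth-normalized) vs *quantitative*
  (globally rescaled) mode.
- **`quantchip.decomposition`** — MA-style summaries and a classifier that
  decides whether a global change is *locally driven* (confined to enriched
  loci) or *genome-wide driven* (uniform over peaks and background), plus
  k-means stratification of per-gene enrichment.
- **`quantchip.expression`** — `MarkExpressionModel`: an L1-regularized
  linear model of expression log2FC on the seven mark log2FCs plus the
  H3K79me2:H3K27ac interaction, with features ranked by lasso-path entry;
  OLS slopes, the φ coefficient, marker-gene ratios, promoter-peak ECDFs.
- **`quantchip.states`** — per-gene chromatin-state signatures (length 30:
  15 promoter + 15 gene-body overlap fractions) and `VaryingInterceptModel`,
  a hierarchical Bayesian model of expression change by dominant promoter
  state: `Log2FC ~ N(α[i], σ)`, `α[i] ~ N(μ′, σ′)`, `μ′ ~ N(0,1)`,
  `σ, σ′ ~ Exp(1)`, sampled by Gibbs-within-slice MCMC with split-R̂
  convergence gating.
- **`quantchip.atac`** — PCA-loading selection of treatment-responsive open
  chromatin, peak annotation with fixed precedence, enhancer fold-change
  summaries, mark co-occurrence by accessibility class, Mann–Whitney U and
  one-sided paired t-tests.

## Worked example

```python
import quantchip as qc

cfg = qc.TruthConfig(seed=1)          # defaults encode the study conditions
genome = qc.generate_genome(cfg)
exp = qc.simulate_chip_counts(genome, cfg)

est = qc.global_scale(
    exp.get(mark="H3K79me2", cell_type="mESC", treatment="DMSO"),
    exp.get(mark="H3K79me2", cell_type="mESC", treatment="DMSO", role="input"),
    exp.get(mark="H3K79me2", cell_type="NPC48h", treatment="DMSO"),
    exp.get(mark="H3K79me2", cell_type="NPC48h", treatment="DMSO", role="input"),
)
print(est.summary())

ret = qc.epz_retention(
    exp.get(mark="H3K79me2", cell_type="NPC48h", treatment="DMSO"),
    exp.get(mark="H3K79me2", cell_type="NPC48h", treatment="DMSO", role="input"),
    exp.get(mark="H3K79me2", cell_type="NPC48h", treatment="EPZ"),
    exp.get(mark="H3K79me2", cell_type="NPC48h", treatment="EPZ", role="input"),
)
print(ret.summary())
```

prints

```
Global scaling factor H3K79me2 mESC_DMSO -> NPC48h_DMSO: 3.89 (log2 +1.958), sd 0.0361, N = 4 pairwise comparisons
H3K79me2: 65.0% +/- 0.5% of the NPC48h_DMSO level (N = 4)
```

The configured truth is a 3.9-fold genome-wide H3K79me2 gain during
differentiation and 64.2% retention under DOT1L inhibition in NPC48h: both
are recovered from the simulated counts by the pairwise input-normalized
ratio estimator, with the spread over the four replicate pairings shown as
the standard deviation.

A command-line interface mirrors the library
(`quantchip simulate | demux | scale | decompose | cluster | model | states
| atac | run-all`); `quantchip run-all --seed 1 --out run/` executes every
stage on a synthetic dataset and writes JSON/TSV results stamped with the
configuration hash.

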