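# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the `admeta` pipeline. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Preprocessing model

Microarray-like ("intensity") studies follow the chain background
correction → quantile normalization → log2 → probe collapse → outlier
screen.

- **Background correction** (`min_shift`) subtracts each array's 5th
  percentile and floors at 1 so the log2 transform stays defined. It is a
  deliberately simple location correction, not an RMA-style convolution
  model; it only applies to linear-scale input, and studies already on
  the log2 scale skip it.
- **Quantile normalization** maps each array's order statistics onto the
  across-array mean of sorted values. Ties within an array receive the
  mean of their tied quantile means, which keeps the operation
  permutation-invariant and idempotent on identical columns.
- **Probe collapse** runs in three fixed steps: duplicate probe-id rows
  are averaged element-wise; probes without a gene symbol are dropped;
  among probes sharing a symbol the probe with the highest mean
  expression across arrays is kept. "Highest expression" is interpreted
  as highest mean (not highest single value), with probe id as the final
  deterministic tie-break. A probe annotated with several symbols keeps
  the first listed symbol; the event is logged.
- **Outlier screen.** Three per-array metrics: mean Euclidean distance to
  the other arrays, the Kolmogorov–Smirnov statistic of the array against
  the pooled value distribution, and mean absolute deviation from the
  row-median pseudo-reference array. A metric flags an array when its
  value exceeds the Tukey upper fence (Q3 + 1.5·IQR) across arrays, and an
  array flagged by any metric is omitted. With fewer than four arrays no
  exclusion is attempted. The three metrics mirror the standard
  distance/distribution/MA categories of array-quality screening while
  being fully specified and deterministic.
- **Screen placement.** By default the screen runs on the collapsed,
  normalized matrix. Quantile normalization, however, equalizes array
  distributions and therefore erases exactly the global-shift artifacts
  the screen looks for; the `outliers_first` switch screens the log2
  matrix *before* normalization, and the demo configuration enables it.
  Which placement a study used is rarely reported in practice, so both
  are supported and recorded in the run config echo.

Count ("RNA-seq-like") studies are transformed to
log2-CPM = log2((count + 0.5)/(libsize + 1) × 10⁶) and re-enter the
common path as derived log2 matrices. Read-level QC, trimming, alignment
and counting are upstream of this package. Differential testing on
log-CPM with the moderated t is a voom-like simplification without
precision weights: adequate for the moderately deep, moderately dispersed
synthetic libraries generated here, less so for very shallow libraries
with dominant mean–variance trends.

## Differential expression

Per gene: logFC = mean(case) − mean(control) on the log2 scale, pooled
variance s²_g on d_g = n₁+n₂−2 df. The default empirical-Bayes moderation
models s²_g ~ s₀²·F(d_g, d₀) and estimates (d₀, s₀²) by method of moments
on {log s²_g} (digamma/trigamma moment equations; the trigamma inverse is
solved by Newton iteration). The moderated variance is
s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g) and t = logFC / (s̃·√(1/n₁+1/n₂)) with
d₀+d_g df. When the excess variance of log s²_g is non-positive, d₀ = ∞
and all genes share s₀² (normal reference distribution); when the prior
cannot be estimated at all (fewer than two positive variances) the test
falls back to the plain pooled t with a logged warning. Degenerate genes
with zero variance and zero logFC get p = 1, not NaN. The equal-variance
pooled t (not Welch) matches the moderation framework. DEG calls use the
strict rule BH-adjusted p < α (default 0.05).

## Meta-analysis

The sample-level **dysregulation event** — expression strictly above the
within-comparison control-group median — is this package's
operationalization; published event-based meta-analyses typically do not
define the sample-level rule. The median split is nonparametric and
direction-free: down-regulated genes produce negative log odds ratios
without special casing, consistent with reading sign(θ̂) as the pooled
direction. A configurable offset (k·MAD above the median) is available;
the default offset is 0.

From the 2×2 table, θ = ln(ad/bc) and v = 1/a+1/b+1/c+1/d, with the
Haldane–Anscombe +0.5 applied to every cell whenever any cell is zero.
With an even control group and continuous values, exactly half the
controls lie above their own median, so c ≈ n_ctrl/2 by construction and
the case event rate carries the signal.

Pooling is DerSimonian–Laird: Q = Σwᵢ(θᵢ−θ_F)² with fixed weights
wᵢ = 1/vᵢ, τ² = max(0, (Q−(k−1))/(Σwᵢ−Σwᵢ²/Σwᵢ)), random weights
w*ᵢ = 1/(vᵢ+τ²), SE = (Σw*ᵢ)^(−1/2), two-sided normal p. A single effect
passes through with τ² = 0. Genes enter the meta-analysis when at least
`min_reports` (default 2, hard minimum 2) comparisons called them DEGs;
by default each gene pools exactly the comparisons that reported it
(the `use_all_comparisons` switch pools every comparison measuring it,
since the convention is not universal). BH runs across all pooled genes
in one batch.

Subgroup analyses map free-text brain-region labels onto the
cytology-based branches (cerebellum; putamen/nucleus accumbens;
amygdala/hippocampus; cerebral neocortex) by keyword; unmapped regions go
to an `other_branch` that is excluded with a warning. BH is applied
within each subgroup, and concordance between two subgroups counts
shared significant symbols split into concordant-up, concordant-down and
discordant.

## Enrichment

Over-representation uses the upper hypergeometric tail
P(X ≥ k | N, K, n) via the survival function (log-space internally).
The background universe defaults to measured genes ∩ genes annotated to
any set — approximating the annotated-universe convention of standard ORA
tools — and is configurable. Sets are restricted to the universe and kept
when their restricted size lies in [3, 1000]; both guards are
configurable. The universe choice moves N, K and n but never the overlap
k.

## Network module

Edges at confidence ≥ 0.9 (inclusive; 0.9 names the lower bound of the
highest-confidence bracket on the 0–1 scale, 900 on the 0–1000 scale)
with both endpoints among the significant meta-genes form the PPIN.
The degree distribution is summarized by OLS of log10(count) on
log10(degree) over nonzero-count degree classes, reported as
count ≈ C·degree^b with R².

DIAMOnD runs in its uniform variant (seed weight α = 1): the candidate
score is the hypergeometric tail of drawing k neighbors from N nodes
partitioned into the s₀ module nodes and the rest, evaluated at the
candidate's k_s links into the module. Ties are broken by higher k_s,
then lower k, then lexicographic symbol, which totally orders candidates
and makes the trace deterministic. The stopping rule is a fixed iteration
budget (default 200, the reference default) or candidate exhaustion.

Hubs are module nodes with degree strictly above the empirical 95th
percentile (linear interpolation) of module-node degrees, measured on the
module-induced subgraph by default ("nodes within the module that had a
high degree"); a switch measures degrees in the full PPIN instead. If no
node exceeds the threshold (ties at the top, or all degrees equal), the
maximum-degree set is returned flagged `degenerate`.

## Synthetic-data model

The generators are pure functions of (config, seed).

- **Cohort.** A shared universe of `n_genes` symbols; fractions
  `frac_up`/`frac_down` (defaults 0.05/0.05) planted with per-study
  effect δ (`effect_size`, default 1.5). Intensity studies draw
  value = baseline + group·(±δ) + N(0, σ²) on the log2 scale (baselines
  uniform on [6, 12], σ default 0.5); a configured fraction of genes
  carries two probes with independent noise, ~2% of probes are
  unannotated junk, and optional outlier arrays receive a global +4σ
  shift. Count studies draw negative-binomial counts with mean
  libsize·π_g·exp(±δ·case) and variance μ + 0.1·μ² (library sizes
  0.8–1.2M); δ acts as a natural-log fold there. One in five studies is
  count-based by default, echoing the microarray/RNA-seq mix of typical
  evidence-synthesis cohorts. Defaults match the conditions the recovery
  checks are stated under (5 studies, 10+10 samples, δ = 1.5, σ = 0.5).
- **Interactome.** A Barabási–Albert backbone (m = 2) plus a planted
  module whose internal pairs are additionally wired with probability
  0.6; edge confidences are drawn in [0.9, 1] so the confidence filter
  passes everything unless `low_scores` is set. Seed genes are a subset
  of the module with association p drawn log-uniformly in [10⁻¹², 10⁻⁸],
  all surviving the inclusive p ≤ 10⁻⁸ genome-wide filter.
- **Gene sets.** Enriched sets draw 80% of members from non-null genes;
  background sets are uniform draws.

What the generator does **not** model: batch effects, probe-sequence
biases, correlated genes, library-size confounding, single-cell
structure, annotation errors. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
noise models, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Monte-Carlo checks use 20 replicates of 300-gene cohorts (recovery, null
false-discovery, enrichment) and 500-node interactomes (module
precision); the end-to-end demo uses 400 genes and 400 nodes. These sizes
give stable rates (hundreds of planted genes per check) while keeping any
single check in the seconds range. All TSV output renders floats at six
significant digits with fixed column order and documented row sorts, so
identical configs and seeds reproduce files byte for byte; round-trips
through TSV preserve values to the printed precision. Sub-seeds for the
pipeline's generators are drawn from a single `numpy` Generator seeded by
the run seed.

## Known limitations

- The dysregulation-event rule and the three QC metrics are this
  package's own fully specified stand-ins for conventions that published
  workflows delegate to external tools without documenting; results on
  real data will differ in detail from any specific tool chain.
- The count path does not model mean–variance precision weights or
  GLM-based dispersion estimation.
- Event tables from even, continuous control groups make the control
  event rate nearly constant (≈ 1/2), so θ̂ is driven by the case rate;
  heavily tied (low-resolution) data would weaken the median-split rule.
- The meta-analysis pools only genes that recur as DEGs, so single-study
  discoveries are invisible by design.
- Region-to-branch mapping is keyword-based; ambiguous labels should be
  curated by the user.
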