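# Methods

This note documents the statistical models, default parameters and design
choices behind `nanovax`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Synthetic RNA-seq generator

Each gene *g* has group means (μ_control, μ_post) and SD σ; every count is
drawn as `round(max(Normal(μ_group, σ), 0))`. Truncation precedes rounding
so the output is guaranteed non-negative; rounding makes the matrix
integer so that count-based tests apply downstream. The default study
design is 300 genes × (5 Control + 5 Post-Vaccination) samples with

| gene class | n | μ_control → μ_post | σ |
|---|---|---|---|
| background | 226 | 100 → 100 | 15 |
| designed_up | 30 | 100 → 300 | 15 |
| designed_down | 30 | 100 → 30 | 15 |
| marker | 14 | 50 → 200 | 15 |

Effect sizes are deliberately large — roughly 10–13 within-group SDs of the
group-mean difference — so that the designed signal is fully detectable at
FDR < 0.05 with n = 5 per group. That is the regime the benchmark is built
for: the "full recovery" result is a property of these study conditions,
not a general power claim. The B/T/plasma-cell markers (CD19, MS4A1; CD3D,
CD8A, CD4; IGHG1, IGHM, PRDM1) are the canonical compartment markers;
memory-T (IL7R, CCR7), cytotoxic (GZMB, PRF1) and epithelial (EPCAM,
KRT18) markers are package defaults and configurable.

What the generator does **not** emulate: library-size variation between
samples (all size factors ≈ 1), overdispersion beyond what truncation and
rounding induce (a normal with σ = 15 at mean 100 is only mildly
overdispersed relative to Poisson), gene–gene correlation, batch effects,
and realistic dynamic range. Passing tests therefore certify the
pipeline's mechanics and calibration on idealized data, not performance on
real RNA-seq.

One master seed drives everything; each stage (simulation, bootstrap,
sampling, splitting, training, GA) derives its own child stream from the
master seed and a stage tag, so stages are independently reproducible.

## Negative-binomial Wald differential expression

The engine is intentionally minimal and fully specified:

* **Size factors** — median-of-ratios over genes with no zero count,
  rescaled to geometric mean 1 (the median is taken in ratio space). With
  no all-positive gene it falls back to total-count ratios with a warning.
* **Dispersion** — per-gene method of moments on normalized counts:
  pooled within-group variance s² (ddof 1, pooled over both groups) versus
  the grand mean μ̄, `α = max((s² − μ̄)/μ̄², 10⁻⁸)`. Equivalently the
  modelled variance is `max(s², μ̄)`: empirical when overdispersed,
  floored at Poisson otherwise. No shrinkage toward a trend.
* **Wald test** — `log2FC = log2((μ̂_post + ½)/(μ̂_ctrl + ½))` on
  normalized group means (pseudocount ½ stabilizes zeros); the standard
  error comes from the delta method with `Var(μ̂_g) = (μ̂_g + αμ̂_g²)/n_g`
  per group, floored at 10⁻⁶; the statistic is referred to the standard
  normal, two-sided; Benjamini–Hochberg step-up adjusts across all genes.

**Calibration.** On negative-binomial null genes (μ = 100, α = 0.02,
5 + 5 samples) the empirical size at the 0.05 level is ≈ 0.07 (0.073 at
the frozen calibration seed; 0.07–0.09 across seeds). The mild
anti-conservativeness is the expected small-sample effect of a
normal-reference Wald statistic with an estimated variance (a t-like
statistic with ~8 df); it shrinks with group size and does not affect the
benchmark conclusions, where the designed effects are enormous relative
to this miscalibration. Users analysing real small-n data should prefer a
full-featured DE package; this engine's virtue is that every step is
transparent and oracle-testable.

Deliberate omissions (non-goals): LFC shrinkage, Cook's outlier
filtering, independent filtering, dispersion-trend shrinkage,
multi-factor designs. Because of these omissions results are close to but
not numerically identical with DESeq2-class tools.

## Immune risk index

`R_c = ΔAUC_c × n_c`, where n_c counts the compartment's markers with
padj < 0.05 and log2FC > 0. ΔAUC_c (targeted-minus-untargeted cumulative
activation, simulation units) is an input: the shipped values (Ig 1.4,
T 1.2, Tmem 1.1, TC 0.9, B 0.8, EP 0.6) are synthetic fixtures chosen to
preserve the reference ordering of compartment activation, not mechanistic
outputs. The bootstrap resamples the compartment's marker genes with
replacement (same size, B = 1000, percentile interval at 95%). We multiply
ΔAUC into the resampled count rather than weighting the resampling itself;
with few markers per compartment the bootstrap distribution is discrete
and the CI collapses to the point estimate when all markers are
(or none is) significant — single-marker compartments are flagged as
degenerate. The index is semi-quantitative: it ranks compartments, it does
not estimate a biological rate.

## LNP scoring function and dataset

`ΔAUC(f) = −0.01(size − 90)² − 0.02·charge² + 0.5·PEG + 1.5·targeting + ε`
with ε ~ N(0, 0.1²). PEG enters in mol% units (0.1–0.5), so its
contribution is 0.05–0.25 and the global optimum over the box is 1.75 at
(90 nm, 0 mV, 0.5 mol%, targeted) — verified against grid search at
1 nm / 0.5 mV / 0.01 mol% resolution. Note the function is monotone
increasing in PEG, so "moderate PEGylation is best" is *not* a property of
this objective; an optimizer on this landscape should push PEG toward 0.5.

The 100-row training set uses a Latin hypercube over the three continuous
dimensions (exactly one point per n-quantile bin per marginal) with a
balanced, shuffled targeting assignment; plain uniform sampling is
available as an option. Noise SD 0.1 is tiny against the objective's range
over the box (≈ [−38, 1.75]), which is why the surrogate's held-out R²
exceeds 0.9 easily — the benchmark checks the pipeline, not a hard
learning problem.

## Random-forest surrogate

scikit-learn `RandomForestRegressor`, 500 trees, min leaf 2, unlimited
depth, fixed feature order (size, charge, peg, targeting), seeded. Metrics
are computed on the held-out 20% only: RMSE and R² (the coefficient of
determination, which can be negative; undefined and reported as missing
for a zero-variance validation target). Feature importances are impurity
based (mean decrease in node impurity), normalized to sum 1. On the
default dataset the **size** term dominates the importances — its quadratic
term spans ≈ 36 score units across the box versus ≤ 2 for charge and
≤ 0.2 for PEG — so size carries most of the explainable variance by
construction. Prediction variability is profiled by refitting on B = 500
bootstrap resamples (lighter 100-tree forests; only the spread matters)
and reporting per-row mean/SD/percentile CI.

## Genetic algorithm

Real-coded GA over the box: population 50, 100 generations, crossover
probability 0.8, mutation probability 0.2 — with the remaining operator
details fixed as follows where the high-level recipe left them open:

* tournament selection, k = 3, without replacement, ties to the first
  drawn;
* crossover: per-gene arithmetic blend with an independent
  β ~ Uniform(0,1) per continuous gene; targeting bits swap with
  probability ½; children clipped to bounds;
* mutation (per individual with probability 0.2): Gaussian perturbation
  with SD = 5% of each gene's range, clipped; targeting flips with
  probability 0.1;
* elitism: the single best individual survives each generation, making
  the best-so-far trace non-decreasing;
* the top-10 is a hall of fame over all evaluated individuals,
  deduplicated on a rounded genome (0.1 nm / 0.1 mV / 0.01 mol%) —
  robust to the final generation's sampling noise.

On the noiseless analytic objective the GA reaches within 0.02 of the
1.75 optimum for 10/10 seeds. On the forest surrogate it converges to
targeted, near-neutral, ≈ 85–92 nm candidates; the exact plateau it lands
on varies by a few nm between seeds because a forest fitted to 100 points
is piecewise constant near the optimum, and its top predicted values
(≈ 1.1–1.5) sit below 1.75 for the same reason. PEG convergence is
surrogate-driven and not meaningful on this landscape (see the scoring
note above).

## DEG-set comparison

Universes are intersected before anything else; DEG sets use strict
thresholds (|log2FC| > 0.5, padj < 0.1 by default). Overlap significance
is a one-sided Fisher exact test (enrichment) on the 2×2 membership
table; direction concordance is the percentage of shared DEGs with equal
log2FC sign; Pearson r is computed over the shared DEGs' paired log2FCs
(reported missing below 2 genes or for constant vectors). Computing r
over the whole shared universe instead is exposed as an option.

## Numerical and testing notes

* Dispersion floor 10⁻⁸, SE floor 10⁻⁶, fold-change pseudocount ½.
* BH is implemented directly (reverse cumulative minimum of m·p/rank) and
  is cross-checked in the tests against a brute-force step-up oracle and
  statsmodels; Fisher p-values are cross-checked against exhaustive
  hypergeometric tail summation; the bootstrap CI distribution against
  exact 3³ enumeration; size factors against an independent brute-force
  median-of-ratios computation and pydeseq2.
* Test problem sizes (e.g. 2000 null genes, 100 seeds for the shift-sign
  check, B = 20 000 for the bootstrap-distribution check) were chosen to
  keep Monte-Carlo error well below the asserted margins while the whole
  suite runs in well under a minute.
* Figures are functional (labels and values) rather than styled; the
  heatmap clusters rows by average linkage on Euclidean distance of
  z-scored columns, both configurable.

## Known limitations

* The DE engine's small-sample anti-conservativeness (above).
* The generator's idealizations mean benchmark recovery rates do not
  transfer to real data.
* ΔAUC fixtures are placeholders pending real mechanistic-simulation
  outputs; risk indices inherit their units and scale.
* The surrogate's top-10 predicted ΔAUC values understate the analytic
  optimum (forest plateau effect); rankings are meaningful, magnitudes
  approximate.
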