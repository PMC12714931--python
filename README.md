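# nanovax

In-silico screening of mRNA-vaccine delivery strategies: synthetic
transcriptomics coupled to AI-guided lipid-nanoparticle (LNP) design.

mRNA vaccines stand or fall with their delivery vehicle. LNP formulations
must balance efficacy (uptake, antigen expression) against safety
(off-target immune activation), and empirically screening the
four-dimensional formulation space — particle size, surface charge,
PEGylation, targeting ligands — is slow and expensive. `nanovax`
implements a fully computational screening loop for prototyping such
designs before any experiment:

**Transcriptomics arm**

1. **Synthetic RNA-seq** — a truth-labelled count matrix emulating a
   post-vaccination study: 300 genes × 10 samples (5 Control, 5
   Post-Vaccination) with 30 designed-up genes, 30 designed-down genes and
   named immune markers (CD19/MS4A1, CD3D/CD8A/CD4, IGHG1/IGHM/PRDM1, …)
   drawn from zero-truncated, rounded normal distributions.
2. **Differential expression** — a self-contained negative-binomial Wald
   test: median-of-ratios size factors, method-of-moments dispersion
   `α = max((s² − μ̄)/μ̄², 10⁻⁸)`, delta-method standard errors under
   `Var = μ + αμ²`, and Benjamini–Hochberg FDR control.
3. **Immune risk index** — per immune compartment *c*,
   `R_c = ΔAUC_c × #{significantly upregulated markers of c}`,
   with a nonparametric bootstrap (B = 1000) percentile CI over the
   compartment's marker genes. ΔAUC is the targeted-minus-untargeted
   cumulative immune activation from upstream mechanistic simulation,
   supplied via configuration.

**Formulation arm**

4. **LNP design space** — size ∈ [50, 150] nm, charge ∈ [−10, 10] mV,
   PEG ∈ [0.1, 0.5] mol%, targeting ∈ {0, 1}, scored by

   `ΔAUC = −0.01(size − 90)² − 0.02·charge² + 0.5·PEG + 1.5·targeting + ε`,
   `ε ~ N(0, 0.1²)`;

   100 training formulations come from a Latin hypercube with balanced
   targeting.
5. **Surrogate** — a random-forest regressor (500 trees) on an 80/20
   split, reported by held-out RMSE/R², impurity importances, and
   bootstrap-refit prediction variability (B = 500).
6. **Genetic algorithm** — real-coded GA (population 50, 100 generations,
   crossover 0.8, mutation 0.2, tournament selection, elitism) maximizing
   the surrogate's prediction; returns a deduplicated top-10.

Plus **DEG-set comparison** (overlap, one-sided Fisher exact test,
direction concordance, log2FC Pearson correlation) for validating
simulated signatures against external differential-expression tables.

## Worked example

```python
import nanovax as nv

# transcriptomics arm
cfg = nv.SimConfig(seed=0)
matrix = nv.simulate_expression(nv.build_gene_catalog(cfg), cfg)
de = nv.wald_test(matrix)
truth = matrix.truth
up = truth.index[truth.gene_class == "designed_up"]
print(int(up.isin(nv.significant_up(de, 0.05)).sum()), "of", len(up), "designed-up genes recovered")

risk = nv.risk_table(nv.default_compartments(), de, seed=0)
print(risk[["n_upregulated", "delta_auc", "risk_index"]])

# formulation arm
ds = nv.sample_formulations(n=100, seed=1, noise_sd=0.1)
train, valid = nv.split_dataset(ds, seed=1)
model = nv.train_rf(train, seed=1)
print("validation R2:", round(nv.evaluate(model, valid).r2, 3))
top = nv.run_ga(model, nv.GAConfig(seed=1)).top_k
print(top.head(3).round(3))
```

prints

```
30 of 30 designed-up genes recovered
             n_upregulated  delta_auc  risk_index
compartment
Ig                       3        1.4         4.2
T                        3        1.2         3.6
Tmem                     2        1.1         2.2
TC                       2        0.9         1.8
B                        2        0.8         1.6
EP                       2        0.6         1.2
validation R2: 0.991
   rank  size_nm  charge_mV  peg_molpct  targeting  predicted_delta_auc
0     1   88.673      1.090       0.211          1                1.144
1     2   88.055      1.053       0.206          1                1.144
2     3   88.248      1.091       0.207          1                1.144
```

Every designed gene is recovered at FDR < 0.05; the plasma-cell (Ig)
compartment carries the largest off-target activation risk and the
epithelial compartment the smallest; the surrogate explains >99% of
held-out variance; and the GA converges on targeted, near-neutral
formulations close to the 90 nm size optimum.

The same pipeline is scriptable from the shell (`nanovax --help`):
subcommands `simulate-rnaseq`, `diffexpr`, `risk-index`, `simulate-lnp`,
`train-surrogate`, `optimize`, `compare-degs` and `run-all` (one YAML
config, all artifacts + figures + a JSON run report). Narrative
walk-throughs for each capability live in `examples/`.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
assumptions and their limits, all tunable parameters with defaults, and
the numerical choices made where the design was open.
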