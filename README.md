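# metnetmap

Maternal metabolome-wide association and Gaussian-graphical network mapping
for pregnancy-cohort metabolomics panels.

Studies of the intrauterine environment ask whether maternal circulating
metabolites — beyond glucose and BMI — are associated with newborn size and
adiposity. The analysis pattern is common to several large OGTT cohorts:
fasting and 1-h maternal serum panels (targeted amino acids/acylcarnitines,
conventional clinical assays, untargeted GC-MS) are normalized against
pooled-QC injections, screened per metabolite against newborn outcomes
(birthweight, sum of skinfolds, cord C-peptide) under two covariate models,
and mapped as a sparse partial-correlation network with community
structure. `metnetmap` implements that whole pipeline as a tested library
plus a seeded synthetic cohort generator with known truth, so every
estimator can be scored against what was planted.

The package is for statistical programmers and methodologists who need a
reproducible, truth-checked implementation of this analysis — either to run
on their own delimited tables or to study the operating characteristics of
the estimators.

## The statistics

**Preprocessing.** GC-MS peak areas are log2-transformed, acylcarnitines
(and 3-hydroxybutyrate) natural-log-transformed. For each metabolite a
two-part Bernoulli–Normal model is fit to the pooled-QC injections:
detection ~ Bernoulli(logit⁻¹(γ₀ + γ_batch)) and observed intensity
~ N(μ + b_batch + r·position, σ²), with Σ b_batch = 0; the fitted
b_batch + r·position is subtracted from every sample. Cells ≥ 5 SD from
the metabolite mean are blanked (inclusive boundary); samples with more
than 10 outlying metabolites per sample time are dropped; metabolites with
≥ 10% (association) or ≥ 1% (network) missingness are excluded.

**Association.** Within each ancestry stratum, OLS of the outcome on the
per-stratum standardized metabolite plus covariates — Model 1: field
center, 3 genetic PCs, MAP, age, parity, height, smoking, alcohol, newborn
sex, gestational age, storage time; Model 2 adds maternal BMI and the
glucose measurement matched to the sample time. Stratum estimates are
pooled by fixed-effect inverse variance (β = Σwᵢβᵢ/Σwᵢ, w = se⁻²), and
p-values are Benjamini–Hochberg adjusted within each
(sample time × outcome × model) family. Cord C-peptide is analyzed on the
log scale.

**Network.** Metabolites with <1% missingness are residualized on Model 2
covariates; the residual correlation matrix S feeds the graphical lasso

  max_Θ log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θᵢⱼ|,

solved by block coordinate descent (diagonal unpenalized, so λ→0 recovers
the MLE). λ is selected by a rotation information criterion: columns are
independently permuted to destroy cross-column dependence, and λ* is the
largest absolute off-diagonal correlation observed across rotations —
calibrated so independent data yield an empty graph. Edges carry partial
correlations ρᵢⱼ = −Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ); nodes are sized by −log10 of the
Model 2 nominal p; communities come from minimizing the
Reichardt–Bornholdt spin-glass Hamiltonian
H = −Σ_{i<j}[Aᵢⱼ − γkᵢkⱼ/2m]δ(σᵢ,σⱼ) by seeded simulated annealing.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (seed 2023 by default):

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_qc.py
python analysis/03_metabolite_associations.py
python analysis/04_metabolite_networks.py
python analysis/05_recovery_benchmarks.py
```

`01` writes a 1000-dyad cohort (60 metabolites, 6 planted communities, 118
true edges) under `results/cohort/` and prints its marginals — e.g.
`birthweight: mean 3410.6, sd 489.0`, matching the configured population
(3391.5 ± 485 g). `02` removes the planted batch shifts with mean absolute
error 0.022 log-units. `03` prints Table-style rows per outcome, e.g. the
planted triglyceride-like metabolite on fasting birthweight:

```
met_001: M1 82.41 (51.94–112.88, 1.15 × 10^−7) | M2 53.25 (22.80–83.70, 6.10 × 10^−4)
```

(outcome units per 1 SD of metabolite; the Model-1 → Model-2 shrinkage is
the BMI/glucose adjustment), and the planted pure-BMI marker flipping from
Model-1 significant to Model-2 null. `04` estimates the networks — on the
fasting panel: `lambda* 0.127, 75 edges, 9 communities; edge F1 vs truth
0.89, community ARI 0.78` — and exports GraphML sized per outcome. `05`
scores the estimators across replicates: edge F1 0.79 and community ARI
0.98 at n = 2000, 0.00% edges on null data, 0.00% global-null FDR calls,
planted-effect bias −1.3 g/SD.

The same pipeline runs from the command line on simulated or external CSV
tables:

```
metnetmap all --seed 7 --out results/run
metnetmap simulate --seed 7 --out results/cohort7
```

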