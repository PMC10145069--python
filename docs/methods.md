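# Methods

## The synthetic cohort generator

The generator (`metnetmap.synthetic`) emulates a multi-center pregnancy
cohort in which maternal serum metabolomics was assayed fasting and 1 h
into an OGTT, with enough of the real data's nuisance structure that the
pipeline's conditioning stages have something genuine to remove.

**Covariates.** Samples are assigned to 11 field centers; each center
draws ancestry (5 levels) from a center-specific categorical dominated by
one ancestry, because in multinational cohorts centers are ancestrally
skewed and the stratified regressions must absorb that confounding. Three
genetic PCs track ancestry (ancestry-specific means plus unit noise).
Continuous covariates use natural-unit moments typical of a pregnancy
cohort at ~28 weeks: age 29.2 (5.8) y, height 161.0 (7.1) cm, BMI 27.9
(5.1) kg/m², MAP 80.7 (7.8) mmHg, fasting glucose 4.5 (0.4) and 1-h
glucose 7.5 (1.7) mmol/L, gestational age at delivery 39.8 (1.2) wk,
storage time 10 (2) y. BMI correlates 0.3 with MAP and fasting glucose;
fasting and 1-h glucose correlate 0.5. Smoking (2.6%), alcohol (4.4%),
parity (46.7% parous) and newborn sex (50.3% male) are Bernoulli.

**Metabolite panel.** The conditional-dependence truth is a
block-structured precision matrix: within each community, pairs connect
with probability `edge_density_within` and get partial correlation
`within_partial_corr`; `n_cross_edges` bridges join communities. A
unit-diagonal precision with off-diagonals −ρ on support A is positive
definite only while ρ < 1/λmax(A); the builder diagonally loads to a
minimum eigenvalue of 0.1 and rescales so the implied covariance has unit
diagonal, and fails loudly if loading would halve the requested strength.
Defaults (p = 60, six communities of 10, density 0.4, ρ = 0.3, 6 bridges)
keep each community one cohesive connected subgraph — sparser blocks
fragment into components and then have no community structure to recover —
at a realized partial correlation of ≈ 0.2–0.3. Communities are class-
coherent (acylcarnitine-like, amino-acid-like, lipid-like, ...), matching
how metabolite networks cluster by class; assay follows class (AC/AA
targeted, a few conventional lipids, the rest GC-MS).

The 1-h panel shares the same precision matrix with a within-person
correlation of 0.5 to the fasting draw. Batch structure: samples fall into
contiguous daily batches; each batch has a per-metabolite additive shift
~ N(0, 0.4²) on the analysis (log) scale and a linear run-order drift of
0.001 per injection; pooled-QC aliquots are injected first/middle/last per
batch with 0.05 SD injection noise. Detection-limit missingness applies to
GC-MS metabolites only: half are fully detected, the rest left-censored at
a fixed quantile up to `censor_fraction` (default 8%) — so the <1%-missing
network subset is the targeted panel plus well-detected GC-MS metabolites,
as in real panels. Gross outliers can be planted at chosen z-offsets.

**Outcomes.** Birthweight 3391.5 (485) g, SSF 12.5 (2.7) mm, cord
C-peptide 0.3 (0.2) nmol/L. C-peptide is log-normal (moments matched on
the natural scale) so its analysis-scale model is linear. Each outcome is
covariate effects (per-SD: e.g. BMI → +110 g birthweight, gestational age
→ +160 g) plus planted per-SD metabolite effects plus Gaussian noise whose
SD is chosen so the realized total variance matches the configured
moments; the implied signal R² (≈ 0.15–0.25 by default) is recorded in the
truth file. One default metabolite (`met_002`) loads 0.6 SD/SD on BMI with
no direct outcome effect — the purely mediated case that should be
Model-1 significant and Model-2 null.

**What the generator does not emulate.** Spectra, retention times, peak
deconvolution, isomer curation; longitudinal sampling; non-Gaussian
metabolite tails; missingness mechanisms other than left-censoring;
heterogeneous effects across ancestry (the truth is one coefficient per
metabolite). Passing tests therefore demonstrate correct statistical
machinery under a faithful-but-idealized data model, not robustness to
every failure mode of real GC-MS data.

## Preprocessing

Transforms: GC-MS → log2, acylcarnitines → natural log, everything else
untouched (a 3-hydroxybutyrate-style conventional metabolite can be added
to the natural-log list by id). The QC model is fit per metabolite by
factorized maximum likelihood: the detection part reduces to per-batch
detection rates, the intensity part to least squares on sum-to-zero batch
contrasts plus run position. When the drift term is unidentifiable
(a single QC position per batch) it is set to 0; when QC intensities are
constant (σ̂ = 0) normalization falls back to batch means with a warning;
a metabolite whose QC record is entirely missing in some batch is returned
unnormalized and flagged. Outlier means/SDs are computed once on the
post-normalization matrix (single pass, not iterated; a config flag can
move the rule before normalization is deliberately not offered — the
single-pass convention is fixed and documented). Boundaries: ≥ 5 SD
inclusive, > 10 outliers per sample exclusive, missingness thresholds
strict (<10%, <1%). Missing values are never imputed in preprocessing.

## Association

Per-metabolite, per-stratum OLS with the metabolite standardized to the
stratum's complete cases, so betas are outcome units per 1 SD and
comparable across metabolites. Field center enters as indicator contrasts;
center levels emptied by complete-case restriction alias the intercept and
are dropped greedily (one aggregated warning). The scan core is a compact
closed-form OLS (β, se, t-p) — a metabolome-wide scan runs thousands of
small regressions and per-fit model-object overhead dominates otherwise —
cross-checked against statsmodels in the tests. Strata with n ≤ p + 6 are
omitted and recorded by absence. Pooling is fixed-effect inverse variance;
the pooled p is two-sided normal. BH adjustment is the p·m/rank step-up
with a cumulative-minimum pass, applied within (time × outcome × model),
cross-checked against statsmodels and a direct-formula oracle. The
alternative pooling — one regression with ancestry indicators — was
considered and rejected as the default because stratification also frees
all covariate slopes to differ by ancestry; the fixed-effect pool of
stratum betas is the conservative reading of a per-ancestry analysis.

## Network estimation

Residualization fits each metabolite on Model 2 covariates over samples
complete on all covariates; remaining missing cells (below 1% by
construction of the network set) are mean-imputed per metabolite before
the fit; residual columns are standardized, and (near-)zero-variance
columns (residual variance ≤ 1e-10) are flagged and excluded. The
covariance handed to the graphical lasso is therefore a correlation
matrix; an unstandardized variant would only rescale Θ rows/columns and
leave partial correlations unchanged.

The graphical lasso penalizes off-diagonals only, keeping the λ = 0 limit
equal to inv(S) (returned in closed form at exactly λ = 0) and preserving
the partial-correlation reading of Θ. The solver is classic block
coordinate descent on the working covariance W with a warm-started
coordinate-wise soft-threshold lasso per column; convergence when the mean
absolute off-diagonal change of W per sweep falls below tol (default 1e-4)
times the mean |S| off-diagonal. Every fit reports a KKT certificate from
W = Θ⁻¹: on the support |Wᵢⱼ − Sᵢⱼ − λ·sign(Θᵢⱼ)|, off it
max(|Wᵢⱼ − Sᵢⱼ| − λ, 0); converged fits certify below 10·tol. Edge
support uses the relative zero threshold |Θᵢⱼ| > 1e-6 · max diag Θ. The
penalty path is log-spaced over [0.05·λmax, λmax] with λmax = max |Sᵢⱼ|
(the smallest penalty giving the empty graph), 30 points.

The rotation information criterion is implemented operationally as
column-wise permutation: each of 20 rotations permutes sample order
independently within every column, and λ* is the maximum absolute
off-diagonal of the permuted correlation matrices, snapped up to the
nearest path value. Permutation is a rotation-to-null surrogate that
preserves margins exactly while destroying all cross-column dependence; by
construction independent data then select a penalty at or above their own
largest spurious correlation, yielding (near-)empty graphs. Rotation count
and the max statistic are configurable.

Spin-glass communities minimize the Reichardt–Bornholdt Hamiltonian with
the configuration null model at γ = 1 on the unweighted support graph,
per connected component (each with its own 2m), by single-spin Metropolis
annealing: geometric cooling 1.0 → 0.01 at factor 0.99, node-count sweeps
per temperature, followed by a zero-temperature greedy polish to a local
minimum; isolated nodes are singletons; labels are relabeled consecutively
in order of first appearance, deterministic given the seed. On all small
test graphs the annealed partition attains the exhaustively enumerated
minimum. Community count is capped at 25 (warn and continue).

One graph is fit per sample time; the three outcomes re-skin the same
topology with their own −log10(nominal Model-2 p) node sizes, exported as
one GraphML per time (per-outcome size attributes) plus a CSV edge list.
p = 0 caps node size at 50; a missing p gives size 0, both with warnings.

## Orchestration and determinism

A single JSON config (round-tripping losslessly) plus one integer seed
drives everything; the seed fans out to per-stage 31-bit seeds via
`numpy.random.SeedSequence`. All artifacts are CSV/JSON/GraphML with fixed
float formatting; the manifest checksums (SHA-256) every file, so two runs
under one seed are verifiably bit-identical (stage timings live outside
the checksummed set). Any stage failure aborts naming the stage and leaves
partial outputs under a FAILED marker.

## Problem sizes used by the tests and benchmarks

Chosen as the smallest sizes at which each property is statistically
sharp: solver-oracle agreement on 25 random correlation instances,
p ∈ {3..8}; graph/community recovery on 5 cohorts of n = 2000, p = 40
(4 communities of 10, density 0.4); rotation-criterion null behavior on 50
replicates of n = 500, p = 20; FDR control on 50 global-null cohorts of
500 metabolites at n = 300; effect recovery and Model-2 attenuation on 100
cohorts of n = 2000; determinism on a full n = 300, p = 16 double run. The
analysis drivers use n = 1000, p = 60 with reduced replicate counts and
print the same measurements.

## Known limitations

- The glasso inner loop is pure Python/numpy; p in the few hundreds is
  comfortable, p ≫ 1000 is not the target regime.
- Fixed-effect pooling assumes a common true beta across ancestries; no
  heterogeneity statistics are computed.
- The RIC permutation surrogate controls the maximal null correlation, a
  conservative (family-wise-style) calibration; true edges weaker than the
  null maximum are not recoverable at the selected penalty.
- Spin-glass annealing is exact only empirically; for graphs beyond the
  exhaustively checkable sizes the polish guarantees a local, not global,
  Hamiltonian minimum.
- Left-censored cells in the network set are mean-imputed (affects < 1% of
  cells by construction); association fits are complete-case throughout.
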