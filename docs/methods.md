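# Methods

This note documents the models, defaults and numerical choices behind
`tmekit`, and what the synthetic cohorts do and do not establish.

## Synthetic cohort generator (`tmekit.synth`)

**Composition.** Patient-level subpopulation frequencies follow a
logistic-normal model: latent log-abundances z = μ + e with
e ~ N(0, σ²R), where R is block-exchangeable — correlation ρ
(`within_module_corr`, default 0.8) between subpopulations of the same
planted module, 0 between modules — and σ = `composition_noise_sd`
(default 0.1); frequencies are softmax(z) per patient. The logistic-normal
was chosen because it is simplex-valid with a tunable co-occurrence
structure; the simplex closure induces a mild negative correlation between
blocks, which is also what closure does to real compositional data.
Baseline log-abundances μ are drawn once per cohort from N(0, 0.5) so no
subpopulation dominates.

**Expression.** Gene baseline relative abundances are log-normal(0, 1),
normalized to sum to 1; library sizes are log-normal
(`libsize_log_mean` 8.5, `libsize_log_sd` 0.3, i.e. a median of ~5,000
counts per cell, typical of droplet data). A cell carrying program p has the
expected expression of p's genes multiplied by exp(effect); the default
effect ln 4 is a strong but realistic marker fold change. Expected
expression is *not* renormalized after the boost, so the configured effect
is exactly the expected count ratio between program and background cells.
Counts are gamma-Poisson (negative binomial) with shape `nb_dispersion`
(default 2, moderate overdispersion); `poisson_limit=True` removes the
gamma stage for distributional-limit checks — note the Poisson limit is
exact marginally only when library sizes are equal.

**Survival.** Event times are exponential with rate
λ·exp(Σ βᵢ·scoreᵢ) (baseline λ = 0.1 events per time unit), censoring
independent exponential with rate `censor_rate` (default 0.05); the event
indicator is 1 iff the event precedes censoring. Exponential hazards make
the proportional-hazards assumption of the downstream Cox stages exactly
true — recovery tests therefore measure estimation quality, not robustness
to misspecification.

One integer seed governs the whole cohort through per-stage
`SeedSequence` keys, so each layer is independently reproducible.

**What the generator does not emulate:** batch effects, doublets,
ambient RNA, cell-cycle structure, overlapping programs per cell, spatial
context, and informative censoring. Passing recovery tests on these cohorts
shows the estimators are correct under their own assumptions; it does not
show robustness to the technical artifacts of real data.

## Preprocessing (`tmekit.preprocess`)

QC keeps a cell iff total UMI ≤ 50,000 (upper bound; the printed rule is
also configurable as a lower bound via `umi_min` since the direction is a
known ambiguity of this filter family), detected genes > 200 and
mitochondrial fraction < 25% (case-sensitive symbol prefix `MT-`).
Normalization is ln(1 + count/libsize·10⁴); zeros are preserved exactly.
HVG selection bins genes into 20 equal-frequency mean-expression bins and
z-scores the dispersion (variance/mean of expm1 values) within bins; genes
with exactly constant expression are excluded by an exact-range test (the
two-pass variance can leave ~1e-31 of float dust), remaining ties break by
gene symbol. Clustering delegates to scanpy: scale (cap 10) → PCA (30
components) → kNN graph (k = 15) → Leiden at each resolution, all seeded.

The marker test is a one-vs-rest two-sided Wilcoxon rank-sum computed
in-package: midranks, tie-corrected normal approximation with 0.5
continuity correction; log2FC = log2((mean expm1 in + ε)/(mean expm1 out + ε))
with ε = 1e-9; BH adjustment within each cluster's test family. Ranks and
tie-correction sums are computed once per matrix (they do not depend on the
cluster split). Clusters with fewer than 3 cells are skipped with a warning.

## Composition analytics (`tmekit.composition`)

Ro/e entries with a zero margin are reported missing (NaN), never 0, and
the table-level chi-square uses no continuity correction. For co-occurrence
modules the distance is 1 − r, not 1 − |r|: anti-correlated subpopulations
must not co-cluster. Correlation p-values are reported unadjusted and
BH-adjusted. The number of modules k is user-supplied (the analysis this
reimplements reports five without a stated criterion); `k=None` selects k ∈
[2, 10] by maximum mean silhouette on the 1 − r distance. Dominant-module
ties go to the lexicographically smallest module id.

## Program discovery (`tmekit.programs`)

Marker-set filtering follows the fixed rules (drop mitochondrial prefix,
padj ≥ 0.05, log2FC ≤ 0, expressed in ≤ 20% of cluster cells; rank by padj
then log2FC; top 200). Greedy dedup keeps the earlier set in input order
(sample, then resolution ascending) — deterministic in the absence of a
canonical keep-rule.

Consensus clustering uses each set's row of the Jaccard matrix as its
feature vector (L2-normalized, a spherical-k-means surrogate), 50 resamples
of 80% of rows, k-means per k (feasible k capped at one below the resample
size: at k ≥ resample size every row becomes its own cluster and the
consensus matrix is vacuously "clean"). The consensus entry (i, j) is the
co-clustering frequency among resamples containing both.

Model selection: PAC = mass of off-diagonal consensus entries inside
(0.1, 0.9). On cleanly separated data PAC is near zero for *every* k at or
above the true one, because the optimal k-means split of near-duplicate
profiles is itself stable — raw PAC minimization therefore over-splits.
k values within 0.05 of the minimum PAC are treated as statistically tied;
among them the k whose consensus partition (average linkage on
1 − consensus) maximizes the mean silhouette on the feature profiles wins,
with remaining ties to the smaller k. When no k achieves PAC ≤ 0.5 the
matrix is declared structureless and the smallest k is returned. Program
signatures rank genes by recurrence across member sets (retain ≥ 0.25,
cap 50; ties by symbol).

## Scoring engines (`tmekit.scoring`)

* Module score: 25 equal-frequency expression bins, 100 seeded control
  draws per signature gene without replacement within a bin (all bin genes
  when the bin is smaller); score = signature mean − pooled control mean.
* AUC activity: genes ranked per unit with seeded random tie-breaking; area
  under the recovery curve within the top 5% of the ranking, normalized by
  the best achievable area. Invariant to monotone transformations of
  expression within a unit.
* Single-sample enrichment: rank-weighted running-sum ES with weight
  rank^0.25; this is an ssGSEA-style statistic standing in for GSVA's
  kernel-ECDF score (a per-sample set score is what downstream stages
  need); optional normalization by the overall score range.
* ULM TF activity: slope t-value of the unit's profile regressed on the
  TF's weight vector over all genes (absent targets weight 0); regulons
  with < 5 targets present are dropped. Zero-variance expression profiles
  get t = 0 by convention. Regulons of size 2–3 should be scored by mean
  expression instead of rank-ES (rank statistics are unstable at that
  size); `module_survival` uses plain marker means for the same reason.
* Chi-square specificity: Pearson statistic without continuity correction
  (so perfect separation of 20 vs 20 cells gives exactly χ² = n = 40).

## Mediators (`tmekit.mediators`)

The communication score is mean ligand (sender) × mean receptor (receiver),
complexes combined by minimum (limiting-subunit semantics); cofactors,
Hill-function kinetics and pathway pattern analysis of full communication
frameworks are deliberately not modelled — the contract is a ranked,
significance-filtered (sender, receiver, pair) weight table. Significance
comes from cluster-label permutation with p = (1 + #{null ≥ obs})/(n_perm+1),
flooring p at 1/(n_perm+1). Permutations are vectorized as one
(n_perm × cells) boolean matmul per cluster. Clusters under 50 cells are
excluded; pairs with no subunit present on a side are skipped and logged.

Ridge drug-sensitivity imputation standardizes features on training
statistics, fits per drug with penalty λ (10-fold CV over a log grid for
`alpha="cv"`), and predicts on the standardized test matrix.

## Survival (`tmekit.survival`)

KM, log-rank and Cox regression delegate to lifelines (Efron tie handling).
The maximally selected cutpoint uses the Lausen–Schumacher form: per-subject
log-rank scores aᵢ = eventᵢ − NelsonAalen(tᵢ), candidate cutoffs are
midpoints of sorted unique scores leaving ≥ minprop (default 0.1) of
patients per side, and the statistic is the high-group score sum
standardized by its permutation mean and variance. The sequential
(hypergeometric-variance) standardization was rejected: in small samples its
variance shrinks for unbalanced splits and the maximum drifts to extreme
cutoffs even under perfect separation.

The risk model runs univariate Cox per regulon (keep p < 0.05), then an
L1 Cox path (scikit-survival Coxnet, scores standardized internally,
coefficients returned on the raw scale) with the penalty chosen at the
maximum summed held-out Breslow partial log-likelihood over 10 folds —
i.e. the CV-deviance minimum, not the 1-SE rule; the choice is configurable
via `alpha`. An empty stage-1 survivor set returns an empty model with an
explicit status rather than an error.

Median stratification assigns scores equal to the median to the low-risk
group. Time-dependent ROC is the IPCW cumulative-case/dynamic-control
estimator: cases weighted by 1/G(Tᵢ⁻), controls by 1/G(t), with G the
Kaplan–Meier censoring survival; with no censoring it reduces exactly to
pair counting. ROC horizons are a required user parameter in the same time
unit as the records (no default is asserted). Infiltration correlations use
Pearson r with t-based p and star coding (* < 0.05, ** < 0.01, *** < 0.001).

## Pipeline and problem sizes

`run_pipeline` executes simulate → qc → cluster → modules → programs →
score → communicate → survival → riskmodel → drugs, writing plain-text
artifacts and a manifest with per-stage seeds and SHA-256 checksums. The
default cohort (80 patients, 20 subpopulations, 800 cells over 8
pseudo-samples, 400 genes, 3 programs) is sized so a full run completes in
well under a minute while still exercising every stage; recovery-grade
experiments in the test suite use larger dedicated cohorts (200 patients /
30 subpopulations for module recovery; 3,000 cells / 10 samples / 5×60-gene
programs for program recovery; n = 600 with 20 candidate regulons for the
risk model; n = 500 with 50 replicates for the cutpoint).

## Known limitations

* Consensus-k selection is reliable when each true program retains several
  marker sets after dedup; when dedup collapses a program to a single set
  (possible with very clean, noise-free markers) its consensus signal is a
  singleton and k can be under-estimated.
* The communication model ignores cofactors and pathway aggregation beyond
  a plain sum over member pairs.
* `cluster_multires` inherits any platform-dependence of the underlying
  PCA/Leiden stack; determinism is guaranteed for a fixed environment and
  seed.
* Gene symbols are case-sensitive and never auto-mapped; identifier
  harmonization is an input-preparation concern.
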