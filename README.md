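# tmekit

Analysis toolkit for dissecting the tumor immune microenvironment (TIME) from
single-cell RNA-seq cohorts and linking its organisation to patient outcome.
It is aimed at computational biologists studying solid tumors (the built-in
synthetic cohorts emulate driver-mutant non-small-cell lung cancer) who want
a tested, scriptable re-implementation of a common analysis arc:

1. **Cell modules (CMs)** — groups of cell subpopulations whose per-patient
   frequencies co-occur. From a patient × subpopulation composition matrix
   (rows closed to 1, "unknown" cells excluded), pairwise Pearson
   correlations r across patients are tested with
   t = r·√(n−2)/√(1−r²) and clustered by Ward linkage on distance 1 − r;
   cutting the tree yields modules CM1..CMk. Each patient's **dominant
   module** is the argmax of renormalized module frequency sums.
2. **Tissue preference (Ro/e)** — the ratio of observed to expected cell
   counts, E(i,j) = row·col/grand total, with chi-square significance;
   Ro/e > 1 flags preference of a subpopulation for a patient group.
3. **Gene elements (GEs)** — recurrent cancer-cell transcriptional programs.
   Per (sample, resolution, cluster) marker sets (one-vs-rest Wilcoxon
   rank-sum, BH-adjusted, top 200 by padj then log2FC) are compared by
   Jaccard similarity J(A,B) = |A∩B|/|A∪B|, size-filtered (≥ 20 genes),
   deduplicated (J > 0.95), and consensus-clustered: resampled k-means on
   similarity profiles, number of clusters chosen by the proportion of
   ambiguous clustering (PAC) with a silhouette refinement among
   statistically tied k.
4. **Activity scoring** — expression-bin-matched module scores
   (signature mean minus bin-matched control mean), top-rank recovery AUC,
   single-sample rank-weighted enrichment (ssGSEA-style, weight rankᵅ),
   univariate-linear-model TF activity (slope t-values of expression on
   regulon weights), chi-square specificity ranking and hypergeometric
   gene-set enrichment with BH q-values.
5. **Mediators** — simplified ligand–receptor communication: score(s→r) =
   mean ligand expression in sender × mean receptor expression in receiver
   (complex subunits combined by minimum), with label-permutation p-values;
   plus weighted in/out signaling roles and ridge-regression drug-sensitivity
   imputation.
6. **Prognosis** — Kaplan–Meier, log-rank, maximally selected survival
   cutpoints (Lausen–Schumacher standardized log-rank scores), Cox HR with
   age covariate ("Worse survival" when HR > 1), and a two-stage regulon
   risk model: univariate Cox filter (p < 0.05) then L1-penalized Cox with
   10-fold cross-validated penalty. The risk score of patient j is

   RS_j = Σᵢ coefᵢ · scoreᵢⱼ

   with median stratification and IPCW time-dependent ROC validation.

A synthetic-cohort generator (`tmekit.synth`) produces all required inputs
with planted ground truth — co-occurrence blocks, overexpressed gene
programs, proportional-hazards survival — so the whole pipeline runs and is
tested without any external download.

## Worked example

Discover planted cell modules and fit a regulon risk model on a synthetic
cohort of 600 patients (3 of 20 regulons carry a true hazard effect,
β = 0.5):

```python
from tmekit.synth import (CohortConfig, generate_composition,
                          generate_regulon_scores, generate_survival)
from tmekit.composition import cooccurrence_modules
from tmekit.survival import (fit_risk_model, risk_score, stratify_median,
                             logrank, split_cohort, time_roc)

cfg = CohortConfig(seed=1, n_patients=600, n_subpops=30, n_modules=5,
                   surv_betas={f"R{i:02d}": (0.5 if i < 3 else 0.0)
                               for i in range(20)})
comp, truth = generate_composition(cfg)
partition, r, p, padj = cooccurrence_modules(comp, k=5)
print("modules:", {m: len(partition.members(m)) for m in partition.modules})

scores = generate_regulon_scores(cfg, sorted(cfg.surv_betas))
records, _ = generate_survival(scores, cfg)
train, test = split_cohort(len(records), train_frac=0.7, seed=1)
model = fit_risk_model(scores.iloc[train], records.iloc[train], seed=1)
print("selected regulons:", model.regulons)
print("coefficients:", [round(c, 3) for c in model.coefficients])

rs = risk_score(scores.iloc[test], model)
groups = stratify_median(rs)
stat, df, pval = logrank(groups.to_numpy(), records.iloc[test])
print(f"validation log-rank chi2 = {stat:.1f} (p = {pval:.2e})")
print("AUC(t):", {t: round(v, 2)
                  for t, v in time_roc(rs, records.iloc[test],
                                       horizons=[2.0, 5.0]).items()})
```

Output:

```
modules: {'CM1': 6, 'CM2': 6, 'CM3': 6, 'CM4': 6, 'CM5': 6}
selected regulons: ['R00', 'R01', 'R02']
coefficients: [0.451, 0.41, 0.566]
validation log-rank chi2 = 27.2 (p = 1.88e-07)
AUC(t): {2.0: 0.72, 5.0: 0.72}
```

The five planted 6-subpopulation co-occurrence blocks are recovered exactly;
the penalized Cox stage selects precisely the three regulons with planted
effects (coefficients near the true β = 0.5); the resulting risk score
separates held-out patients (log-rank p ≈ 2·10⁻⁷) with time-dependent AUC
well above chance.

## Command line

Every stage is available as a subcommand over a YAML config
(`tmekit simulate|qc|cluster|modules|programs|score|communicate|survival|riskmodel|drugs|run`,
flags `--config`, `--seed`, `--outdir`, `--log-level`). `tmekit run --seed 7
--outdir out/` executes the full pipeline on the default synthetic cohort and
writes plain-text artifacts (MTX counts, CSV/TSV tables, GMT signatures) plus
a `manifest.json` with the config snapshot, per-stage seeds and SHA-256
checksums of every output; identical config + seed reproduce identical
checksums.

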