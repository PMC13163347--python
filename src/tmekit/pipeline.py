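"""End-to-end orchestration on a synthetic cohort, with run provenance.

``run_pipeline`` executes the analysis stages in dependency order
(simulate -> qc -> cluster -> modules -> programs -> score -> communicate ->
survival -> riskmodel -> drugs), writing plain-text artifacts and a JSON
manifest (config snapshot, per-stage seeds, output checksums). Identical
config + seed reproduces bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp_mod
from . import io as tio
from . import mediators, preprocess, programs, scoring, survival, synth

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGES"]

STAGES = [
    "simulate",
    "qc",
    "cluster",
    "modules",
    "programs",
    "score",
    "communicate",
    "survival",
    "riskmodel",
    "drugs",
]


@dataclass
class RunConfig:
    """Flat, versioned pipeline configuration; every stage default overridable."""

    outdir: str = "tmekit_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    config_version: int = 1
    # synthetic cohort
    n_patients: int = 80
    n_subpops: int = 20
    n_modules: int = 4
    n_cells: int = 800
    n_samples: int = 8
    n_genes: int = 400
    n_programs: int = 3
    genes_per_program: int = 40
    program_effect: float = float(np.log(4.0))
    within_module_corr: float = 0.8
    composition_noise_sd: float = 0.1
    nb_dispersion: float = 2.0
    baseline_rate: float = 0.1
    censor_rate: float = 0.03
    n_regulons: int = 10
    n_active_regulons: int = 3
    regulon_beta: float = 0.5
    # qc
    umi_max: float = 50_000
    min_genes_qc: int = 25
    max_mito_frac: float = 0.25
    mito_prefix: str = "MT-"
    # cluster
    resolutions: list[float] = field(default_factory=lambda: [0.3, 0.8])
    n_pcs: int = 30
    n_neighbors: int = 15
    # modules
    module_k: int = 4
    # programs
    padj_max: float = 0.05
    min_pct: float = 0.2
    top_n_markers: int = 200
    jaccard_min_size: int = 10
    dedup_threshold: float = 0.95
    consensus_k_max: int = 6
    n_resamples: int = 20
    subsample_frac: float = 0.8
    min_recurrence: float = 0.25
    signature_top_n: int = 50
    # communicate
    lr_min_cells: int = 30
    n_perm: int = 500
    # riskmodel
    train_frac: float = 0.7
    p_uni: float = 0.05
    cv_folds: int = 5
    roc_horizons: list[float] = field(default_factory=lambda: [2.0, 5.0])
    # drugs
    n_cell_lines: int = 60
    min_shared_genes: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")


@dataclass
class RunManifest:
    """Provenance of one run: config, seeds, and checksums of every output."""

    config: dict
    package_version: str
    stage_seeds: dict[str, int] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, outdir: Path, *paths: Path) -> None:
    for p in paths:
        if p.is_dir():
            _register(manifest, outdir, *sorted(p.iterdir()))
        else:
            manifest.outputs[str(p.relative_to(outdir))] = _sha256(p)


def _cohort_config(cfg: RunConfig) -> synth.CohortConfig:
    progs = synth.default_programs(cfg.n_programs, cfg.genes_per_program, cfg.program_effect)
    betas = {f"R{i:02d}": (cfg.regulon_beta if i < cfg.n_active_regulons else 0.0) for i in range(cfg.n_regulons)}
    return synth.CohortConfig(
        n_patients=cfg.n_patients,
        n_subpops=cfg.n_subpops,
        n_modules=cfg.n_modules,
        within_module_corr=cfg.within_module_corr,
        composition_noise_sd=cfg.composition_noise_sd,
        n_genes=cfg.n_genes,
        programs=progs,
        nb_dispersion=cfg.nb_dispersion,
        surv_betas=betas,
        baseline_rate=cfg.baseline_rate,
        censor_rate=cfg.censor_rate,
        seed=cfg.seed,
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the configured stages in dependency order; halt on failure with a
    manifest recording partial completion."""
    from . import __version__

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), package_version=__version__)
    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)

    state: dict = {}
    ccfg = _cohort_config(config)
    try:
        for stage in [s for s in STAGES if s in config.stages]:
            manifest.stage_seeds[stage] = config.seed
            _STAGE_FUNCS[stage](config, ccfg, outdir, state, manifest)
            manifest.completed_stages.append(stage)
            manifest.write(manifest_path)
    finally:
        manifest.write(manifest_path)
    _register(manifest, outdir, *[p for p in sorted(outdir.iterdir()) if p.name != "manifest.json"])
    manifest.write(manifest_path)
    return manifest


# ---------------------------------------------------------------- stages


def _stage_simulate(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    comp, truth_c = synth.generate_composition(ccfg)
    meta = synth.assign_cells_to_programs(ccfg, cfg.n_cells, n_samples=cfg.n_samples)
    adata, truth_e = synth.generate_expression(ccfg, meta["state"])
    adata.obs["sample"] = meta["sample"]
    # pseudo-samples map onto the first n_samples patients
    sample_patient = {f"Smp{i:02d}": f"Pt{i:03d}" for i in range(cfg.n_samples)}
    adata.obs["patient_id"] = adata.obs["sample"].map(sample_patient)
    regulons = sorted(ccfg.surv_betas)
    scores = synth.generate_regulon_scores(ccfg, regulons)
    records, truth_s = synth.generate_survival(scores, ccfg)
    subtypes = synth.generate_subtypes(ccfg)

    comp.to_csv(outdir / "composition.csv")
    tio.write_counts(adata, outdir / "counts")
    adata.obs.rename_axis("cell_id").to_csv(outdir / "cell_meta.tsv", sep="\t")
    scores.rename_axis("patient_id").to_csv(outdir / "regulon_scores.csv")
    records.to_csv(outdir / "survival.csv")
    subtypes.rename_axis("patient_id").to_csv(outdir / "subtypes.csv")
    synth.SyntheticTruth(
        module_partition=truth_c.module_partition,
        program_membership=truth_e.program_membership,
        cell_states=truth_e.cell_states,
        true_coefficients=truth_s.true_coefficients,
    ).to_json(outdir / "truth.json")
    # a small ligand-receptor table over the simulated gene universe
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 99)))
    genes = list(adata.var_names)
    picks = rng.choice(len(genes), size=12, replace=False)
    lr = pd.DataFrame(
        {
            "pair": [f"LR{i}" for i in range(6)],
            "ligand_subunits": [genes[picks[2 * i]] for i in range(6)],
            "receptor_subunits": [genes[picks[2 * i + 1]] for i in range(6)],
        }
    )
    lr.to_csv(outdir / "lr_pairs.csv", index=False)
    state.update(adata=adata, comp=comp, scores=scores, records=records, subtypes=subtypes)


def _stage_qc(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    adata = state["adata"]
    kept = preprocess.filter_cells(
        adata,
        umi_max=cfg.umi_max,
        min_genes=cfg.min_genes_qc,
        max_mito_frac=cfg.max_mito_frac,
        mito_prefix=cfg.mito_prefix,
    )
    adata = adata[kept].copy()
    norm = preprocess.log_normalize(adata)
    pd.Series(kept).to_csv(outdir / "kept_cells.txt", index=False, header=False)
    state.update(adata=adata, norm=norm)


def _stage_cluster(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    norm = state["norm"]
    clusters = preprocess.cluster_multires(
        norm, cfg.resolutions, seed=cfg.seed, n_pcs=cfg.n_pcs, n_neighbors=cfg.n_neighbors
    )
    clusters.rename_axis("cell_id").to_csv(outdir / "clusters.tsv", sep="\t")
    markers = {
        col: preprocess.rank_markers(norm, clusters[col]) for col in clusters.columns
    }
    pd.concat(
        [m.assign(resolution=col) for col, m in markers.items()], ignore_index=True
    ).to_csv(outdir / "markers.tsv", sep="\t", index=False)
    state.update(clusters=clusters, markers=markers)


def _stage_modules(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    comp = state["comp"]
    partition, r, p, padj = comp_mod.cooccurrence_modules(comp, k=cfg.module_k)
    dominant = comp_mod.dominant_module(comp, partition)
    pd.Series(partition.assignment).rename_axis("subpopulation").rename("module").to_csv(
        outdir / "module_partition.tsv", sep="\t"
    )
    r.to_csv(outdir / "cooccurrence_r.csv")
    padj.to_csv(outdir / "cooccurrence_padj.csv")
    dominant.rename_axis("patient_id").to_csv(outdir / "dominant_module.tsv", sep="\t")
    cells = pd.DataFrame(
        {
            "patient_id": np.repeat(comp.index, 3),
            "subpop": np.tile(comp.columns[:3], len(comp)),
        }
    )
    meta = cells.merge(state["subtypes"].rename("subtype"), left_on="patient_id", right_index=True)
    roe_tbl, chi2, pval = comp_mod.roe(meta, "subpop", "subtype")
    roe_tbl.to_csv(outdir / "roe.csv")
    state.update(partition=partition, dominant=dominant)


def _stage_programs(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    markers = state["markers"]
    tables = [("cohort", float(col.split("_")[1]), tbl) for col, tbl in markers.items()]
    sets = programs.collect_marker_sets(
        tables,
        mito_prefix=cfg.mito_prefix,
        padj_max=cfg.padj_max,
        min_pct=cfg.min_pct,
        top_n=cfg.top_n_markers,
    )
    J, retained = programs.jaccard_matrix(
        sets, min_size=cfg.jaccard_min_size, dedup_threshold=cfg.dedup_threshold
    )
    progs, consensus, k, pac = programs.consensus_programs(
        J,
        k_range=range(2, cfg.consensus_k_max + 1),
        n_resamples=cfg.n_resamples,
        subsample_frac=cfg.subsample_frac,
        seed=cfg.seed,
    )
    progs = programs.program_signatures(
        progs, retained, min_recurrence=cfg.min_recurrence, top_n=cfg.signature_top_n
    )
    J.to_csv(outdir / "jaccard.csv")
    consensus[k].to_csv(outdir / "consensus.csv")
    pac.rename_axis("k").rename("pac").to_csv(outdir / "pac.csv")
    tio.write_gmt({p.program: p.signature for p in progs if p.signature}, outdir / "programs.gmt")
    state.update(progs=progs, chosen_k=k)


def _stage_score(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    norm, progs = state["norm"], state["progs"]
    sigs = {p.program: p.signature for p in progs if p.signature}
    score_df = pd.DataFrame(
        {name: scoring.module_score(norm, sig, seed=cfg.seed) for name, sig in sigs.items()}
    )
    states = programs.assign_states(score_df)
    score_df.rename_axis("cell_id").to_csv(outdir / "program_scores.csv")
    states.rename_axis("cell_id").to_csv(outdir / "cell_states.tsv", sep="\t")
    state.update(program_scores=score_df, cell_states=states)


def _stage_communicate(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    norm = state["norm"]
    pairs = tio.read_lr_pairs(outdir / "lr_pairs.csv")
    labels = state["cell_states"].reindex(norm.obs_names)
    res = mediators.lr_communication(
        norm, labels, pairs, min_cells=cfg.lr_min_cells, n_perm=cfg.n_perm, seed=cfg.seed
    )
    summary = mediators.interaction_summary(res)
    W = summary.pivot(index="sender", columns="receiver", values="strength").fillna(0.0)
    W = W.reindex(index=sorted(set(W.index) | set(W.columns)), columns=sorted(set(W.index) | set(W.columns))).fillna(0.0)
    roles = mediators.signaling_roles(W)
    res.to_csv(outdir / "communication.csv", index=False)
    summary.to_csv(outdir / "interaction_summary.csv", index=False)
    roles.rename_axis("cluster").to_csv(outdir / "signaling_roles.csv")


def _stage_survival(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    records = state["records"]
    km = survival.km_estimate(records)
    km.to_csv(outdir / "km_overall.csv", index=False)
    dominant = state["dominant"].reindex(records.index)
    if dominant.nunique() > 1:
        stat, dof, p = survival.logrank(dominant.to_numpy(), records)
    else:  # every patient dominated by the same module
        stat = dof = p = float("nan")
    pd.DataFrame([{"test": "dominant_module_logrank", "chi2": stat, "df": dof, "pvalue": p}]).to_csv(
        outdir / "survival_tests.csv", index=False
    )


def _stage_riskmodel(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    scores, records = state["scores"], state["records"]
    n = len(records)
    tr, te = survival.split_cohort(n, train_frac=cfg.train_frac, seed=cfg.seed)
    model = survival.fit_risk_model(
        scores.iloc[tr], records.iloc[tr], p_uni=cfg.p_uni, folds=cfg.cv_folds, seed=cfg.seed
    )
    model.to_json(outdir / "risk_model.json")
    rs = survival.risk_score(scores, model)
    rs.rename_axis("patient_id").to_csv(outdir / "risk_score.csv")
    groups = survival.stratify_median(rs.iloc[te])
    if model.regulons and groups.nunique() > 1:
        stat, dof, p = survival.logrank(groups.to_numpy(), records.iloc[te])
    else:
        stat = dof = p = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aucs = survival.time_roc(rs.iloc[te], records.iloc[te], cfg.roc_horizons)
    out = aucs.rename_axis("horizon").rename("auc").reset_index()
    out.to_csv(outdir / "time_roc.csv", index=False)
    pd.DataFrame([{"test": "validation_risk_group_logrank", "chi2": stat, "df": dof, "pvalue": p}]).to_csv(
        outdir / "riskmodel_tests.csv", index=False
    )
    state.update(model=model, rs=rs)


def _stage_drugs(cfg: RunConfig, ccfg, outdir: Path, state: dict, manifest) -> None:
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    genes = [f"G{g:04d}" for g in range(cfg.n_genes)]
    train_expr = pd.DataFrame(
        rng.normal(size=(cfg.n_cell_lines, len(genes))),
        index=[f"CL{i:03d}" for i in range(cfg.n_cell_lines)],
        columns=genes,
    )
    beta = np.zeros(len(genes))
    beta[:5] = 1.0
    resp = pd.DataFrame(
        {"drugA": train_expr.to_numpy() @ beta + rng.normal(scale=0.5, size=cfg.n_cell_lines)},
        index=train_expr.index,
    )
    test_expr = pd.DataFrame(
        rng.normal(size=(cfg.n_patients, len(genes))),
        index=[f"Pt{i:03d}" for i in range(cfg.n_patients)],
        columns=genes,
    )
    pred = mediators.ridge_sensitivity(
        train_expr, resp, test_expr, alpha="cv", seed=cfg.seed,
        folds=5, min_shared_genes=cfg.min_shared_genes,
    )
    pred.rename_axis("patient_id").to_csv(outdir / "predicted_sensitivity.csv")
    r, p = mediators.expr_sensitivity_correlation(test_expr[genes[0]], pred["drugA"])
    pd.DataFrame([{"gene": genes[0], "drug": "drugA", "r": r, "pvalue": p}]).to_csv(
        outdir / "sensitivity_correlation.csv", index=False
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "modules": _stage_modules,
    "programs": _stage_programs,
    "score": _stage_score,
    "communicate": _stage_communicate,
    "survival": _stage_survival,
    "riskmodel": _stage_riskmodel,
    "drugs": _stage_drugs,
}
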