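"""Synthetic tumor-microenvironment cohorts with planted ground truth.

Generates the three data layers the analysis pipeline consumes:

* patient x subpopulation composition matrices with planted co-occurrence
  blocks (logistic-normal with block covariance, closed to the simplex);
* sparse negative-binomial count matrices with planted overexpressed gene
  programs shared across pseudo-samples;
* survival records drawn from an exponential proportional-hazards model on
  planted regulon scores, with independent exponential censoring.

Every planted entity (module partition, program membership, per-cell state,
hazard coefficients) is recorded in a :class:`SyntheticTruth` so recovery
tests can compare pipeline output against the generating model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_composition",
    "generate_expression",
    "generate_survival",
    "default_programs",
    "write_cohort",
]


def default_programs(
    n_programs: int = 5, genes_per_program: int = 60, effect: float = float(np.log(4.0))
) -> list[tuple[str, list[str], float]]:
    """Disjoint gene programs over the start of the gene universe.

    Each program is ``(name, member genes, log-fold effect)``; genes are the
    synthetic symbols ``G0000, G0001, ...`` used by :func:`generate_expression`.
    """
    out = []
    for p in range(n_programs):
        genes = [f"G{g:04d}" for g in range(p * genes_per_program, (p + 1) * genes_per_program)]
        out.append((f"P{p + 1}", genes, effect))
    return out


@dataclass
class CohortConfig:
    """Parameters of the generating model.

    Composition: ``n_subpops`` subpopulations are partitioned into modules via
    ``planted_modules`` (defaults to equal-size contiguous blocks of
    ``n_modules``); latent log-abundances get a block-exchangeable Gaussian
    perturbation with marginal sd ``composition_noise_sd`` and within-block
    correlation ``within_module_corr`` before softmax closure.

    Expression: gene baseline relative abundances are log-normal; cells
    carrying a program have that program's genes scaled by ``exp(effect)``;
    counts are gamma-Poisson (negative binomial with shape ``nb_dispersion``;
    ``poisson_limit=True`` gives the dispersion-free Poisson limit) with
    log-normal library sizes.

    Survival: event times are exponential with rate
    ``baseline_rate * exp(sum beta_i * score_i)`` over ``surv_betas``;
    censoring is independent exponential with rate ``censor_rate``.
    """

    n_patients: int = 200
    subtype_labels: dict[str, float] = field(
        default_factory=lambda: {"EGFR": 0.4, "KRAS": 0.3, "ALK_ROS1": 0.2, "Other": 0.1}
    )
    n_subpops: int = 30
    n_modules: int = 5
    planted_modules: dict[str, str] | None = None
    within_module_corr: float = 0.8
    composition_noise_sd: float = 0.1
    n_genes: int = 1000
    programs: list[tuple[str, list[str], float]] = field(default_factory=default_programs)
    libsize_log_mean: float = 8.5
    libsize_log_sd: float = 0.3
    nb_dispersion: float = 2.0
    poisson_limit: bool = False
    surv_betas: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 0.1
    censor_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.subtype_labels.values()), 1.0):
            raise ValueError("subtype proportions must sum to 1")
        if not (0.0 <= self.within_module_corr < 1.0):
            raise ValueError("within_module_corr must lie in [0, 1)")
        if self.composition_noise_sd <= 0:
            raise ValueError("composition_noise_sd must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_rate <= 0 or self.censor_rate < 0:
            raise ValueError("rates must be positive (censor_rate may be 0)")
        universe = {f"G{g:04d}" for g in range(self.n_genes)}
        for name, genes, _ in self.programs:
            extra = set(genes) - universe
            if extra:
                raise ValueError(f"program {name} has genes outside the universe: {sorted(extra)[:5]}")

    # one SeedSequence per stage so stages are independently reproducible
    def _rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, _STAGES[stage])))

    def module_map(self) -> dict[str, str]:
        if self.planted_modules is not None:
            return dict(self.planted_modules)
        if self.n_modules < 2 or self.n_subpops < self.n_modules:
            raise ValueError("need at least 2 modules and n_subpops >= n_modules")
        per = int(np.ceil(self.n_subpops / self.n_modules))
        return {
            f"S{j:02d}": f"CM{j // per + 1}" for j in range(self.n_subpops)
        }


_STAGES = {"composition": 1, "expression": 2, "survival": 3, "subtype": 4, "scores": 5}


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort layer."""

    module_partition: dict[str, str] = field(default_factory=dict)
    program_membership: dict[str, str] = field(default_factory=dict)
    cell_states: dict[str, str] = field(default_factory=dict)
    true_coefficients: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def generate_composition(config: CohortConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Patient x subpopulation frequency matrix with planted co-occurrence blocks.

    Latent log-abundance ``z = mu + e`` with ``e ~ N(0, sd^2 * R)`` where R is
    block-exchangeable (``within_module_corr`` inside a planted module, 0
    between); frequencies are ``softmax(z)`` per patient, so each row sums to 1.
    """
    modules = config.module_map()
    subpops = list(modules)
    if len(subpops) < 2 or len(set(modules.values())) < 2:
        raise ValueError("need at least 2 subpopulations in at least 2 modules")
    rng = config._rng("composition")
    k = len(subpops)
    block = pd.Series(modules).to_numpy()
    same = block[:, None] == block[None, :]
    corr = np.where(same, config.within_module_corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    cov = (config.composition_noise_sd**2) * corr
    # baseline log-abundances: modest spread so no subpop dominates
    mu = rng.normal(0.0, 0.5, size=k)
    z = rng.multivariate_normal(mu, cov, size=config.n_patients, method="cholesky")
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    comp = pd.DataFrame(p, index=[f"Pt{i:03d}" for i in range(config.n_patients)], columns=subpops)
    truth = SyntheticTruth(module_partition=modules)
    return comp, truth


def assign_cells_to_programs(
    config: CohortConfig,
    n_cells: int,
    n_samples: int = 1,
    background_frac: float = 0.2,
) -> pd.DataFrame:
    """Cell metadata with pseudo-sample of origin and planted program state.

    ``background_frac`` of cells carry no program; the rest are split evenly
    across the configured programs. Deterministic given the config seed.
    """
    rng = config._rng("expression")
    names = [name for name, _, _ in config.programs]
    if names:
        states = rng.choice(
            ["background"] + names,
            size=n_cells,
            p=[background_frac] + [(1 - background_frac) / len(names)] * len(names),
        )
    else:
        states = np.full(n_cells, "background")
    samples = np.sort(rng.integers(0, n_samples, size=n_cells))
    return pd.DataFrame(
        {
            "cell_id": [f"C{i:05d}" for i in range(n_cells)],
            "sample": [f"Smp{s:02d}" for s in samples],
            "state": states,
        }
    ).set_index("cell_id")


def generate_expression(
    config: CohortConfig, cell_assignments: pd.Series | None = None, n_cells: int = 1000
) -> tuple[AnnData, SyntheticTruth]:
    """Negative-binomial counts with planted overexpressed programs.

    ``cell_assignments`` maps cell id to a program name (or ``"background"``);
    omitted, cells are assigned by :func:`assign_cells_to_programs`. Cells of
    program *p* have the expected expression of *p*'s genes multiplied by
    ``exp(effect)``. Returns cells x genes counts as an :class:`AnnData`.
    """
    if cell_assignments is None:
        cell_assignments = assign_cells_to_programs(config, n_cells)["state"]
    rng = config._rng("expression").spawn(1)[0]
    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    gene_idx = {g: i for i, g in enumerate(genes)}
    n = len(cell_assignments)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    base /= base.sum()
    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n)

    prog_boost = {}
    membership: dict[str, str] = {}
    for name, pgenes, effect in config.programs:
        idx = np.array([gene_idx[g] for g in pgenes])
        prog_boost[name] = (idx, float(np.exp(effect)))
        for g in pgenes:
            membership[g] = name

    states = np.asarray(cell_assignments)
    mu = np.outer(libsize, base)
    for name, (idx, boost) in prog_boost.items():
        mask = states == name
        if mask.any():
            mu[np.ix_(mask, idx)] *= boost

    if config.poisson_limit:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=config.nb_dispersion, scale=mu / config.nb_dispersion)
        counts = rng.poisson(lam)

    adata = AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame({"state": states}, index=list(cell_assignments.index)),
        var=pd.DataFrame(index=genes),
    )
    truth = SyntheticTruth(
        program_membership=membership,
        cell_states={c: s for c, s in zip(adata.obs_names, states)},
    )
    return adata, truth


def generate_regulon_scores(
    config: CohortConfig, regulons: list[str], n_patients: int | None = None
) -> pd.DataFrame:
    """Independent standard-normal per-patient activity scores for ``regulons``."""
    rng = config._rng("scores")
    n = n_patients or config.n_patients
    return pd.DataFrame(
        rng.normal(size=(n, len(regulons))),
        index=[f"Pt{i:03d}" for i in range(n)],
        columns=regulons,
    )


def generate_survival(
    regulon_scores: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Survival records from an exponential proportional-hazards model.

    Event time ~ Exp(rate = baseline_rate * exp(linear predictor)), censoring
    time ~ Exp(censor_rate) independently; observed time is the minimum and
    the event indicator is 1 iff the event precedes censoring.
    """
    betas = {r: config.surv_betas.get(r, 0.0) for r in regulon_scores.columns}
    lp = regulon_scores.to_numpy() @ np.array([betas[r] for r in regulon_scores.columns])
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    rng = config._rng("survival")
    rate = config.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=len(t_event))
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    age = rng.normal(65.0, 10.0, size=len(time))
    records = pd.DataFrame(
        {"time": time, "event": event, "age": age}, index=list(regulon_scores.index)
    )
    records.index.name = "patient_id"
    truth = SyntheticTruth(true_coefficients={k: float(v) for k, v in betas.items()})
    return records, truth


def generate_subtypes(config: CohortConfig) -> pd.Series:
    """Driver-mutation subtype label per patient, from configured proportions."""
    rng = config._rng("subtype")
    labels = list(config.subtype_labels)
    probs = np.array([config.subtype_labels[l] for l in labels], dtype=float)
    draw = rng.choice(labels, size=config.n_patients, p=probs / probs.sum())
    return pd.Series(draw, index=[f"Pt{i:03d}" for i in range(config.n_patients)], name="subtype")


def write_cohort(outdir: str | Path, config: CohortConfig, n_cells: int = 1000) -> dict[str, Path]:
    """Generate all layers and write them as plain-text artifacts.

    Writes 10x-style MTX triplet, cell-metadata TSV, composition CSV, regulon
    score CSV, survival CSV and a truth JSON; returns the path map.
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp, truth_c = generate_composition(config)
    meta = assign_cells_to_programs(config, n_cells)
    adata, truth_e = generate_expression(config, meta["state"])
    adata.obs["sample"] = meta["sample"]
    regulons = sorted(config.surv_betas) or [f"R{i:02d}" for i in range(10)]
    scores = generate_regulon_scores(config, regulons)
    records, truth_s = generate_survival(scores, config)
    subtypes = generate_subtypes(config)

    paths = {
        "composition": outdir / "composition.csv",
        "counts": outdir / "counts",
        "cell_meta": outdir / "cell_meta.tsv",
        "regulon_scores": outdir / "regulon_scores.csv",
        "survival": outdir / "survival.csv",
        "subtypes": outdir / "subtypes.csv",
        "truth": outdir / "truth.json",
    }
    comp.to_csv(paths["composition"])
    tio.write_counts(adata, paths["counts"])
    adata.obs.rename_axis("cell_id").to_csv(paths["cell_meta"], sep="\t")
    scores.rename_axis("patient_id").to_csv(paths["regulon_scores"])
    records.to_csv(paths["survival"])
    subtypes.rename_axis("patient_id").to_csv(paths["subtypes"])
    truth = SyntheticTruth(
        module_partition=truth_c.module_partition,
        program_membership=truth_e.program_membership,
        cell_states=truth_e.cell_states,
        true_coefficients=truth_s.true_coefficients,
    )
    truth.to_json(paths["truth"])
    return paths
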