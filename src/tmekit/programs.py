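"""Gene-element (meta-program) discovery from multi-resolution cluster markers.

Marker gene sets collected per (sample, resolution, cluster) are compared by
Jaccard similarity, deduplicated, and consensus-clustered (resampled k-means
on similarity profiles with PAC model selection) into recurrent transcriptional
programs. Per-cell program states and CNV aggregation by state round out the
module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "MarkerSet",
    "ProgramSet",
    "discover_programs",
    "collect_marker_sets",
    "jaccard_matrix",
    "consensus_programs",
    "program_signatures",
    "assign_states",
    "aggregate_cnv",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """Ordered marker gene list of one (sample, resolution, cluster)."""

    sample: str
    resolution: float
    cluster: str
    genes: list[str]

    @property
    def id(self) -> str:
        return f"{self.sample}|res{self.resolution:g}|{self.cluster}"


@dataclass
class ProgramSet:
    """One consensus program (gene element): member marker sets + signature."""

    program: str
    member_ids: list[str]
    signature: list[str] = field(default_factory=list)
    consensus_score: float = float("nan")


def discover_programs(
    adata,
    sample_col: str,
    resolutions: list[float] = (0.2, 0.5, 1.0),
    seed: int = 0,
    min_cells: int = 50,
    k_range: range = range(2, 21),
    n_resamples: int = 50,
    min_set_size: int = 20,
    signature_top_n: int = 50,
    min_recurrence: float = 0.25,
):
    """Meta-program discovery from raw counts, end to end.

    Per sample (samples with fewer than ``min_cells`` cells are excluded):
    log-normalize, cluster at every resolution, call rank-sum markers. The
    per-(sample, resolution, cluster) marker sets are filtered and ranked
    (:func:`collect_marker_sets`), compared by Jaccard similarity with
    size-filter and dedup (:func:`jaccard_matrix`), consensus-clustered with
    PAC-selected k (:func:`consensus_programs`) and given recurrence
    signatures (:func:`program_signatures`).

    Returns ``(programs, chosen k, PAC per k, retained marker sets)``.
    """
    from . import preprocess

    tables = []
    for sample, idx in adata.obs.groupby(sample_col, observed=True).groups.items():
        if len(idx) < min_cells:
            logger.info("sample %s excluded (fewer than %d cells)", sample, min_cells)
            continue
        sub = adata[idx].copy()
        norm = preprocess.log_normalize(sub)
        clusters = preprocess.cluster_multires(norm, list(resolutions), seed=seed)
        for col in clusters.columns:
            if clusters[col].nunique() < 2:
                continue
            res = float(col.split("_", 1)[1])
            tables.append((str(sample), res, preprocess.rank_markers(norm, clusters[col])))
    sets = collect_marker_sets(tables)
    J, retained = jaccard_matrix(sets, min_size=min_set_size)
    progs, _, k, pac = consensus_programs(
        J, k_range=k_range, n_resamples=n_resamples, seed=seed
    )
    progs = program_signatures(
        progs, retained, min_recurrence=min_recurrence, top_n=signature_top_n
    )
    return progs, k, pac, retained


def collect_marker_sets(
    marker_tables: list[tuple[str, float, pd.DataFrame]],
    mito_prefix: str = "MT-",
    padj_max: float = 0.05,
    min_pct: float = 0.2,
    top_n: int = 200,
) -> list[MarkerSet]:
    """Filtered, ranked marker gene sets per (sample, resolution, cluster).

    ``marker_tables`` holds ``(sample, resolution, marker table)`` triples as
    produced by :func:`tmekit.preprocess.rank_markers`. Per cluster:
    mitochondrial-prefixed genes, ``padj >= padj_max``, ``log2fc <= 0`` and
    genes expressed in ``<= min_pct`` of the cluster's cells are dropped; the
    survivors are ranked by (padj ascending, log2fc descending) and truncated
    to ``top_n``. Clusters left empty are dropped with a log entry.
    """
    out: list[MarkerSet] = []
    for sample, res, tbl in marker_tables:
        for cluster, sub in tbl.groupby("cluster", sort=True):
            keep = sub[
                (~sub["gene"].astype(str).str.startswith(mito_prefix))
                & (sub["padj"] < padj_max)
                & (sub["log2fc"] > 0)
                & (sub["pct_in"] > min_pct)
            ]
            if keep.empty:
                logger.info("empty marker set dropped: %s res%g cluster %s", sample, res, cluster)
                continue
            ranked = keep.sort_values(
                ["padj", "log2fc", "gene"], ascending=[True, False, True], kind="mergesort"
            )
            genes = ranked["gene"].astype(str).drop_duplicates().head(top_n).tolist()
            out.append(MarkerSet(sample=str(sample), resolution=float(res), cluster=str(cluster), genes=genes))
    return out


def jaccard_matrix(
    sets: list[MarkerSet], min_size: int = 20, dedup_threshold: float = 0.95
) -> tuple[pd.DataFrame, list[MarkerSet]]:
    """Jaccard similarity matrix over size-filtered, deduplicated marker sets.

    Sets with fewer than ``min_size`` genes are removed first; remaining sets
    are deduplicated greedily in input order (a set is dropped when its
    Jaccard similarity with any earlier retained set exceeds
    ``dedup_threshold``). Returns the symmetric unit-diagonal matrix over
    survivors plus the surviving sets.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 marker sets")
    sized = [s for s in sets if len(s.genes) >= min_size]
    retained: list[MarkerSet] = []
    retained_sets: list[set[str]] = []
    for s in sized:
        g = set(s.genes)
        if any(len(g & h) / len(g | h) > dedup_threshold for h in retained_sets):
            continue
        retained.append(s)
        retained_sets.append(g)
    if not retained:
        raise ValueError("all marker sets removed by size filter / dedup")
    genes = sorted(set().union(*retained_sets))
    gi = {g: i for i, g in enumerate(genes)}
    M = np.zeros((len(retained), len(genes)), dtype=float)
    for i, g in enumerate(retained_sets):
        M[i, [gi[x] for x in g]] = 1.0
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    J = inter / union
    ids = [s.id for s in retained]
    return pd.DataFrame(J, index=ids, columns=ids), retained


def _cut_consensus(C: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage partition of 1 - consensus into k clusters."""
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _profile_silhouette(feats: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of a partition on the (k-independent) feature profiles.

    Singleton clusters contribute 0 (no within-cluster distance to compare);
    a single-cluster partition scores -inf.
    """
    if len(np.unique(labels)) < 2:
        return -np.inf
    D = np.linalg.norm(feats[:, None, :] - feats[None, :, :], axis=2)
    n = len(labels)
    sil = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == l].mean() for l in np.unique(labels) if l != labels[i])
        denom = max(a, b)
        sil[i] = (b - a) / denom if denom > 0 else 0.0
    return float(sil.mean())


def consensus_programs(
    similarity: pd.DataFrame,
    k_range: range = range(2, 21),
    n_resamples: int = 50,
    subsample_frac: float = 0.8,
    seed: int = 0,
    spherical: bool = True,
    pac_window: tuple[float, float] = (0.1, 0.9),
    pac_ambiguous: float = 0.5,
    stability_margin: float = 0.05,
) -> tuple[list[ProgramSet], dict[int, pd.DataFrame], int, pd.Series]:
    """Consensus clustering of marker sets into programs with automatic k.

    Each set's row of the Jaccard matrix is its feature vector (L2-normalized
    when ``spherical``). For each k, ``n_resamples`` random row subsamples are
    k-means clustered and the consensus matrix records how often two sets
    co-cluster among the resamples containing both. k is chosen by minimum
    proportion of ambiguous clustering (PAC: consensus mass inside
    ``pac_window``). PAC values within ``stability_margin`` of the minimum are
    treated as indistinguishable (on cleanly separated data every k at or
    above the true one yields near-zero PAC, since the optimal split of
    near-duplicate profiles is itself stable); within that stable set the k
    whose consensus partition maximizes the mean silhouette on the feature
    profiles wins, remaining ties to the smaller k. When no k
    reaches PAC ``<= pac_ambiguous`` the matrix is declared structureless and
    the smallest k is returned. The final partition cuts average-linkage
    clustering of ``1 - consensus`` at the chosen k.

    Returns ``(programs, consensus matrix per k, chosen k, PAC per k)``.
    """
    A = similarity.to_numpy()
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T) or not np.allclose(np.diag(A), 1.0):
        raise ValueError("similarity must be symmetric with unit diagonal")
    n = A.shape[0]
    feats = A.copy()
    if spherical:
        norms = np.linalg.norm(feats, axis=1, keepdims=True)
        feats = feats / np.where(norms > 0, norms, 1.0)
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))
    # k must stay below the resample size, else every resampled row gets its
    # own k-means cluster and the consensus matrix is trivially empty
    ks = [k for k in k_range if 2 <= k <= min(n - 1, m - 1)]
    if list(k_range) != ks:
        warnings.warn("k_range truncated to the feasible window [2, min(n, subsample size) - 1]")
    if not ks:
        raise ValueError("no feasible k in k_range")
    draws = [rng.permutation(n)[:m] for _ in range(n_resamples)]
    kmeans_seeds = rng.integers(0, 2**31 - 1, size=(len(ks), n_resamples))

    consensus: dict[int, pd.DataFrame] = {}
    pac = {}
    lo, hi = pac_window
    for ki, k in enumerate(ks):
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for ri, idx in enumerate(draws):
            if k >= len(idx):
                continue
            lab = KMeans(
                n_clusters=k, n_init=3, random_state=int(kmeans_seeds[ki, ri])
            ).fit_predict(feats[idx])
            ind = np.zeros((len(idx), k))
            ind[np.arange(len(idx)), lab] = 1.0
            co[np.ix_(idx, idx)] += ind @ ind.T
            both[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(both > 0, co / both, 0.0)
        np.fill_diagonal(C, 1.0)
        consensus[k] = pd.DataFrame(C, index=similarity.index, columns=similarity.columns)
        iu = np.triu_indices(n, 1)
        vals = C[iu]
        pac[k] = float(np.mean((vals > lo) & (vals < hi)))
    pac_s = pd.Series(pac).sort_index()
    if pac_s.min() > pac_ambiguous:
        best_k = min(ks)  # structureless: no stable clustering at any k
    else:
        stable = [k for k in ks if pac_s[k] <= pac_s.min() + stability_margin]
        best_k, best_sil = stable[0], -np.inf
        for k in stable:
            lab = _cut_consensus(consensus[k].to_numpy(), k)
            sil = _profile_silhouette(feats, lab)
            if sil > best_sil + 1e-12:
                best_k, best_sil = k, sil
    labels = _cut_consensus(consensus[best_k].to_numpy(), best_k)
    remap: dict[int, str] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = f"GE{len(remap) + 1}"
    C = consensus[best_k].to_numpy()
    programs = []
    for name in sorted(set(remap.values()), key=lambda s: int(s[2:])):
        member_idx = [i for i, l in enumerate(labels) if remap[l] == name]
        block = C[np.ix_(member_idx, member_idx)]
        score = float(block[np.triu_indices(len(member_idx), 1)].mean()) if len(member_idx) > 1 else 1.0
        programs.append(
            ProgramSet(
                program=name,
                member_ids=[similarity.index[i] for i in member_idx],
                consensus_score=score,
            )
        )
    return programs, consensus, best_k, pac_s


def program_signatures(
    programs: list[ProgramSet],
    sets: list[MarkerSet],
    min_recurrence: float = 0.25,
    top_n: int = 50,
) -> list[ProgramSet]:
    """Recurrence-based signature genes per program.

    Genes are ranked by the fraction of the program's member sets containing
    them; genes with recurrence ``>= min_recurrence`` are retained (ties by
    gene symbol), capped at ``top_n``. Programs left with an empty signature
    are flagged with a warning.
    """
    if not programs:
        raise ValueError("no programs")
    by_id = {s.id: set(s.genes) for s in sets}
    out = []
    for prog in programs:
        members = [by_id[i] for i in prog.member_ids]
        counts: dict[str, int] = {}
        for g in set().union(*members):
            counts[g] = sum(g in m for m in members)
        rec = pd.Series(counts, dtype=float) / len(members)
        ranked = rec[rec >= min_recurrence].sort_index().sort_values(ascending=False, kind="mergesort")
        sig = ranked.head(top_n).index.tolist()
        if not sig:
            warnings.warn(f"program {prog.program} has an empty signature")
        out.append(
            ProgramSet(
                program=prog.program,
                member_ids=list(prog.member_ids),
                signature=sig,
                consensus_score=prog.consensus_score,
            )
        )
    return out


def assign_states(scores: pd.DataFrame) -> pd.Series:
    """Per-cell program state: argmax score, ties to the smallest program id."""
    if scores.isna().all(axis=1).any():
        raise ValueError("cells with all-missing scores")
    ordered = scores[sorted(scores.columns)]
    return ordered.idxmax(axis=1).rename("state")


def aggregate_cnv(
    cnv: pd.DataFrame, states: pd.Series, top_n: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean copy-number signal per gene per program state.

    ``cnv`` is genes x cells, centered at 0 (positive = amplification,
    negative = deletion). Returns the genes x states mean matrix and a table
    of the ``top_n`` most amplified and deleted genes per state. States with
    no cells are skipped.
    """
    if not np.isfinite(cnv.to_numpy()).all():
        raise ValueError("CNV values must be finite")
    states = states.reindex(cnv.columns)
    if states.isna().any():
        raise ValueError("state labels must cover all cells")
    means = {}
    for s in sorted(states.unique()):
        cells = states[states == s].index
        if len(cells) == 0:
            continue
        means[s] = cnv[cells].mean(axis=1)
    mean_df = pd.DataFrame(means)
    rows = []
    for s in mean_df.columns:
        col = mean_df[s].sort_values(kind="mergesort")
        for g in col.index[-top_n:][::-1]:
            rows.append({"state": s, "gene": g, "mean_cnv": col[g], "direction": "amplified"})
        for g in col.index[:top_n]:
            rows.append({"state": s, "gene": g, "mean_cnv": col[g], "direction": "deleted"})
    return mean_df, pd.DataFrame(rows)
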