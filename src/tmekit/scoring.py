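"""Signature and activity scoring engines.

Implements the scoring primitives the analysis needs on cells or bulk
samples: expression-bin-matched module scores, top-rank AUC activity,
single-sample rank-weighted enrichment, univariate-linear-model TF activity,
chi-square specificity ranking and hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "module_score",
    "auc_score",
    "ssgsea_score",
    "ulm_activity",
    "tf_specificity_rank",
    "hypergeom_enrich",
]


def _as_frame(data) -> pd.DataFrame:
    """Units x genes DataFrame from AnnData or DataFrame input."""
    if isinstance(data, AnnData):
        X = data.X
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        return pd.DataFrame(X, index=data.obs_names, columns=data.var_names)
    return data


def module_score(
    data,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-matched signature score per unit (cell or sample).

    Genes are binned into ``n_bins`` equal-frequency bins of mean expression;
    for every signature gene, ``n_ctrl`` control genes are drawn from its bin
    (without replacement within the bin where possible). The score is the mean
    expression of the signature genes minus the mean over the pooled control
    draws, per unit. Warns when fewer than half the signature is present;
    raises when none of it is.
    """
    df = _as_frame(data)
    present = [g for g in dict.fromkeys(gene_set) if g in df.columns]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if len(present) < 0.5 * len(set(gene_set)):
        warnings.warn("fewer than 50% of signature genes present")
    rng = np.random.default_rng(seed)
    avg = df.mean(axis=0)
    order = avg.rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(order)), labels=False, duplicates="drop")
    ctrl_pool: list[str] = []
    for g in present:
        bin_genes = bins.index[bins == bins[g]]
        take = min(n_ctrl, len(bin_genes))
        ctrl_pool.extend(rng.choice(bin_genes, size=take, replace=False))
    score = df[present].mean(axis=1) - df[ctrl_pool].mean(axis=1)
    return score.rename("module_score")


def auc_score(
    data, gene_set: list[str], top_frac: float = 0.05, seed: int = 0
) -> pd.Series:
    """Top-rank recovery AUC of a gene set per unit, in [0, 1].

    Per unit, genes are ranked by decreasing expression (ties broken by a
    seeded random permutation); the area under the recovery curve of set
    genes within the top ``top_frac`` of the ranking is normalized by its
    maximum (all recoverable set genes at the very top).
    """
    df = _as_frame(data)
    n_genes = df.shape[1]
    m = int(np.floor(top_frac * n_genes))
    if m < 2:
        raise ValueError("top_frac * n_genes must be at least 2")
    in_set = df.columns.isin(set(gene_set))
    if in_set.sum() > n_genes:
        raise ValueError("set larger than the gene universe")
    s_max = min(int(in_set.sum()), m)
    if s_max == 0:
        raise ValueError("no set gene present in the matrix")
    max_area = float(np.minimum(np.arange(1, m + 1), s_max).sum())
    rng = np.random.default_rng(seed)
    X = df.to_numpy()
    out = np.empty(df.shape[0])
    for i in range(df.shape[0]):
        perm = rng.permutation(n_genes)
        order = perm[np.argsort(-X[i, perm], kind="stable")]
        hits = in_set[order[:m]]
        out[i] = hits.cumsum().sum() / max_area
    return pd.Series(out, index=df.index, name="auc")


def ssgsea_score(
    data,
    gene_sets: dict[str, list[str]] | list[str],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample rank-weighted enrichment score per (unit, gene set).

    Per unit, genes are ordered by decreasing expression; the score is the
    sum over ranking positions of the difference between the weighted in-set
    ECDF (weights ``rank^alpha``, with rank n for the top gene) and the
    uniform out-of-set ECDF. With ``normalize=True`` scores are divided by
    the overall score range across the result matrix.
    """
    df = _as_frame(data)
    if isinstance(gene_sets, list):
        gene_sets = {"set": gene_sets}
    n = df.shape[1]
    if n < 2:
        raise ValueError("degenerate single-gene universe")
    X = df.to_numpy()
    ranks = stats.rankdata(X, axis=1)  # ascending: top gene has rank n
    out = pd.DataFrame(index=df.index, columns=list(gene_sets), dtype=float)
    col_in = {name: df.columns.isin(set(gs)) for name, gs in gene_sets.items()}
    for name, mask in col_in.items():
        if mask.sum() < 2:
            raise ValueError(f"gene set {name!r} overlaps fewer than 2 genes")
    order = np.argsort(-X, axis=1, kind="stable")
    for name, mask in col_in.items():
        n_out = n - int(mask.sum())
        for i in range(X.shape[0]):
            o = order[i]
            in_run = mask[o]
            w = np.where(in_run, np.abs(ranks[i, o]) ** alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_run) / n_out
            out.loc[df.index[i], name] = float(np.sum(p_in - p_out))
    if normalize:
        rng_ = out.to_numpy().max() - out.to_numpy().min()
        if rng_ > 0:
            out = out / rng_
    return out


def ulm_activity(expr: pd.DataFrame, network: pd.DataFrame, min_targets: int = 5) -> pd.DataFrame:
    """TF activity per unit by univariate linear regression on regulon weights.

    ``expr`` is genes x units; ``network`` has columns (tf, target, weight).
    For each TF, the unit's expression profile is regressed on the TF's
    weight vector over all genes (absent targets get weight 0); the activity
    is the slope t-value. TFs with fewer than ``min_targets`` targets present
    in the expression matrix are dropped with a warning.
    """
    dup = network.duplicated(subset=["tf", "target"])
    if dup.any():
        raise ValueError("duplicate (tf, target) pairs in the network")
    genes = expr.index
    n = len(genes)
    tfs, cols = [], []
    for tf, sub in network.groupby("tf", sort=True):
        w = pd.Series(0.0, index=genes)
        hit = sub[sub["target"].isin(genes)]
        if len(hit) < min_targets:
            warnings.warn(f"TF {tf!r} has fewer than {min_targets} targets present; dropped")
            continue
        w.loc[hit["target"].to_numpy()] = hit["weight"].to_numpy()
        if w.std(ddof=0) == 0:
            raise ValueError(f"zero-variance weight vector for TF {tf!r}")
        tfs.append(tf)
        cols.append(w.to_numpy())
    if not tfs:
        raise ValueError("no TF with enough targets")
    W = np.column_stack(cols)  # genes x TFs
    Y = expr.to_numpy()  # genes x units
    Wc = W - W.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    wn = np.linalg.norm(Wc, axis=0)
    yn = np.linalg.norm(Yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Wc.T @ Yc) / np.outer(wn, yn)
    r = np.where(np.isfinite(r), r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return pd.DataFrame(t, index=tfs, columns=expr.columns)


def tf_specificity_rank(high_counts: pd.DataFrame, total_counts: pd.DataFrame) -> pd.DataFrame:
    """Rank TFs by chi-square specificity of high-activity calls across groups.

    ``high_counts`` and ``total_counts`` are TF x group tables of
    high-activity cell counts and total cell counts. Per TF a Pearson
    chi-square (no continuity correction) is computed on the group x
    {high, low} table; TFs are returned sorted by statistic descending.
    TFs with a zero margin are skipped.
    """
    rows = []
    for tf in high_counts.index:
        high = high_counts.loc[tf].to_numpy(dtype=float)
        low = total_counts.loc[tf].to_numpy(dtype=float) - high
        tab = np.vstack([high, low])
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        rows.append({"tf": tf, "chi2": float(chi2), "pvalue": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values("chi2", ascending=False, kind="mergesort").reset_index(drop=True)


def hypergeom_enrich(
    query: list[str],
    universe: list[str],
    collections: dict[str, list[str]],
    p_max: float = 0.05,
    q_max: float = 0.2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set against collections.

    Per collection set: overlap k of the query with the set (both intersected
    with the universe), ``p = P(X >= k)`` for X hypergeometric(|universe|,
    |set|, |query|); BH q-values across sets. Rows are retained iff
    ``p < p_max`` and ``q < q_max``, sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    if set(query) - uni:
        raise ValueError("query contains genes outside the universe")
    rows = []
    for name, gs in collections.items():
        s = set(gs) & uni
        if not s:
            continue
        k = len(q & s)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))
        rows.append({"set": name, "overlap": k, "set_size": len(s), "pvalue": min(p, 1.0)})
    tbl = pd.DataFrame(rows)
    if tbl.empty:
        return tbl
    tbl["qvalue"] = multipletests(tbl["pvalue"], method="fdr_bh")[1]
    keep = tbl[(tbl["pvalue"] < p_max) & (tbl["qvalue"] < q_max)]
    return keep.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
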