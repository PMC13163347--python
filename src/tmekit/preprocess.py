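"""QC filtering, normalization, variable-gene selection, clustering, markers.

Operates on cells x genes :class:`~anndata.AnnData` objects (sparse or
dense). Graph clustering is delegated to scanpy (PCA -> kNN -> Leiden); the
rank-sum marker test is computed in-package with midranks, tie-corrected
variance and continuity correction so it is exactly reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.special import ndtr
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_cells",
    "log_normalize",
    "select_hvg",
    "cluster_multires",
    "rank_markers",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def filter_cells(
    adata: AnnData,
    umi_max: float = 50_000,
    umi_min: float = 0,
    min_genes: int = 200,
    max_mito_frac: float = 0.25,
    mito_prefix: str = "MT-",
) -> pd.Index:
    """Cell ids passing the QC rules.

    A cell is kept iff ``umi_min <= total UMI <= umi_max``, detected genes
    ``> min_genes`` and mitochondrial fraction ``< max_mito_frac``.
    Mitochondrial genes are identified by a case-sensitive symbol prefix.
    The UMI rule is an upper bound by default (doublet guard); set ``umi_min``
    to additionally require a floor.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    if umi_max <= 0 or min_genes <= 0 or max_mito_frac <= 0:
        raise ValueError("QC thresholds must be positive")
    X = adata.X
    total = np.ravel(X.sum(axis=1)).astype(float)
    if sp.issparse(X):
        n_genes = np.ravel((X > 0).sum(axis=1))
    else:
        n_genes = (np.asarray(X) > 0).sum(axis=1)
    mito = adata.var_names.str.startswith(mito_prefix)
    mito_sum = np.ravel(X[:, np.where(mito)[0]].sum(axis=1)) if mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_sum / total, 0.0)
    keep = (
        (total <= umi_max)
        & (total >= umi_min)
        & (n_genes > min_genes)
        & (mito_frac < max_mito_frac)
    )
    return adata.obs_names[keep]


def log_normalize(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Library-size normalization: ``ln(1 + count / libsize * scale)``.

    Returns a new AnnData; zeros stay zero, so sparsity is preserved.
    """
    libsize = np.ravel(adata.X.sum(axis=1)).astype(float)
    if np.any(libsize <= 0):
        raise ValueError("zero library size: run filter_cells first")
    out = adata.copy()
    if sp.issparse(out.X):
        X = out.X.tocsr().astype(float)
        X = sp.diags(scale / libsize) @ X
        X.data = np.log1p(X.data)
        out.X = X
    else:
        out.X = np.log1p(np.asarray(out.X, dtype=float) / libsize[:, None] * scale)
    return out


def select_hvg(adata: AnnData, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned standardized dispersion.

    On log-normalized data: per gene, mean and dispersion (variance/mean) of
    ``expm1`` values; genes are binned into ``n_bins`` equal-frequency bins of
    mean expression and dispersion is z-scored within each bin. Ties are
    broken by gene symbol (ascending) for determinism; genes with zero
    dispersion are never selected before any positive-dispersion gene.
    """
    if n > adata.n_vars:
        raise ValueError("n exceeds the number of genes")
    X = _dense(adata.X)
    vals = np.expm1(X)
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order_stat = pd.Series(mean).rank(method="first")
    bins = pd.qcut(order_stat, q=min(n_bins, adata.n_vars), labels=False, duplicates="drop")
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        mu, sd = disp[m].mean(), disp[m].std(ddof=1) if m.sum() > 1 else 0.0
        z[m] = (disp[m] - mu) / sd if sd and sd > 0 else 0.0
    # constant genes (exact zero range; var may carry float dust) never win
    constant = vals.max(axis=0) == vals.min(axis=0)
    z = np.where(constant, -np.inf, z)
    tbl = pd.DataFrame({"gene": adata.var_names, "z": z}).sort_values(
        ["z", "gene"], ascending=[False, True], kind="mergesort"
    )
    return tbl["gene"].head(n).tolist()


def cluster_multires(
    adata: AnnData,
    resolutions: list[float],
    seed: int = 0,
    n_pcs: int = 30,
    n_neighbors: int = 15,
) -> pd.DataFrame:
    """Leiden community labels at each resolution.

    PCA (``n_pcs`` components) on the normalized matrix, kNN graph
    (``n_neighbors``), then Leiden clustering per resolution. Deterministic
    given the seed. Returns one string-label column ``res_<r>`` per resolution.
    """
    import scanpy as sc

    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells")
    if any(r <= 0 for r in resolutions):
        raise ValueError("resolutions must be positive")
    if adata.n_obs <= n_neighbors:
        raise ValueError("fewer cells than the neighbors parameter")
    ad = adata.copy()
    sc.pp.scale(ad, max_value=10)
    n_comps = min(n_pcs, ad.n_obs - 1, ad.n_vars - 1)
    sc.tl.pca(ad, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(ad, n_neighbors=n_neighbors, random_state=seed)
    out = pd.DataFrame(index=ad.obs_names)
    for r in resolutions:
        key = f"res_{r:g}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            sc.tl.leiden(ad, resolution=r, key_added=key, random_state=seed, flavor="leidenalg")
        out[key] = ad.obs[key].astype(str).to_numpy()
    return out


def _tie_term(X: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tied groups."""
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        out[j] = (counts**3 - counts).sum()
    return out


def _ranksum_p(
    ranks: np.ndarray, tie_term: np.ndarray, in_mask: np.ndarray
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column (midranks, tie-corrected
    normal approximation, 0.5 continuity correction).

    ``ranks`` are midranks over all cells; ``tie_term`` the per-column
    tie-correction sums (both cluster-independent, computed once).
    """
    n = ranks.shape[0]
    n1 = int(in_mask.sum())
    n2 = n - n1
    r1 = ranks[in_mask].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    diff = u1 - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, (diff - 0.5 * np.sign(diff)) / sigma, 0.0)
    return np.minimum(2.0 * ndtr(-np.abs(z)), 1.0)


def rank_markers(
    adata: AnnData, labels: pd.Series | np.ndarray, eps: float = 1e-9
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker table on log-normalized expression.

    Per (cluster, gene): ``log2fc = log2((mean expm1 in + eps) /
    (mean expm1 out + eps))``, expressing fractions inside/outside, two-sided
    rank-sum p and BH-adjusted p (adjusted within each cluster's family).
    Clusters with fewer than 3 cells are skipped with a warning.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    clusters = sorted(labels.unique(), key=str)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    X = _dense(adata.X).astype(float)
    vals = np.expm1(X)
    ranks = rankdata(X, axis=0)
    ties = _tie_term(X)
    rows = []
    for c in clusters:
        in_mask = (labels == c).to_numpy()
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {c!r} has fewer than 3 cells; skipped")
            continue
        mean_in = vals[in_mask].mean(axis=0)
        mean_out = vals[~in_mask].mean(axis=0)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        pct_in = (X[in_mask] > 0).mean(axis=0)
        pct_out = (X[~in_mask] > 0).mean(axis=0)
        p = _ranksum_p(ranks, ties, in_mask)
        padj = multipletests(p, method="fdr_bh")[1]
        rows.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": adata.var_names,
                    "log2fc": log2fc,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "pvalue": p,
                    "padj": padj,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
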