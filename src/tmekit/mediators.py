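"""Ligand-receptor communication scoring and drug-sensitivity imputation.

Communication between cell clusters is scored as the product of the sender's
mean ligand expression and the receiver's mean receptor expression
(multi-subunit complexes combine by minimum, limiting-subunit semantics),
with significance from cluster-label permutation. Deliberately simpler than
full communication-probability models: the contract is a ranked,
significance-filtered sender -> receiver -> pair weight table.

Also: interaction count/strength summaries, weighted in/out signaling roles,
and ridge-regression drug-sensitivity imputation from bulk expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold

__all__ = [
    "LRPair",
    "lr_communication",
    "interaction_summary",
    "signaling_roles",
    "ridge_sensitivity",
    "expr_sensitivity_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class LRPair:
    """Ligand-receptor pair; multi-subunit sides hold several gene symbols."""

    name: str
    ligand: list[str]
    receptor: list[str]

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("both sides need at least one subunit")
        if len(set(self.ligand)) != len(self.ligand) or len(set(self.receptor)) != len(self.receptor):
            raise ValueError("duplicate subunits within a side")


def _expr_frame(data) -> pd.DataFrame:
    if isinstance(data, AnnData):
        X = data.X
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        return pd.DataFrame(X, index=data.obs_names, columns=data.var_names)
    return data


def lr_communication(
    data,
    labels: pd.Series | np.ndarray,
    pairs: list[LRPair],
    min_cells: int = 50,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-tested ligand-receptor scores between cell clusters.

    Complex expression is the minimum over subunit cluster means on the
    normalized matrix; ``score(sender -> receiver, pair) = ligand(sender) *
    receptor(receiver)``. p-values come from ``n_perm`` label permutations:
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` (floored at
    ``1/(n_perm+1)``). Clusters with fewer than ``min_cells`` cells are
    excluded; pairs with no subunit present on a side are skipped.
    """
    df = _expr_frame(data)
    labels = pd.Series(np.asarray(labels, dtype=object), index=df.index)
    sizes = labels.value_counts()
    clusters = sorted(sizes[sizes >= min_cells].index, key=str)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters after the min_cells filter")
    mask_cells = labels.isin(clusters).to_numpy()
    df = df.loc[mask_cells]
    labels = labels[mask_cells]

    usable: list[tuple[LRPair, list[str], list[str]]] = []
    genes_needed: set[str] = set()
    for p in pairs:
        lig = [g for g in p.ligand if g in df.columns]
        rec = [g for g in p.receptor if g in df.columns]
        if not lig or not rec:
            logger.info("pair %s skipped: no subunit present on one side", p.name)
            continue
        usable.append((p, lig, rec))
        genes_needed.update(lig + rec)
    if not usable:
        raise ValueError("no usable ligand-receptor pair")
    gene_list = sorted(genes_needed)
    X = df[gene_list].to_numpy()
    gi = {g: j for j, g in enumerate(gene_list)}
    codes = labels.map({c: i for i, c in enumerate(clusters)}).to_numpy()
    n_cells, n_cl = len(codes), len(clusters)
    counts = np.bincount(codes, minlength=n_cl).astype(float)

    onehot = np.zeros((n_cl, n_cells))
    onehot[codes, np.arange(n_cells)] = 1.0
    means = (onehot @ X) / counts[:, None]  # clusters x genes

    rng = np.random.default_rng(seed)
    perms = np.tile(codes, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    # permuted cluster means: one matmul per cluster
    perm_means = np.empty((n_perm, n_cl, X.shape[1]))
    for c in range(n_cl):
        perm_means[:, c, :] = ((perms == c).astype(float) @ X) / counts[c]

    rows = []
    for p, lig, rec in usable:
        li = [gi[g] for g in lig]
        ri = [gi[g] for g in rec]
        lig_obs = means[:, li].min(axis=1)
        rec_obs = means[:, ri].min(axis=1)
        lig_perm = perm_means[:, :, li].min(axis=2)  # n_perm x clusters
        rec_perm = perm_means[:, :, ri].min(axis=2)
        for si, s in enumerate(clusters):
            for rj, r in enumerate(clusters):
                obs = lig_obs[si] * rec_obs[rj]
                null = lig_perm[:, si] * rec_perm[:, rj]
                pval = (1.0 + np.count_nonzero(null >= obs)) / (n_perm + 1.0)
                rows.append(
                    {"sender": s, "receiver": r, "pair": p.name, "score": float(obs), "pvalue": float(pval)}
                )
    return pd.DataFrame(rows)


def interaction_summary(result: pd.DataFrame, p_max: float = 0.05) -> pd.DataFrame:
    """Per (sender, receiver): count and summed strength of significant pairs."""
    if result.empty:
        raise ValueError("empty communication result")
    sig = result[result["pvalue"] < p_max]
    base = result[["sender", "receiver"]].drop_duplicates()
    agg = (
        sig.groupby(["sender", "receiver"])
        .agg(count=("pair", "size"), strength=("score", "sum"))
        .reset_index()
    )
    out = base.merge(agg, on=["sender", "receiver"], how="left").fillna({"count": 0, "strength": 0.0})
    out["count"] = out["count"].astype(int)
    return out.sort_values(["sender", "receiver"], kind="mergesort").reset_index(drop=True)


def signaling_roles(weights: pd.DataFrame, include_self: bool = True) -> pd.DataFrame:
    """Outgoing (row sums) and incoming (column sums) signaling strength.

    ``weights`` is a square non-negative sender x receiver matrix; with
    ``include_self=False`` the diagonal is excluded from both sums.
    """
    W = weights.to_numpy(dtype=float)
    if W.shape[0] != W.shape[1] or not weights.index.equals(weights.columns):
        raise ValueError("weights must be square with matching labels")
    if (W < 0).any():
        raise ValueError("negative interaction weights")
    if not include_self:
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    return pd.DataFrame(
        {"outgoing": W.sum(axis=1), "incoming": W.sum(axis=0)}, index=weights.index
    )


def ridge_sensitivity(
    train_expr: pd.DataFrame,
    train_response: pd.DataFrame,
    test_expr: pd.DataFrame,
    alpha: float | str = "cv",
    seed: int = 0,
    folds: int = 10,
    min_shared_genes: int = 100,
    standardize: bool = True,
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Drug-response imputation by ridge regression on shared genes.

    Per drug, ``beta = argmin ||y - X beta||^2 + alpha ||beta||^2`` on the
    training cell lines; with ``alpha="cv"`` the penalty is chosen by
    ``folds``-fold cross-validation over a log grid. Features are
    standardized on training statistics (also applied to test samples).
    """
    shared = train_expr.columns.intersection(test_expr.columns)
    if len(shared) < min_shared_genes:
        raise ValueError(f"fewer than {min_shared_genes} shared genes")
    Xtr = train_expr[shared].to_numpy(dtype=float)
    Xte = test_expr[shared].to_numpy(dtype=float)
    if standardize:
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    preds = {}
    for drug in train_response.columns:
        y = train_response[drug].to_numpy(dtype=float)
        if alpha == "cv":
            if len(y) < folds:
                raise ValueError("fewer training lines than CV folds")
            cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
            model = RidgeCV(alphas=np.logspace(-3, 5, 17), cv=cv, fit_intercept=fit_intercept)
        else:
            model = Ridge(alpha=float(alpha), fit_intercept=fit_intercept, solver="cholesky")
        model.fit(Xtr, y)
        preds[drug] = model.predict(Xte)
    return pd.DataFrame(preds, index=test_expr.index)


def expr_sensitivity_correlation(
    expression: pd.Series, sensitivity: pd.Series
) -> tuple[float, float]:
    """Pearson correlation (r, t-based p) between expression and predicted
    sensitivity over shared samples; undefined (NaN) for zero variance."""
    joined = pd.concat([expression, sensitivity], axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise ValueError("need at least 4 shared samples")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
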