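"""Patient-level composition analytics.

Normalized subpopulation frequencies per patient, innate/adaptive immune
balance, Ro/e tissue-preference ratios, co-occurrence cell-module discovery
by correlation clustering, and per-patient dominant-module assignment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "composition_from_cells",
    "immune_balance",
    "roe",
    "cooccurrence_modules",
    "dominant_module",
    "ModulePartition",
]

UNKNOWN_LABEL = "unknown"


@dataclass
class ModulePartition:
    """Disjoint assignment of subpopulations to cell modules (CM1..CMk)."""

    assignment: dict[str, str]
    k: int

    def members(self, module: str) -> list[str]:
        return [s for s, m in self.assignment.items() if m == module]

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def composition_from_cells(
    cell_meta: pd.DataFrame, level: str, patient_col: str = "patient_id"
) -> pd.DataFrame:
    """Patient x subpopulation frequency matrix, rows closed to 1.

    Cells labelled ``"unknown"`` at ``level`` are excluded before closure;
    patients left with no counted cells are dropped with a warning.
    """
    counted = cell_meta[cell_meta[level].astype(str) != UNKNOWN_LABEL]
    dropped = set(cell_meta[patient_col]) - set(counted[patient_col])
    if dropped:
        warnings.warn(f"patients with only 'unknown' cells dropped: {sorted(dropped)}")
    tab = pd.crosstab(counted[patient_col], counted[level])
    comp = tab.div(tab.sum(axis=1), axis=0)
    comp.index.name = patient_col
    return comp


def immune_balance(
    cell_meta: pd.DataFrame,
    lineage_col: str = "lineage",
    patient_col: str = "patient_id",
    group_col: str | None = None,
    innate_lineages: tuple[str, ...] = ("Myeloid",),
    adaptive_lineages: tuple[str, ...] = ("T", "B"),
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-patient innate (myeloid) vs adaptive (T+B) immune proportions.

    The two proportions sum to 1 over each patient's immune cells; patients
    with no immune cells are excluded. With ``group_col``, every group pair is
    compared on the innate proportion by Welch's t-test.
    """
    lin = cell_meta[lineage_col].astype(str)
    innate = cell_meta[lin.isin(innate_lineages)].groupby(patient_col).size()
    adaptive = cell_meta[lin.isin(adaptive_lineages)].groupby(patient_col).size()
    tab = pd.DataFrame({"innate": innate, "adaptive": adaptive}).fillna(0.0)
    tab = tab[tab.sum(axis=1) > 0]
    props = tab.div(tab.sum(axis=1), axis=0)
    tests = None
    if group_col is not None:
        grp = cell_meta.drop_duplicates(patient_col).set_index(patient_col)[group_col]
        props = props.join(grp.rename("group"))
        rows = []
        for a, b in itertools.combinations(sorted(props["group"].dropna().unique()), 2):
            xa = props.loc[props["group"] == a, "innate"]
            xb = props.loc[props["group"] == b, "innate"]
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"group_a": a, "group_b": b, "t": t, "pvalue": p})
        tests = pd.DataFrame(rows)
    return props, tests


def roe(
    cell_meta: pd.DataFrame, row_level: str, col_level: str
) -> tuple[pd.DataFrame, float, float]:
    """Ratio of observed to expected cell counts (Ro/e) with chi-square p.

    ``Ro/e(i,j) = O(i,j) / E(i,j)`` with ``E = row_total * col_total / grand
    total``; values above 1 flag a preference of subpopulation *i* for group
    *j*. Entries with a zero margin are reported missing (NaN), not 0.
    Returns ``(roe matrix, chi-square statistic, p)`` for the whole table.
    """
    obs = pd.crosstab(cell_meta[row_level], cell_meta[col_level]).astype(float)
    if obs.size == 0:
        raise ValueError("empty contingency table")
    grand = obs.to_numpy().sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(expected > 0, obs.to_numpy() / expected, np.nan)
    out = pd.DataFrame(ratio, index=obs.index, columns=obs.columns)
    if min(obs.shape) < 2:
        return out, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return out, float(chi2), float(p)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    np.fill_diagonal(p, 0.0)
    return np.minimum(p, 1.0)


def cooccurrence_modules(
    comp: pd.DataFrame, k: int | None = None, linkage: str = "ward", k_max: int = 10
) -> tuple[ModulePartition, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell modules from Pearson co-occurrence of subpopulation frequencies.

    Pairwise Pearson r across patients; p from ``t = r sqrt(n-2)/sqrt(1-r^2)``
    (unadjusted and BH-adjusted); agglomerative clustering with Ward linkage
    on distance ``1 - r`` cut into ``k`` modules. ``1 - r`` (not ``1 - |r|``)
    keeps anti-correlated subpopulations apart. With ``k=None`` the cut
    maximizing mean silhouette over ``2..k_max`` is used.

    Returns ``(partition, r matrix, p matrix, BH-adjusted p matrix)``.
    """
    if comp.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    var = comp.var(axis=0)
    keep = var[var > 0].index
    if len(keep) < len(comp.columns):
        warnings.warn(f"zero-variance subpopulations excluded: {sorted(set(comp.columns) - set(keep))}")
    comp = comp[keep]
    n, m = comp.shape
    if k is not None and k > m:
        raise ValueError("k exceeds the number of clustered subpopulations")
    r = np.corrcoef(comp.to_numpy(), rowvar=False)
    p = _corr_pvalues(r, n)
    iu = np.triu_indices(m, 1)
    padj = np.ones_like(p)
    if len(iu[0]):
        adj = multipletests(p[iu], method="fdr_bh")[1]
        padj[iu] = adj
        padj[(iu[1], iu[0])] = adj
    np.fill_diagonal(padj, 0.0)

    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    if k is None:
        best, best_sil = 2, -np.inf
        for kk in range(2, min(k_max, m - 1) + 1):
            lab = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            sil = silhouette_score(dist, lab, metric="precomputed")
            if sil > best_sil + 1e-12:
                best, best_sil = kk, sil
        k = best
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # stable module ids: CM1 = module of the first column, etc.
    remap: dict[int, str] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = f"CM{len(remap) + 1}"
    partition = ModulePartition({s: remap[l] for s, l in zip(comp.columns, labels)}, k=k)
    rdf = pd.DataFrame(r, index=comp.columns, columns=comp.columns)
    pdf = pd.DataFrame(p, index=comp.columns, columns=comp.columns)
    padjdf = pd.DataFrame(padj, index=comp.columns, columns=comp.columns)
    return partition, rdf, pdf, padjdf


def dominant_module(comp: pd.DataFrame, partition: ModulePartition) -> pd.Series:
    """Dominant cell module per patient.

    Member frequencies are summed per module, renormalized across modules and
    the argmax module returned; exact ties go to the lexicographically
    smallest module id.
    """
    missing = set(comp.columns) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover columns: {sorted(missing)}")
    sums = pd.DataFrame(
        {m: comp[partition.members(m)].sum(axis=1) for m in partition.modules}
    )
    tot = sums.sum(axis=1)
    if (tot <= 0).any():
        raise ValueError("patients with all-zero module sums")
    shares = sums.div(tot, axis=0)
    # idxmax returns the first maximum; columns are sorted module ids
    return shares[sorted(shares.columns)].idxmax(axis=1).rename("dominant_module")
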