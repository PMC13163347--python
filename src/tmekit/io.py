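"""Readers and writers for the formats the pipeline exchanges.

10x-style MTX triplets and dense CSV count matrices (into AnnData), GMT gene
set collections, regulon networks, ligand-receptor pair tables and survival
CSVs. Gene symbols are case-sensitive and never auto-mapped: identifier
conversion is an input-preparation concern.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .mediators import LRPair

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "read_lr_pairs",
    "read_survival",
]


def read_counts(path: str | Path) -> AnnData:
    """Count matrix from a 10x MTX triplet directory or a dense CSV.

    MTX directories hold ``matrix.mtx`` (genes x cells), ``features.tsv`` and
    ``barcodes.tsv``; dense CSVs have genes as rows (first column = symbol)
    and cells as header columns. Returns cells x genes AnnData with symbols
    and barcodes preserved verbatim.
    """
    path = Path(path)
    if path.is_dir():
        m = scipy.io.mmread(path / "matrix.mtx")
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
        if m.shape[0] != len(features) or m.shape[1] != len(barcodes):
            raise ValueError(
                f"dimension mismatch: matrix {m.shape} vs {len(features)} features, {len(barcodes)} barcodes"
            )
        return AnnData(
            X=sp.csr_matrix(m.T),
            obs=pd.DataFrame(index=barcodes[0].astype(str)),
            var=pd.DataFrame(index=features[0].astype(str)),
        )
    df = pd.read_csv(path, index_col=0)
    return AnnData(
        X=df.to_numpy().T.astype(float),
        obs=pd.DataFrame(index=df.columns.astype(str)),
        var=pd.DataFrame(index=df.index.astype(str)),
    )


def write_counts(adata: AnnData, path: str | Path) -> None:
    """Write a cells x genes AnnData as a 10x-style MTX triplet directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(X.T))
    pd.Series(adata.var_names).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene set collection: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are dropped with a warning; empty sets are
    rejected; malformed lines are reported with their line number.
    """
    out: dict[str, list[str]] = {}
    lines = Path(path).read_text().splitlines()
    if not any(l.strip() for l in lines):
        warnings.warn(f"empty GMT file: {path}")
        return out
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {i}: expected name, description, genes")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if not genes:
            raise ValueError(f"empty gene set {name!r} at line {i}")
        dedup = list(dict.fromkeys(genes))
        if len(dedup) < len(genes):
            warnings.warn(f"duplicate genes in set {name!r} deduplicated")
        out[name] = dedup
    return out


def write_gmt(collection: dict[str, list[str]], path: str | Path, description: str = "tmekit") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in collection.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_regulons(path: str | Path) -> pd.DataFrame:
    """Regulon network CSV with columns (tf, target, weight)."""
    df = pd.read_csv(path)
    need = {"tf", "target", "weight"}
    if not need <= set(df.columns):
        raise ValueError(f"regulon CSV needs columns {sorted(need)}")
    if not np.isfinite(df["weight"]).all():
        raise ValueError("non-finite regulon weights")
    return df


def read_lr_pairs(path: str | Path) -> list[LRPair]:
    """Ligand-receptor pair CSV: (pair, ligand_subunits, receptor_subunits),
    subunits pipe-separated."""
    df = pd.read_csv(path)
    return [
        LRPair(
            name=str(r["pair"]),
            ligand=str(r["ligand_subunits"]).split("|"),
            receptor=str(r["receptor_subunits"]).split("|"),
        )
        for _, r in df.iterrows()
    ]


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival CSV indexed by patient_id with time/event (+ covariates)."""
    df = pd.read_csv(path, index_col=0)
    if not {"time", "event"} <= set(df.columns):
        raise ValueError("survival CSV needs time and event columns")
    return df
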