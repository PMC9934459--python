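"""Readers and writers for the plain-text formats the pipeline consumes.

Count matrices travel as TSV (genes x samples, header row), GCT 1.2, or MTX
triplets with companion row/column name files; gene sets as GMT; donor
metadata and result tables as TSV.  Writers mirror the dialect of the input
they are asked for.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


# ---------------------------------------------------------------- matrices
def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 file; the Description column is dropped."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        n_genes, n_samples = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_genes, n_samples):
        raise ValueError(f"GCT header promises {(n_genes, n_samples)}, file has {df.shape}")
    df.index.name = "gene"
    return df


def write_gct(df: pd.DataFrame, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        desc = [descriptions.get(g, "na") if descriptions else "na" for g in df.index]
        out.insert(0, "Description", desc)
        out.to_csv(fh, sep="\t", index_label="Name")


def read_mtx(prefix: str | Path) -> pd.DataFrame:
    """Read ``<prefix>.mtx`` with ``<prefix>.rows.txt`` / ``<prefix>.cols.txt``."""
    prefix = Path(prefix)
    mat = mmread(prefix.with_suffix(".mtx")).toarray()
    rows = Path(str(prefix) + ".rows.txt").read_text().split()
    cols = Path(str(prefix) + ".cols.txt").read_text().split()
    return pd.DataFrame(mat, index=pd.Index(rows, name="gene"), columns=cols)


def write_mtx(df: pd.DataFrame, prefix: str | Path) -> None:
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), coo_matrix(df.to_numpy()))
    Path(str(prefix) + ".rows.txt").write_text("\n".join(map(str, df.index)) + "\n")
    Path(str(prefix) + ".cols.txt").write_text("\n".join(map(str, df.columns)) + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .gct, .mtx (triplet prefix), else TSV."""
    p = Path(path)
    if p.suffix == ".gct":
        return read_gct(p)
    if p.suffix == ".mtx":
        return read_mtx(p.with_suffix(""))
    return read_counts_tsv(p)


# ---------------------------------------------------------------- gene sets
def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _desc, *genes = line.rstrip("\n").split("\t")
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------- metadata
def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "donor_id" in meta.columns:
        meta = meta.set_index("donor_id")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=meta.index.name is not None)


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene")
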