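"""Tabular file round-tripping for the pipeline artifacts.

All tables are UTF-8 TSV with a header row and "." decimals; floats are
written with 6 significant digits. Gene sets use the GMT convention
(set name, description, tab-separated member genes).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "read_edges",
    "write_edges",
    "write_sif",
    "read_gmt",
    "write_gmt",
    "read_degree_table",
]

FLOAT_FMT = "%.6g"


class ParseError(ValueError):
    """A tabular artifact failed validation."""


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix: first column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup_mask = df.index.duplicated()
    if dup_mask.any():
        pos = int(dup_mask.argmax())  # first repeated occurrence
        raise ParseError(
            f"{path}: duplicate gene id {df.index[pos]!r} (line {pos + 2})"
        )
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in header")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing/ragged values at gene {gene!r}")
    df.index.name = "gene"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "class", "batch"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    bad = set(df["class"]) - {"P", "NP"}
    if bad:
        raise ParseError(f"{path}: class labels must be P or NP, got {sorted(bad)}")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["gene_a"] >= df["gene_b"]).any():
        i = int((df["gene_a"] >= df["gene_b"]).idxmax()) + 2
        raise ParseError(f"{path}: non-canonical pair ordering (line {i})")
    if df.duplicated(subset=["gene_a", "gene_b"]).any():
        i = int(df.duplicated(subset=["gene_a", "gene_b"]).idxmax()) + 2
        raise ParseError(f"{path}: duplicate canonical pair (line {i})")
    return df


def write_edges(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_sif(df: pd.DataFrame, path: str | Path) -> None:
    """Simple interaction format; relation 'pos'/'neg' by sign of r."""
    rel = df["r"].map(lambda v: "pos" if v >= 0 else "neg") if "r" in df else "pos"
    out = pd.DataFrame({"gene_a": df["gene_a"], "relation": rel, "gene_b": df["gene_b"]})
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {lineno}: expected name, description, genes")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise ParseError(f"{path}: line {lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = set(genes)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_degree_table(path: str | Path) -> pd.DataFrame:
    """Per-gene degree pairs (columns: gene, K_NP, K_P) for direct DIFFK input."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "K_NP", "K_P"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids")
    return df
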