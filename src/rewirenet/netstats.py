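"""Network topology statistics for differential-connectivity analysis.

Given per-group co-expression edge sets, this module filters to
biomarker-incident (seed) subnetworks, computes degrees and hub genes
(mean + 2 SD rule), the differential connectivity DIFFK = k_NP - k_P on
max-normalized degrees with across-gene z-scores (|z| >= 1.96 flags a
significantly rewired gene), and a DyNet-style union network with per-node
edge rewiring scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "canonical_edges",
    "seed_subnetwork",
    "degree",
    "hubs",
    "diffk",
    "diffk_zscores",
    "union_rewiring",
]

Z_CRITICAL = 1.96


def canonical_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Validate/normalize an edge table: gene_a < gene_b, no self edges or dups."""
    df = edges.copy()
    swap = df["gene_a"] > df["gene_b"]
    if swap.any():
        a = df.loc[swap, "gene_b"].to_numpy()
        df.loc[swap, "gene_b"] = df.loc[swap, "gene_a"].to_numpy()
        df.loc[swap, "gene_a"] = a
    if (df["gene_a"] == df["gene_b"]).any():
        raise ValueError("self-edges are not allowed")
    if df.duplicated(subset=["gene_a", "gene_b"]).any():
        dup = df[df.duplicated(subset=["gene_a", "gene_b"])].iloc[0]
        raise ValueError(f"duplicate edge {dup['gene_a']}-{dup['gene_b']}")
    return df


def seed_subnetwork(edges: pd.DataFrame, seeds: list[str]) -> pd.DataFrame:
    """Edges with at least one endpoint in ``seeds``."""
    if not seeds:
        raise ValueError("seed list is empty")
    df = canonical_edges(edges)
    nodes = set(df["gene_a"]) | set(df["gene_b"])
    missing = [s for s in seeds if s not in nodes]
    if missing:
        warnings.warn(f"seed gene(s) absent from the network: {missing[:10]}", stacklevel=2)
    seedset = set(seeds)
    mask = df["gene_a"].isin(seedset) | df["gene_b"].isin(seedset)
    return df.loc[mask].reset_index(drop=True)


def degree(edges: pd.DataFrame, nodes: list[str] | None = None) -> pd.Series:
    """Incident-edge count per gene; ``nodes`` adds isolated genes with K = 0."""
    df = canonical_edges(edges)
    counts = pd.concat([df["gene_a"], df["gene_b"]]).value_counts()
    if nodes is not None:
        counts = counts.reindex(nodes, fill_value=0)
    counts.index.name = "gene"
    counts.name = "K"
    return counts.astype(int)


def hubs(K: pd.Series) -> list[str]:
    """Genes with degree above mean + 2 * SD (sample SD, n-1 denominator)."""
    if len(K) < 2:
        raise ValueError("need at least 2 genes for hub detection")
    sd = float(K.std(ddof=1))
    if sd == 0:
        return []
    cutoff = float(K.mean()) + 2.0 * sd
    return list(K.index[K > cutoff])


def diffk(K_NP: pd.Series | dict, K_P: pd.Series | dict) -> pd.DataFrame:
    """Differential connectivity over the union node set.

    Each group's degrees are standardized by that group's maximum degree,
    k = K / max(K); DIFFK = k_NP - k_P. Genes missing from one group get
    K = 0 there.
    """
    K_NP = pd.Series(K_NP, dtype=float)
    K_P = pd.Series(K_P, dtype=float)
    if len(K_NP) == 0 or len(K_P) == 0:
        raise ValueError("degree maps must be non-empty")
    genes = K_NP.index.union(K_P.index, sort=True)
    knp = K_NP.reindex(genes, fill_value=0.0)
    kp = K_P.reindex(genes, fill_value=0.0)
    if knp.max() <= 0 or kp.max() <= 0:
        raise ValueError("maximum degree must be positive in both networks")
    out = pd.DataFrame(
        {
            "gene": genes,
            "K_NP": knp.to_numpy().astype(int),
            "K_P": kp.to_numpy().astype(int),
            "k_NP": (knp / knp.max()).to_numpy(),
            "k_P": (kp / kp.max()).to_numpy(),
        }
    )
    out["diffk"] = out["k_NP"] - out["k_P"]
    return out


def diffk_zscores(records: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score the DIFFK column across genes; |z| >= 1.96 flags rewiring."""
    if len(records) < 2:
        raise ValueError("need at least 2 genes to z-score DIFFK")
    out = records.copy()
    d = out["diffk"].to_numpy(dtype=float)
    sd = float(np.std(d, ddof=ddof))
    if sd == 0:
        warnings.warn("DIFFK has zero spread; all z-scores set to 0", stacklevel=2)
        out["z"] = 0.0
    else:
        out["z"] = (d - d.mean()) / sd
    out["significant"] = np.abs(out["z"]) >= Z_CRITICAL
    return out


def union_rewiring(
    edges_P: pd.DataFrame, edges_NP: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DyNet-style central reference network and per-node rewiring scores.

    Returns the union edge table with an ``origin`` column (P, NP or both)
    and a per-node table partitioning incident edges into only-P / only-NP /
    shared with rewiring_score = (only_P + only_NP) / total incident.
    """
    p = canonical_edges(edges_P)[["gene_a", "gene_b"]]
    np_ = canonical_edges(edges_NP)[["gene_a", "gene_b"]]
    set_p = set(map(tuple, p.to_numpy()))
    set_np = set(map(tuple, np_.to_numpy()))
    rows = []
    for a, b in sorted(set_p | set_np):
        if (a, b) in set_p and (a, b) in set_np:
            origin = "both"
        elif (a, b) in set_p:
            origin = "P"
        else:
            origin = "NP"
        rows.append((a, b, origin))
    union = pd.DataFrame(rows, columns=["gene_a", "gene_b", "origin"])
    counts: dict[str, np.ndarray] = {}
    for a, b, origin in rows:
        for g in (a, b):
            c = counts.setdefault(g, np.zeros(3, dtype=int))
            c[{"P": 0, "NP": 1, "both": 2}[origin]] += 1
    rec = pd.DataFrame(
        [
            {
                "gene": g,
                "edges_only_P": int(c[0]),
                "edges_only_NP": int(c[1]),
                "edges_shared": int(c[2]),
                "rewiring_score": float((c[0] + c[1]) / c.sum()) if c.sum() else 0.0,
            }
            for g, c in sorted(counts.items())
        ]
    )
    return union, rec
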