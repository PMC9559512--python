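"""Hypergeometric over-representation analysis (ORA) with BH-FDR.

Query gene lists (e.g. genes co-expressed with a biomarker) are tested for
over-representation in user-supplied gene sets against a custom background
of expressed genes: p = P(X >= overlap) under the hypergeometric null,
adjusted across sets by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_overrep", "bh_fdr", "ora"]


def hypergeom_overrep(
    query: Iterable[str], geneset: Iterable[str], background: Iterable[str]
) -> tuple[int, float, float]:
    """Upper-tail hypergeometric test of a query list against one gene set.

    Genes outside the background are dropped from both query (with a
    warning) and gene set. Returns (n_overlap, fold_enrichment, p) with
    p = P(X >= n_overlap) for population |background|, |geneset ∩ background|
    successes and |query| draws.
    """
    bg = set(background)
    q = set(query)
    outside = q - bg
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
        q &= bg
    if not q:
        raise ValueError("query is empty after intersecting with the background")
    s = set(geneset) & bg
    k = len(q & s)
    M, n, N = len(bg), len(s), len(q)
    p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
    expected = n / M * N
    fold = (k / expected) if expected > 0 else np.nan
    return k, float(fold), min(p, 1.0)


def bh_fdr(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query: Iterable[str],
    collection: Mapping[str, set[str]],
    background: Iterable[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set in the collection; BH across all tested sets.

    Returns one record per set with at least one overlapping gene, sorted by
    adjusted p (q) ascending, with a ``significant`` flag at q <= fdr_max.
    """
    if not collection:
        raise ValueError("empty gene set collection")
    bg = set(background)
    rows = []
    for name, genes in collection.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        k, fold, p = hypergeom_overrep(query, genes, bg)
        rows.append(
            {
                "set_name": name,
                "n_query": len(set(query) & bg),
                "n_set": len(set(genes) & bg),
                "n_background": len(bg),
                "n_overlap": k,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"])
    df["significant"] = df["q"] <= fdr_max
    df = df[df["n_overlap"] >= 1].sort_values(["q", "p", "set_name"]).reset_index(drop=True)
    return df
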