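"""Co-expression edge inference with the PCIT algorithm.

For every trio of genes (x, y, z) the three first-order partial correlations
are computed; the trio-local tolerance is the average of the ratios of
partial to direct correlation, and the edge x-y is eliminated whenever some
third gene z explains it, i.e. |r_xy| <= |eps * r_xz| and
|r_xy| <= |eps * r_yz|. Surviving edges are additionally screened by the
two-sided t-test on the Pearson correlation (p <= 0.05 by default), the
conjunction defining a significant co-expression pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "pearson_matrix",
    "partial_correlation",
    "correlation_pvalues",
    "pcit",
    "significant_edges",
]


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    r: np.ndarray  # symmetric, unit diagonal
    n_samples: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] != len(self.gene_ids):
            raise ValueError("r must be square and match gene_ids")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        self.r = r


def pearson_matrix(norm: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation across genes of a (genes x samples) matrix.

    The matrix should already be restricted to the samples of one phenotype
    group. Zero-variance genes make the correlation undefined and raise.
    """
    if norm.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    x = norm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(norm.index[sd == 0])
        raise ValueError(f"zero-variance gene(s): {bad[:10]}")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(norm.index), r, norm.shape[1])


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z."""
    for v in (r_xy, r_xz, r_yz):
        if abs(v) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise ValueError("partial correlation undefined: |r_xz| or |r_yz| equals 1")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values of Pearson correlations via t = r sqrt((n-2)/(1-r^2))."""
    if n < 4:
        raise ValueError("need n >= 4 samples for correlation p-values")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


@numba.njit(cache=True)
def _ratio_contrib(partial: float, direct: float) -> tuple[float, int]:
    """Partial/direct ratio with the PCIT conventions: 0/0 counts as 1; a
    zero direct correlation with a nonzero partial is excluded from the
    tolerance average."""
    if direct == 0.0:
        if partial == 0.0:
            return 1.0, 1
        return 0.0, 0
    return partial / direct, 1


@numba.njit(cache=True)
def _pcit_eliminated(r: np.ndarray) -> np.ndarray:
    """Trio-wise elimination matrix (upper triangle meaningful).

    For each pair (x, y) scan conditioning genes z; the scan stops at the
    first z that explains the pair. A z correlated at exactly |r| = 1 with
    either endpoint makes the partials degenerate and counts as explaining
    the pair.
    """
    n = r.shape[0]
    elim = np.zeros((n, n), numba.boolean)
    for x in range(n - 1):
        for y in range(x + 1, n):
            r_xy = r[x, y]
            for z in range(n):
                if z == x or z == y:
                    continue
                r_xz = r[x, z]
                r_yz = r[y, z]
                if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
                    elim[x, y] = True
                    break
                if abs(r_xy) >= 1.0:
                    # partials conditioning on x or y are undefined; no
                    # finite tolerance can be formed for this trio
                    continue
                d_z = (1.0 - r_xz * r_xz) * (1.0 - r_yz * r_yz)
                d_y = (1.0 - r_xy * r_xy) * (1.0 - r_yz * r_yz)
                d_x = (1.0 - r_xy * r_xy) * (1.0 - r_xz * r_xz)
                p_xy = (r_xy - r_xz * r_yz) / np.sqrt(d_z)
                p_xz = (r_xz - r_xy * r_yz) / np.sqrt(d_y)
                p_yz = (r_yz - r_xy * r_xz) / np.sqrt(d_x)
                s = 0.0
                cnt = 0
                v, c = _ratio_contrib(p_xy, r_xy)
                s += v
                cnt += c
                v, c = _ratio_contrib(p_xz, r_xz)
                s += v
                cnt += c
                v, c = _ratio_contrib(p_yz, r_yz)
                s += v
                cnt += c
                if cnt == 0:
                    continue
                eps = s / cnt
                if abs(r_xy) <= abs(eps * r_xz) and abs(r_xy) <= abs(eps * r_yz):
                    elim[x, y] = True
                    break
    return elim


def _pcit_keep_mask(r: np.ndarray) -> np.ndarray:
    """Boolean keep-matrix over gene pairs after trio-wise elimination."""
    elim = _pcit_eliminated(np.ascontiguousarray(r, dtype=np.float64))
    elim = elim | elim.T
    return ~elim


def pcit(
    corr: CorrelationMatrix,
    p_max: float = 0.05,
    mode: str = "pcit_and_p",
) -> pd.DataFrame:
    """Apply PCIT elimination plus the correlation significance filter.

    Returns the canonical edge table over all gene pairs (gene_a < gene_b)
    with columns ``r``, ``p``, ``pcit_significant`` and ``significant``. The
    final flag is the conjunction of PCIT retention and p <= ``p_max``
    (``mode='pcit_and_p'``); ``mode='pcit_only'`` and ``mode='p_only'``
    expose the individual filters. With fewer than 3 genes PCIT is skipped
    and only the p-filter applies.
    """
    if mode not in ("pcit_and_p", "pcit_only", "p_only"):
        raise ValueError(f"unknown mode {mode!r}")
    r = corr.r
    n_genes = len(corr.gene_ids)
    pvals = correlation_pvalues(r, corr.n_samples)
    if n_genes >= 3 and mode != "p_only":
        keep = _pcit_keep_mask(r)
    else:
        keep = np.ones_like(r, dtype=bool)
    iu = np.triu_indices(n_genes, k=1)
    genes = np.asarray(corr.gene_ids)
    df = pd.DataFrame(
        {
            "gene_a": genes[iu[0]],
            "gene_b": genes[iu[1]],
            "r": r[iu],
            "p": pvals[iu],
            "pcit_significant": keep[iu],
        }
    )
    if mode == "pcit_only":
        df["significant"] = df["pcit_significant"]
    elif mode == "p_only":
        df["significant"] = df["p"] <= p_max
    else:
        df["significant"] = df["pcit_significant"] & (df["p"] <= p_max)
    return df


def significant_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Rows flagged significant, as a standalone canonical edge set."""
    return edges.loc[edges["significant"]].reset_index(drop=True)
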