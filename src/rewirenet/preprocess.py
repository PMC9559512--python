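"""Count normalization: CPM, low-expression filtering, variance stabilization,
and batch adjustment.

The output of :func:`normalize` (optionally followed by :func:`adjust_batch`)
is the expression matrix consumed by both the supervised feature-selection
tier and the co-expression network tier. Both tiers only require a monotone
log-like transform, so ``log_cpm`` is the default; ``vst_like`` provides a
negative-binomial variance-stabilizing alternative built on median-of-ratios
size factors and a moment estimate of a common dispersion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_cpm",
    "filter_low_expressed",
    "normalize",
    "adjust_batch",
    "run_preprocess",
]


def _check_matrix(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column rescaled to sum to 1e6."""
    _check_matrix(counts)
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / libsize * 1e6


def filter_low_expressed(
    cpm: pd.DataFrame, min_cpm: float = 0.5, min_fraction: float = 0.5
) -> list[str]:
    """Gene ids expressed at >= ``min_cpm`` in at least ``min_fraction`` of samples.

    A gene passing in exactly ``ceil(min_fraction * n_samples)`` samples is
    kept (a tie at 50% counts as expressed). Input order is preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    need = int(np.ceil(min_fraction * cpm.shape[1]))
    ok = (cpm >= min_cpm).sum(axis=1) >= need
    kept = list(cpm.index[ok])
    if not kept:
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return kept


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes with no zero count."""
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample; cannot fit size factors")
    logc = np.log(counts[positive])
    log_geo_mean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geo_mean, axis=0))
    return sf


def _common_dispersion(q: np.ndarray) -> float:
    """Moment estimate of a common NB dispersion on size-factor-normalized counts."""
    mean = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = alpha[np.isfinite(alpha)]
    if alpha.size == 0:
        return 1e-8
    return float(max(np.median(alpha), 1e-8))


def normalize(counts: pd.DataFrame, method: str = "log_cpm") -> pd.DataFrame:
    """Transform filtered counts to a log2-like scale.

    ``log_cpm``: log2(CPM + 1).
    ``vst_like``: per-sample size-factor scaling followed by the NB
    variance-stabilizing map x -> asinh(sqrt(alpha * x / sf)) / sqrt(alpha)
    with a single moment-estimated dispersion alpha. Both transforms are
    strictly monotone in counts within a sample.
    """
    _check_matrix(counts)
    if (counts.sum(axis=1) == 0).any():
        bad = counts.index[counts.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero gene rows (filter first): {bad[:5]}")
    if method == "log_cpm":
        return np.log2(compute_cpm(counts) + 1.0)
    if method == "vst_like":
        x = counts.to_numpy(dtype=float)
        sf = _size_factors(x)
        alpha = _common_dispersion(x / sf)
        vst = np.arcsinh(np.sqrt(alpha * x / sf)) / np.sqrt(alpha)
        return pd.DataFrame(vst, index=counts.index, columns=counts.columns)
    raise ValueError(f"unknown normalization method: {method!r}")


def adjust_batch(norm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Remove the additive batch component while preserving class differences.

    Per gene, an ordinary least-squares fit on [intercept, class indicator,
    sum-to-zero batch contrasts] is computed and only the fitted batch
    component is subtracted, mirroring the standard limma-style batch
    removal that protects the condition effect. With balanced batches the
    class means are untouched exactly.
    """
    meta = samples.set_index("sample").loc[list(norm.columns)]
    batches = pd.Categorical(meta["batch"])
    classes = pd.Categorical(meta["class"])
    n_batch = len(batches.categories)
    if n_batch == 1:
        warnings.warn("single batch: adjust_batch is the identity", stacklevel=2)
        return norm.copy()
    n = norm.shape[1]
    cls = (classes.codes == 1).astype(float)
    # sum-to-zero contrasts: batch j -> +1, last batch -> -1 on every contrast
    contrasts = np.zeros((n, n_batch - 1))
    for j in range(n_batch - 1):
        contrasts[batches.codes == j, j] = 1.0
        contrasts[batches.codes == n_batch - 1, j] = -1.0
    design = np.column_stack([np.ones(n), cls, contrasts])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch is confounded with class; cannot adjust")
    y = norm.to_numpy(dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    batch_component = contrasts @ coef[2:, :]
    return pd.DataFrame(
        (y - batch_component).T, index=norm.index, columns=norm.columns
    )


def run_preprocess(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_cpm: float = 0.5,
    min_fraction: float = 0.5,
    method: str = "log_cpm",
    batch_adjust: bool = True,
) -> pd.DataFrame:
    """CPM filter -> normalize -> (optional) batch adjustment."""
    kept = filter_low_expressed(compute_cpm(counts), min_cpm, min_fraction)
    norm = normalize(counts.loc[kept], method=method)
    if batch_adjust and samples["batch"].nunique() > 1:
        norm = adjust_batch(norm, samples)
    return norm
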