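"""Synthetic two-class RNA-seq count simulation with planted structure.

Generates gene-level count matrices for a pregnant (P) / non-pregnant (NP)
study design: a latent log2-expression layer carries class-discriminative
marker genes, group-specific correlation modules (the substrate for
co-expression rewiring) and an additive batch offset; observed counts are
drawn from a negative-binomial model around the exponentiated latent means.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ModuleSpec", "SimulationConfig", "GroundTruth", "simulate"]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    Parameters
    ----------
    size
        Number of member genes.
    r_P, r_NP
        Within-module latent correlation in the P and NP groups. A module
        with ``r_P != r_NP`` is differentially connected by construction and
        its members are recorded as expected rewired genes.
    """

    size: int
    r_P: float
    r_NP: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        for r in (self.r_P, self.r_NP):
            if not -0.99 <= r <= 0.99:
                raise ValueError(f"module correlation {r} outside [-0.99, 0.99]")


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate`.

    Defaults mirror a 25 P vs 18 NP bulk RNA-seq design with a two-block
    batch structure, three planted marker genes at a log2 fold change of 2,
    and moderate negative-binomial overdispersion.
    """

    n_genes: int = 600
    n_samples_P: int = 25
    n_samples_NP: int = 18
    n_batches: int = 2
    batch_log2_shift: float = 0.5
    n_marker_genes: int = 3
    marker_log2fc: float = 2.0
    module_specs: tuple[ModuleSpec, ...] = ()
    nb_dispersion: float = 0.1
    baseline_log2_mean_range: tuple[float, float] = (6.0, 12.0)
    latent_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_specs = tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.module_specs
        )
        if min(self.n_genes, self.n_samples_P, self.n_samples_NP) < 1:
            raise ValueError("n_genes and per-class sample counts must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.latent_log2_sd <= 0:
            raise ValueError("latent_log2_sd must be positive")
        if not 0 <= self.n_marker_genes <= self.n_genes:
            raise ValueError("n_marker_genes must be in [0, n_genes]")
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("module sizes sum exceeds n_genes")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise ValueError("baseline_log2_mean_range must be (low, high)")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    marker_gene_ids: list[str]
    module_membership: dict[str, int]  # gene id -> module index (genes in a module only)
    expected_rewired_ids: list[str]
    marker_module_overlap: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _block_cov(size: int, r: float) -> np.ndarray:
    cov = np.full((size, size), r)
    np.fill_diagonal(cov, 1.0)
    return cov


def _module_latent(rng: np.random.Generator, size: int, r: float, n: int) -> np.ndarray:
    """Draw an (size x n) block of unit-variance Gaussians with equicorrelation r."""
    cov = _block_cov(size, r)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # r below -1/(size-1)
        raise ValueError(
            f"equicorrelation {r} is not positive definite for module size {size}"
        ) from exc
    return chol @ rng.standard_normal((size, n))


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a count matrix, sample table and ground truth.

    Returns
    -------
    counts
        genes x samples integer DataFrame (index: gene ids, columns: sample ids).
    samples
        one row per sample with columns ``sample``, ``class`` (P/NP), ``batch``.
    truth
        planted markers, module membership and expected rewired genes.

    Notes
    -----
    Module genes are allocated from the start of the gene list, so a module
    declared alongside ``n_marker_genes > 0`` is seeded on the first marker
    gene(s); the overlap is recorded in ``truth.marker_module_overlap``.
    Identical config (including seed) yields identical output.
    """
    cfg = config
    n_samples = cfg.n_samples_P + cfg.n_samples_NP
    width = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    sample_ids = [f"P{i + 1:02d}" for i in range(cfg.n_samples_P)] + [
        f"NP{i + 1:02d}" for i in range(cfg.n_samples_NP)
    ]
    classes = np.array(["P"] * cfg.n_samples_P + ["NP"] * cfg.n_samples_NP)
    # round-robin batches within each class so batch is never confounded with class
    batch = np.empty(n_samples, dtype=int)
    batch[: cfg.n_samples_P] = np.arange(cfg.n_samples_P) % cfg.n_batches
    batch[cfg.n_samples_P :] = np.arange(cfg.n_samples_NP) % cfg.n_batches

    # independent child streams keep each stage's draws stable under reordering
    ss = np.random.SeedSequence(cfg.seed)
    rng_means, rng_latent, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))

    lo, hi = cfg.baseline_log2_mean_range
    baseline = rng_means.uniform(lo, hi, size=cfg.n_genes)

    # unit-variance latent residuals with block-equicorrelation per module
    z = np.empty((cfg.n_genes, n_samples))
    is_p = classes == "P"
    membership: dict[str, int] = {}
    rewired: list[str] = []
    start = 0
    structured = np.zeros(cfg.n_genes, dtype=bool)
    for mi, mod in enumerate(cfg.module_specs):
        idx = np.arange(start, start + mod.size)
        z[np.ix_(idx, is_p)] = _module_latent(rng_latent, mod.size, mod.r_P, int(is_p.sum()))
        z[np.ix_(idx, ~is_p)] = _module_latent(rng_latent, mod.size, mod.r_NP, int((~is_p).sum()))
        structured[idx] = True
        for g in idx:
            membership[gene_ids[g]] = mi
        if mod.r_P != mod.r_NP:
            rewired.extend(gene_ids[g] for g in idx)
        start += mod.size
    free = ~structured
    z[free] = rng_latent.standard_normal((int(free.sum()), n_samples))

    log2_mu = baseline[:, None] + cfg.latent_log2_sd * z
    marker_ids = gene_ids[: cfg.n_marker_genes]
    if cfg.n_marker_genes:
        log2_mu[: cfg.n_marker_genes][:, is_p] += cfg.marker_log2fc
    log2_mu += (batch * cfg.batch_log2_shift)[None, :]

    mu = np.exp2(log2_mu)
    # NB parameterized by dispersion alpha: var = mu + alpha*mu^2
    alpha = cfg.nb_dispersion
    nb_n = 1.0 / alpha
    nb_p = nb_n / (nb_n + mu)
    counts = rng_counts.negative_binomial(nb_n, nb_p)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    samples_df = pd.DataFrame(
        {"sample": sample_ids, "class": classes, "batch": [f"B{b + 1}" for b in batch]}
    )
    truth = GroundTruth(
        marker_gene_ids=list(marker_ids),
        module_membership=membership,
        expected_rewired_ids=rewired,
        marker_module_overlap=[g for g in marker_ids if g in membership],
    )
    return counts_df, samples_df, truth
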