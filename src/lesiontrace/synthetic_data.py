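"""Synthetic source/target domain pairs, blood-cell backgrounds and CTC-WBC
pseudo-aggregates.

The generator emulates the statistical structure the domain-adaptation method
relies on: every lesion class carries a block of elevated marker genes on the
log2(TPM+1) scale; the target domain shares a subset of classes but its mean
is displaced by a domain-wide per-gene offset (covariate shift) and carries
independent Gaussian noise.  Blood-cell classes use marker blocks disjoint
from all tumor signatures.  Pseudo-aggregates mix one tumor and one white
blood cell profile on the linear TPM scale at a chosen tumor fraction, then
re-log, mimicking physical CTC-WBC cluster aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DomainDataset, ExpressionMatrix

__all__ = [
    "SimConfig",
    "AggregateSpec",
    "generate_domain_pair",
    "generate_blood_background",
    "make_pseudo_aggregates",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic expression generator.

    Defaults describe the standard desk-scale fixture: 500 genes, six source
    lesion classes of 200 cells, four of which recur in the target at 50
    cells each under a unit-magnitude covariate shift.
    """

    n_genes: int = 500
    source_classes: int = 6
    common_classes: int = 4
    cells_per_class_source: int = 200
    cells_per_class_target: int = 50
    class_signature_size: int = 20
    shift_magnitude: float = 1.0
    noise_sd: float = 0.5
    wbc_classes: int = 3
    seed: int = 0
    signature_strength: float = 4.0  # log2-scale elevation of marker genes
    baseline_low: float = 0.1
    baseline_high: float = 2.0

    def __post_init__(self):
        if self.common_classes > self.source_classes:
            raise ValueError("common_classes must be <= source_classes")
        for name in (
            "n_genes", "source_classes", "common_classes",
            "cells_per_class_source", "cells_per_class_target",
            "class_signature_size", "wbc_classes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.shift_magnitude < 0:
            raise ValueError("noise_sd and shift_magnitude must be >= 0")
        needed = (self.source_classes + self.wbc_classes) * self.class_signature_size
        if needed > self.n_genes:
            raise ValueError(
                f"{needed} signature genes required but only {self.n_genes} genes"
            )


@dataclass
class AggregateSpec:
    """How many CTC-WBC pseudo-aggregates to build and at what tumor fraction."""

    tumor_fraction: float
    n_aggregates: int
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.n_aggregates < 1:
            raise ValueError("n_aggregates must be >= 1")


def _gene_ids(cfg: SimConfig) -> list[str]:
    return [f"gene_{i}" for i in range(cfg.n_genes)]


def _baseline(cfg: SimConfig) -> np.ndarray:
    # the baseline is a pure function of the seed so that tumor and blood
    # datasets generated from the same config share their gene space
    rng = np.random.default_rng(cfg.seed)
    return rng.uniform(cfg.baseline_low, cfg.baseline_high, size=cfg.n_genes)


def _class_mean(cfg: SimConfig, baseline: np.ndarray, block: int) -> np.ndarray:
    mean = baseline.copy()
    lo = block * cfg.class_signature_size
    mean[lo : lo + cfg.class_signature_size] += cfg.signature_strength
    return mean


def _sample_cells(
    rng: np.random.Generator, mean: np.ndarray, n: int, noise_sd: float
) -> np.ndarray:
    cells = mean[None, :] + rng.normal(0.0, noise_sd, size=(n, mean.size)) if noise_sd > 0 \
        else np.tile(mean, (n, 1))
    return np.clip(cells, 0.0, None)


def generate_domain_pair(
    cfg: SimConfig, resample_seed: int | None = None
) -> tuple[DomainDataset, DomainDataset]:
    """Generate a labeled source domain and a shifted target domain.

    The target holds the first ``common_classes`` source classes with the same
    marker signatures, displaced by one domain-wide per-gene offset drawn as
    N(0, shift_magnitude^2).  Target labels are attached for evaluation only.
    ``resample_seed`` redraws the cells from the same population (identical
    signatures and domain shift, fresh noise) for held-out batches.
    """
    rng = np.random.default_rng(cfg.seed if resample_seed is None else resample_seed)
    baseline = _baseline(cfg)
    genes = _gene_ids(cfg)
    catalog = [f"lesion_{c}" for c in range(cfg.source_classes)]

    src_rows, src_labels = [], []
    for c in range(cfg.source_classes):
        mean = _class_mean(cfg, baseline, c)
        src_rows.append(_sample_cells(rng, mean, cfg.cells_per_class_source, cfg.noise_sd))
        src_labels += [catalog[c]] * cfg.cells_per_class_source

    # the shift is structural (population-level), so it derives from cfg.seed
    # even when cells are redrawn with a resample_seed
    shift_rng = np.random.default_rng(cfg.seed + 500_009)
    shift = (
        shift_rng.normal(0.0, cfg.shift_magnitude, size=cfg.n_genes)
        if cfg.shift_magnitude > 0
        else np.zeros(cfg.n_genes)
    )
    tgt_rows, tgt_labels = [], []
    for c in range(cfg.common_classes):
        mean = _class_mean(cfg, baseline, c) + shift
        tgt_rows.append(_sample_cells(rng, mean, cfg.cells_per_class_target, cfg.noise_sd))
        tgt_labels += [catalog[c]] * cfg.cells_per_class_target

    src_values = np.vstack(src_rows)
    tgt_values = np.vstack(tgt_rows)
    source = DomainDataset(
        matrix=ExpressionMatrix(
            src_values, genes,
            [f"src_cell_{i}" for i in range(len(src_values))], normalized=True,
        ),
        domain="source",
        labels=src_labels,
        class_catalog=catalog,
    )
    target = DomainDataset(
        matrix=ExpressionMatrix(
            tgt_values, genes,
            [f"tgt_cell_{i}" for i in range(len(tgt_values))], normalized=True,
        ),
        domain="target",
        labels=tgt_labels,
        class_catalog=catalog,
    )
    return source, target


def generate_blood_background(
    cfg: SimConfig, resample_seed: int | None = None
) -> DomainDataset:
    """Generate labeled white-blood-cell classes with tumor-disjoint signatures."""
    base_seed = cfg.seed if resample_seed is None else resample_seed
    rng = np.random.default_rng(base_seed + 1_000_003)
    baseline = _baseline(cfg)
    genes = _gene_ids(cfg)
    catalog = [f"blood:wbc_{b}" for b in range(cfg.wbc_classes)]
    rows, labels = [], []
    for b in range(cfg.wbc_classes):
        mean = _class_mean(cfg, baseline, cfg.source_classes + b)
        rows.append(_sample_cells(rng, mean, cfg.cells_per_class_source, cfg.noise_sd))
        labels += [catalog[b]] * cfg.cells_per_class_source
    values = np.vstack(rows)
    return DomainDataset(
        matrix=ExpressionMatrix(
            values, genes,
            [f"wbc_cell_{i}" for i in range(len(values))], normalized=True,
        ),
        domain="source",
        labels=labels,
        class_catalog=catalog,
    )


def make_pseudo_aggregates(
    tumor: ExpressionMatrix,
    wbc: ExpressionMatrix,
    spec: AggregateSpec,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Mix random tumor and WBC profiles at a fixed tumor fraction.

    Profiles are de-logged to the linear TPM scale, mixed as
    f * tumor + (1-f) * wbc, and re-logged, since aggregation sums
    transcripts rather than log values.  Returns the aggregate matrix plus
    the tumor and WBC row indices sampled for each aggregate (for tracing
    aggregates back to ground-truth labels).
    """
    if tumor.n_cells == 0 or wbc.n_cells == 0:
        raise ValueError("cannot aggregate from an empty matrix")
    if tumor.gene_ids != wbc.gene_ids:
        raise ValueError("tumor and WBC matrices must share the same gene space")
    rng = np.random.default_rng(spec.seed)
    t_idx = rng.integers(0, tumor.n_cells, size=spec.n_aggregates)
    w_idx = rng.integers(0, wbc.n_cells, size=spec.n_aggregates)
    f = spec.tumor_fraction
    lin = f * (2.0 ** tumor.values[t_idx] - 1.0) + (1 - f) * (2.0 ** wbc.values[w_idx] - 1.0)
    values = np.log2(lin + 1.0)
    agg = ExpressionMatrix(
        values,
        list(tumor.gene_ids),
        [f"aggregate_{i}" for i in range(spec.n_aggregates)],
        normalized=True,
    )
    return agg, t_idx, w_idx
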