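"""Desk-scale benchmark routines on the synthetic fixtures.

Each function regenerates its fixture from a seed, runs the relevant part of
the pipeline and returns measured quantities.  The standard fixture is the
`SimConfig` default: 500 genes, six source lesion classes of 200 cells, four
common target classes of 50 cells, unit covariate shift, noise sd 0.5.
Training lengths here (100 epochs for the headline run, 40-60 for secondary
runs) are the package's desk-scale problem sizes; the fixture separates well
before those budgets.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .core_io import DomainDataset, ExpressionMatrix
from .downstream import embed_2d, domain_distance_mmd, identify_markers
from .synthetic_data import (
    AggregateSpec,
    SimConfig,
    generate_blood_background,
    generate_domain_pair,
    make_pseudo_aggregates,
)
from .trainer import TracerModel, TrainConfig, run_background_remover

__all__ = [
    "transductive_benchmark",
    "inductive_benchmark",
    "background_benchmark",
    "aggregate_fraction_benchmark",
    "marker_benchmark",
    "embedding_distance_benchmark",
]


def _subset_cells(m: ExpressionMatrix, idx: np.ndarray, prefix: str) -> ExpressionMatrix:
    return ExpressionMatrix(
        m.values[idx], list(m.gene_ids),
        [f"{prefix}_{i}" for i in range(len(idx))], normalized=True,
    )


def transductive_benchmark(
    seed: int, n_seeds: int = 3, epochs: int = 100
) -> dict:
    """Pseudo-label accuracy of the transductive mode on the standard fixture,
    averaged over ``n_seeds`` replicate fixtures."""
    accs = []
    for s in range(seed, seed + n_seeds):
        src, tgt = generate_domain_pair(SimConfig(seed=s))
        res = TracerModel(src, tgt, train_config=TrainConfig(epochs=epochs, seed=s)).fit()
        accs.append(res.accuracy)
    return {
        "per_seed_accuracy": accs,
        "mean_accuracy": float(np.mean(accs)),
        "n_target_cells": tgt.n_cells,
        "epochs": epochs,
    }


def inductive_benchmark(seed: int, epochs: int = 60) -> dict:
    """Accuracy of a frozen pretrained model on a fresh same-population target
    batch, against a transductive run on that same batch."""
    cfg = SimConfig(seed=seed)
    src, tgt_a = generate_domain_pair(cfg)
    _, tgt_b = generate_domain_pair(cfg, resample_seed=seed + 501)
    pre = TracerModel(
        src, tgt_a, train_config=TrainConfig(epochs=epochs, seed=seed)
    ).fit(mode="inductive-pretrain")
    calls = pre.predict(tgt_b.matrix)
    acc_inductive = float(np.mean(calls["predicted_class"].to_numpy() == np.asarray(tgt_b.labels)))
    trans = TracerModel(
        src, tgt_b, train_config=TrainConfig(epochs=epochs, seed=seed)
    ).fit()
    return {
        "inductive_accuracy": acc_inductive,
        "transductive_accuracy": trans.accuracy,
        "gap": abs(acc_inductive - trans.accuracy),
        "n_target_cells": tgt_b.n_cells,
    }


def background_benchmark(seed: int, epochs: int = 100, blood_target_per_class: int = 50) -> dict:
    """CTC-vs-blood separation: tumor-score AUC on a mixed target of shifted
    tumor cells and fresh blood cells."""
    cfg = SimConfig(seed=seed)
    tumor_src, tumor_tgt = generate_domain_pair(cfg)
    blood_src = generate_blood_background(cfg)
    blood_fresh = generate_blood_background(cfg, resample_seed=seed + 77)
    rng = np.random.default_rng(seed + 13)
    pick = rng.choice(
        blood_fresh.n_cells, size=blood_target_per_class * cfg.wbc_classes, replace=False
    )
    blood_m = _subset_cells(blood_fresh.matrix, pick, "tgt_blood")
    values = np.vstack([tumor_tgt.matrix.values, blood_m.values])
    cells = list(tumor_tgt.matrix.cell_ids) + list(blood_m.cell_ids)
    target = DomainDataset(
        matrix=ExpressionMatrix(values, list(tumor_tgt.matrix.gene_ids), cells, normalized=True),
        domain="target",
    )
    is_tumor = np.array([1] * tumor_tgt.n_cells + [0] * blood_m.n_cells)
    _, calls = run_background_remover(
        tumor_src, blood_src, target,
        train_config=TrainConfig(epochs=epochs, seed=seed),
    )
    auc = float(roc_auc_score(is_tumor, calls["tumor_score"].to_numpy()))
    pure_blood_rate = float(calls["is_CTC"].to_numpy()[is_tumor == 0].mean())
    return {
        "auc": auc,
        "blood_false_positive_rate": pure_blood_rate,
        "n_target_cells": len(is_tumor),
    }


def aggregate_fraction_benchmark(
    seed: int,
    fractions: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 5,
    n_aggregates: int = 100,
    epochs: int = 40,
) -> dict:
    """Lesion-call accuracy on CTC-WBC pseudo-aggregates as a function of the
    tumor fraction, averaged over replicate fixtures."""
    acc = np.zeros((n_seeds, len(fractions)))
    for r, s in enumerate(range(seed, seed + n_seeds)):
        cfg = SimConfig(seed=s)
        src, tgt = generate_domain_pair(cfg)
        res = TracerModel(src, tgt, train_config=TrainConfig(epochs=epochs, seed=s)).fit()
        tumor_pool = generate_domain_pair(cfg, resample_seed=s + 44)[1]
        blood = generate_blood_background(cfg, resample_seed=s + 33)
        for j, f in enumerate(fractions):
            agg, t_idx, _ = make_pseudo_aggregates(
                tumor_pool.matrix, blood.matrix,
                AggregateSpec(tumor_fraction=f, n_aggregates=n_aggregates, seed=s + j),
            )
            calls = res.predict(agg)
            truth = np.asarray(tumor_pool.labels)[t_idx]
            acc[r, j] = np.mean(calls["predicted_class"].to_numpy() == truth)
    mean_acc = acc.mean(axis=0)
    return {
        "fractions": list(fractions),
        "mean_accuracy": mean_acc.tolist(),
        "per_seed_accuracy": acc.tolist(),
        "non_decreasing": bool(np.all(np.diff(mean_acc) >= 0)),
        "n_aggregates": n_aggregates,
    }


def _planted_de_fixture(
    seed: int,
    n_genes: int = 500,
    n_planted: int = 20,
    n_cells: int = 40,
    fold: float = 32.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Two groups identical except for ``n_planted`` genes whose linear mean
    is ``fold`` times higher in the first group (logFC = log2(fold))."""
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i}" for i in range(n_genes)]
    base_lin = rng.uniform(5.0, 50.0, size=n_genes)
    def draw(lin_mean, n, label):
        lin = rng.gamma(shape=4.0, scale=lin_mean / 4.0, size=(n, n_genes))
        return ExpressionMatrix(
            np.log2(lin + 1.0), genes, [f"{label}_{i}" for i in range(n)], normalized=True
        )
    up = base_lin.copy()
    up[:n_planted] *= fold
    ctc = draw(up, n_cells, "ctc")
    primary = draw(base_lin, n_cells, "primary")
    return ctc, primary, genes[:n_planted]


def marker_benchmark(seed: int) -> dict:
    """Recovery of planted differentially expressed genes by the marker filter."""
    ctc, primary, planted = _planted_de_fixture(seed)
    table = identify_markers(ctc, primary)
    flagged = set(table.loc[table["flagged"], "gene"])
    planted_set = set(planted)
    tp = len(flagged & planted_set)
    return {
        "n_flagged": len(flagged),
        "n_planted": len(planted_set),
        "recovered": tp,
        "false_flags": len(flagged - planted_set),
        "exact_recovery": flagged == planted_set,
    }


def embedding_distance_benchmark(seed: int, epochs: int = 40, subsample: int = 150) -> dict:
    """Domain distance (squared MMD on 2-D t-SNE coordinates) between
    matched-class source and target cells, before vs after adaptation."""
    cfg = SimConfig(seed=seed)
    src, tgt = generate_domain_pair(cfg)
    res = TracerModel(src, tgt, train_config=TrainConfig(epochs=epochs, seed=seed)).fit()

    common = set(tgt.class_catalog[: cfg.common_classes])
    keep_src = np.flatnonzero(np.isin(src.labels, list(common)))
    rng = np.random.default_rng(seed)
    keep_src = rng.choice(keep_src, size=min(subsample, keep_src.size), replace=False)
    xs_raw = src.matrix.values[keep_src]
    xt_raw = tgt.matrix.values

    from ._autodiff import Tensor
    f = res.model.extractor
    g = res.model.classifier
    pen_s = g.penultimate(f.forward(Tensor(xs_raw))).data
    pen_t = g.penultimate(f.forward(Tensor(xt_raw))).data

    def mmd_2d(a, b):
        both = np.vstack([a, b])
        coords = embed_2d(both, method="tsne", seed=seed)
        return domain_distance_mmd(coords[: len(a)], coords[len(a):])

    before = mmd_2d(xs_raw, xt_raw)
    after = mmd_2d(pen_s, pen_t)
    return {"mmd_before": before, "mmd_after": after, "reduced": after < before}
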