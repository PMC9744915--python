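"""Transductive / inductive training of the lesion tracer and inference.

`TracerModel` follows the model/results convention of statistical modelling
packages: it is constructed from a labeled source `DomainDataset` and an
unlabeled target `DomainDataset`, and `fit()` returns a `TracerResults`
carrying the fitted networks, the prototype bank, per-cell pseudo-labels with
confidences, the loss history and a text `summary()`.

Each training epoch alternates (a) clustering/matching — embed both domains,
form label-defined source class centers, optimize the target cluster count by
the domain consensus score, propagate pseudo-labels, rebuild the prototype
bank — with (b) gradient updates of the composite objective
l = l_ce + lambda*l_cdd + gamma*l_reg under an Adam optimizer, an
inverse-decay learning-rate schedule and an exponentially annealed gamma.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor, l2_normalize_rows
from .cluster_match import (
    PseudoLabelSet,
    UNASSIGNED,
    assign_pseudo_labels,
    optimize_target_k,
    source_class_assignment,
)
from .core_io import DomainDataset, ExpressionMatrix, align_genes
from .embedding_net import (
    Classifier,
    FeatureExtractor,
    NetworkConfig,
    embed_and_normalize,
)
from .objectives import (
    KernelSpec,
    PRIVATE,
    PrototypeBank,
    cdd_loss,
    cross_entropy_source,
    gamma_weight,
    lr_schedule,
    prototypical_regularizer,
    total_loss,
)

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "TracerModel",
    "TracerResults",
    "predict",
    "run_background_remover",
    "collapse_tumor_labels",
]

MIN_RECOMMENDED_TARGET_CELLS = 30
TUMOR_CLASS = "tumor"


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published training recipe."""

    epochs: int = 500
    batch_size: int = 64
    initial_lr: float = 5e-5
    weight_decay: float = 5e-4
    sched_gamma: float = 10.0
    sched_power: float = 0.75  # 10.0 for inductive pretraining
    lam: float = 0.1
    omega: float = 3.0
    tau: float = 0.1
    recluster_every: int = 1
    patience: int = 20  # consecutive no-consensus epochs before aborting
    k_grid: list[int] | None = None  # default 2 .. 2 * n_source_classes
    n_kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        positive = (
            "epochs", "batch_size", "initial_lr", "weight_decay", "sched_gamma",
            "sched_power", "omega", "tau", "recluster_every", "patience",
            "n_kmeans_restarts",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


class Adam:
    """Adam with decoupled-L2-style weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainedModel:
    """Everything needed for inference: networks, prototype bank, catalogs."""

    extractor: FeatureExtractor
    classifier: Classifier
    bank: PrototypeBank
    class_catalog: list[str]
    gene_ids: list[str]
    net_config: NetworkConfig
    train_config: TrainConfig

    def save(self, path: str | Path) -> None:
        arrays = {}
        for tag, net in (("f", self.extractor), ("g", self.classifier)):
            for i, a in enumerate(net.state_arrays()):
                arrays[f"{tag}_{i}"] = a
        arrays["bank_M"] = self.bank.M
        meta = {
            "schema": "lesiontrace-checkpoint-1",
            "class_catalog": self.class_catalog,
            "gene_ids": self.gene_ids,
            "bank_classes": self.bank.class_of_prototype,
            "tau": self.bank.temperature,
            "net_config": asdict(self.net_config),
            "train_config": asdict(self.train_config),
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            if meta.get("schema") != "lesiontrace-checkpoint-1":
                raise ValueError("unrecognized checkpoint schema")
            net_cfg = NetworkConfig(**meta["net_config"])
            train_cfg = TrainConfig(**meta["train_config"])
            rng = np.random.default_rng(0)
            f = FeatureExtractor(net_cfg, rng)
            g = Classifier(net_cfg, rng)
            f.load_state_arrays([z[k] for k in sorted(
                (k for k in z.files if k.startswith("f_")),
                key=lambda s: int(s.split("_")[1]))])
            g.load_state_arrays([z[k] for k in sorted(
                (k for k in z.files if k.startswith("g_")),
                key=lambda s: int(s.split("_")[1]))])
            bank = PrototypeBank(z["bank_M"], meta["bank_classes"], meta["tau"])
        return cls(
            extractor=f, classifier=g, bank=bank,
            class_catalog=meta["class_catalog"], gene_ids=meta["gene_ids"],
            net_config=net_cfg, train_config=train_cfg,
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(model: TrainedModel, target: ExpressionMatrix) -> pd.DataFrame:
    """Label target cells by their cosine-nearest prototype; no clustering.

    Returns one row per cell with the nearest-prototype call, the classifier
    softmax over the class catalog (``score_<class>`` columns) and the
    softmax-mass score of the called class.
    """
    if target.gene_ids != model.gene_ids:
        if set(model.gene_ids) - set(target.gene_ids):
            raise ValueError("target matrix lacks genes of the model's gene list")
        target = target.subset_genes(model.gene_ids)
    emb = embed_and_normalize(model.extractor, target)
    sims = emb.vectors @ model.bank.M.T
    nearest = np.argmax(sims, axis=1)
    labels = [model.bank.class_of_prototype[i] for i in nearest]
    if any(l == PRIVATE for l in labels):
        warnings.warn(
            "some cells map to a private (unmatched) prototype; labeled 'unassigned'",
            stacklevel=2,
        )
    labels = [UNASSIGNED if l == PRIVATE else l for l in labels]
    scores = _softmax(model.classifier.forward(Tensor(emb.vectors)).data)
    out = pd.DataFrame(
        {
            "cell_id": target.cell_ids,
            "predicted_class": labels,
            "nearest_prototype": nearest,
        }
    )
    for j, c in enumerate(model.class_catalog):
        out[f"score_{c}"] = scores[:, j]
    return out


class TracerModel:
    """Domain-adaptation model transferring lesion labels from a labeled
    source to an unlabeled target expression matrix.

    Parameters
    ----------
    source, target
        Gene-aligned `DomainDataset`s (aligned automatically when their gene
        lists differ).  The source must be labeled; target labels, if
        present, are used only to report accuracy diagnostics.
    net_config, train_config
        Architecture and optimization settings; defaults follow the
        published recipe (1024/512/512 hidden widths, 200-d embedding,
        Adam, lr 5e-5, batch 64, lambda 0.1, omega 3, tau 0.1).
    """

    def __init__(
        self,
        source: DomainDataset,
        target: DomainDataset,
        net_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
        kernel: KernelSpec | None = None,
    ):
        if source.domain != "source" or target.domain != "target":
            raise ValueError("expected one source and one target dataset")
        if source.matrix.gene_ids != target.matrix.gene_ids:
            source, target = align_genes(source, target)
        self.source = source
        self.target = target
        self.train_config = train_config or TrainConfig()
        self.net_config = net_config or NetworkConfig(
            n_genes=source.matrix.n_genes, n_classes=len(source.class_catalog)
        )
        if self.net_config.n_genes != source.matrix.n_genes:
            raise ValueError("net_config.n_genes does not match the matrix")
        if self.net_config.n_classes != len(source.class_catalog):
            raise ValueError("net_config.n_classes does not match the class catalog")
        self.kernel = kernel or KernelSpec()
        if target.n_cells < MIN_RECOMMENDED_TARGET_CELLS:
            warnings.warn(
                f"target has {target.n_cells} cells (<{MIN_RECOMMENDED_TARGET_CELLS}); "
                "label transfer is less reliable on very small targets",
                stacklevel=2,
            )

    # -- internal helpers ----------------------------------------------------
    def _cluster_and_match(self, f: FeatureExtractor, k_grid: list[int], seed: int):
        src_emb = embed_and_normalize(f, self.source.matrix)
        tgt_emb = embed_and_normalize(f, self.target.matrix)
        src_assign = source_class_assignment(
            src_emb, self.source.label_indices(), len(self.source.class_catalog)
        )
        k, tgt_assign, match = optimize_target_k(
            src_assign, src_emb, tgt_emb, k_grid, seed=seed,
            n_restarts=self.train_config.n_kmeans_restarts,
        )
        class_of_src_cluster = dict(enumerate(self.source.class_catalog))
        pseudo = assign_pseudo_labels(match, tgt_assign, class_of_src_cluster)
        t2s = match.target_to_source()
        bank = PrototypeBank(
            tgt_assign.centers,
            [
                self.source.class_catalog[t2s[j]] if j in t2s else PRIVATE
                for j in range(tgt_assign.k)
            ],
            temperature=self.train_config.tau,
        )
        return src_emb, tgt_emb, tgt_assign, match, pseudo, bank

    def _class_aware_batch(
        self,
        rng: np.random.Generator,
        pseudo: PseudoLabelSet,
        batch_size: int,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Near-equal per-class draws from source and pseudo-labeled target,
        plus a small draw of unassigned target cells (regularizer only)."""
        src_labels = np.asarray(self.source.labels)
        tgt_labels = np.asarray(pseudo.labels)
        common = [
            c for c in self.source.class_catalog
            if np.any(src_labels == c) and np.any(tgt_labels == c)
        ]
        if not common:
            raise RuntimeError("no common classes between source and pseudo-labeled target")
        # the source batch spans ALL source classes (the cross-entropy term
        # must see source-private classes); the CDD only uses the common ones
        src_quota = max(1, batch_size // len(self.source.class_catalog))
        tgt_quota = max(1, batch_size // len(common))
        src_idx, tgt_idx = [], []
        for c in self.source.class_catalog:
            pool_s = np.flatnonzero(src_labels == c)
            src_idx.append(rng.choice(pool_s, size=src_quota, replace=len(pool_s) < src_quota))
        for c in common:
            pool_t = np.flatnonzero(tgt_labels == c)
            tgt_idx.append(rng.choice(pool_t, size=tgt_quota, replace=len(pool_t) < tgt_quota))
        src_idx = np.concatenate(src_idx)
        tgt_idx = np.concatenate(tgt_idx)
        unassigned = np.flatnonzero(tgt_labels == UNASSIGNED)
        if unassigned.size:
            extra = rng.choice(unassigned, size=min(8, unassigned.size), replace=False)
        else:
            extra = np.empty(0, dtype=np.intp)
        return src_idx, tgt_idx, extra, common

    # -- fitting -------------------------------------------------------------
    def fit(
        self,
        mode: str = "transductive",
        epochs: int | None = None,
        init_from: TrainedModel | None = None,
    ) -> "TracerResults":
        """Run the alternating cluster/match + gradient-update loop.

        ``mode='inductive-pretrain'`` accelerates the learning-rate decay
        (power 10) to yield a more general frozen model for later inference.
        ``init_from`` warm-starts the networks from a previously trained
        model (transductive refinement) instead of a fresh initialization.
        """
        if mode not in ("transductive", "inductive-pretrain"):
            raise ValueError(f"unknown mode {mode!r}")
        cfg = self.train_config
        if mode == "inductive-pretrain":
            cfg = replace(cfg, sched_power=10.0)
        if epochs is not None:
            cfg = replace(cfg, epochs=epochs)

        rng = np.random.default_rng(cfg.seed)
        f = FeatureExtractor(self.net_config, np.random.default_rng(cfg.seed))
        g = Classifier(self.net_config, np.random.default_rng(cfg.seed + 1))
        if init_from is not None:
            f.load_state_arrays([a.copy() for a in init_from.extractor.state_arrays()])
            g.load_state_arrays([a.copy() for a in init_from.classifier.state_arrays()])
        optimizer = Adam(f.parameters + g.parameters, weight_decay=cfg.weight_decay)

        n_classes = len(self.source.class_catalog)
        k_grid = cfg.k_grid or list(range(2, 2 * n_classes + 1))
        N = cfg.epochs
        d = max(1, self.target.n_cells // cfg.batch_size)
        src_label_idx = self.source.label_indices()

        history: list[dict] = []
        epoch_diag: list[dict] = []
        no_consensus = 0
        state = None  # (tgt_assign, match, pseudo, bank)
        tgt_true = self.target.labels

        for epoch in range(1, N + 1):
            if state is None or (epoch - 1) % cfg.recluster_every == 0:
                try:
                    (_, _, tgt_assign, match, pseudo, bank) = self._cluster_and_match(
                        f, k_grid, seed=cfg.seed + epoch
                    )
                    state = (tgt_assign, match, pseudo, bank)
                    no_consensus = 0
                except RuntimeError as err:
                    no_consensus += 1
                    log.warning("epoch %d: %s", epoch, err)
                    if state is None or no_consensus >= cfg.patience:
                        raise RuntimeError(
                            f"no domain consensus for {no_consensus} consecutive "
                            f"re-clustering attempts (epoch {epoch}); the domains may "
                            "share no classes or the embedding collapsed"
                        ) from err
            tgt_assign, match, pseudo, bank = state

            for i in range(d):
                src_idx, tgt_idx, extra, common = self._class_aware_batch(
                    rng, pseudo, cfg.batch_size
                )
                reg_idx = np.concatenate([tgt_idx, extra])

                src_x = Tensor(self.source.matrix.values[src_idx])
                tgt_x = Tensor(self.target.matrix.values[reg_idx])
                src_h = f.forward(src_x, training=True, rng=rng)
                tgt_h = f.forward(tgt_x, training=True, rng=rng)
                src_v = l2_normalize_rows(src_h, eps=1e-12)
                tgt_v = l2_normalize_rows(tgt_h, eps=1e-12)

                scores = g.forward(src_h)
                l_ce = cross_entropy_source(scores, src_label_idx[src_idx])

                n_lab = tgt_idx.size
                l_cdd = cdd_loss(
                    src_v,
                    np.asarray(self.source.labels)[src_idx],
                    _slice_rows(tgt_v, 0, n_lab),
                    np.asarray(pseudo.labels)[tgt_idx],
                    common,
                    self.kernel,
                )
                l_reg = prototypical_regularizer(
                    tgt_v, bank, tgt_assign.labels[reg_idx]
                )

                gamma = gamma_weight(i, epoch, N, d, cfg.omega)
                lr = lr_schedule(
                    cfg.initial_lr, i, epoch, N, d, cfg.sched_gamma, cfg.sched_power
                )
                loss = total_loss(l_ce, l_cdd, l_reg, cfg.lam, gamma)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step(lr)

                history.append(
                    {
                        "epoch": epoch, "step": i,
                        "l": loss.item(), "l_ce": l_ce.item(),
                        "l_cdd": l_cdd.item(), "l_reg": l_reg.item(),
                        "gamma": gamma, "lr": lr,
                    }
                )
            diag = {
                "epoch": epoch,
                "k": tgt_assign.k,
                "n_matched_pairs": len(match.pairs),
                "mean_consensus": match.mean_consensus,
                "n_unassigned": pseudo.n_unassigned,
            }
            if tgt_true is not None:
                diag["pseudo_label_accuracy"] = float(
                    np.mean(np.asarray(pseudo.labels) == np.asarray(tgt_true))
                )
            epoch_diag.append(diag)

        # final clustering/matching state with the fitted weights
        (_, _, tgt_assign, match, pseudo, bank) = self._cluster_and_match(
            f, k_grid, seed=cfg.seed + N + 1
        )
        model = TrainedModel(
            extractor=f, classifier=g, bank=bank,
            class_catalog=list(self.source.class_catalog),
            gene_ids=list(self.source.matrix.gene_ids),
            net_config=self.net_config, train_config=cfg,
        )
        return TracerResults(
            model=model,
            pseudo_labels=pseudo,
            loss_history=pd.DataFrame(history),
            epoch_diagnostics=pd.DataFrame(epoch_diag),
            mode=mode,
            target_cell_ids=list(self.target.matrix.cell_ids),
            target_true_labels=list(tgt_true) if tgt_true is not None else None,
        )


def _slice_rows(t: Tensor, start: int, stop: int) -> Tensor:
    """Differentiable row slice (gradient scatters back into the parent)."""
    sel = np.zeros((stop - start, t.shape[0]))
    sel[np.arange(stop - start), np.arange(start, stop)] = 1.0
    return Tensor(sel) @ t


@dataclass
class TracerResults:
    """Fitted tracer: estimates, diagnostics and inference methods."""

    model: TrainedModel
    pseudo_labels: PseudoLabelSet
    loss_history: pd.DataFrame
    epoch_diagnostics: pd.DataFrame
    mode: str
    target_cell_ids: list[str]
    target_true_labels: list[str] | None = None

    def predict(self, target: ExpressionMatrix) -> pd.DataFrame:
        return predict(self.model, target)

    def pseudo_label_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.target_cell_ids,
                "pseudo_label": self.pseudo_labels.labels,
                "source_cluster": self.pseudo_labels.source_cluster,
                "confidence": self.pseudo_labels.confidence,
            }
        )

    @property
    def accuracy(self) -> float | None:
        """Pseudo-label accuracy against held-out target labels, if any."""
        if self.target_true_labels is None:
            return None
        return float(
            np.mean(
                np.asarray(self.pseudo_labels.labels)
                == np.asarray(self.target_true_labels)
            )
        )

    def save(self, path: str | Path) -> None:
        self.model.save(path)

    def summary(self) -> str:
        buf = io.StringIO()
        last = self.epoch_diagnostics.iloc[-1] if len(self.epoch_diagnostics) else None
        w = buf.write
        w("Lesion tracer fit (" + self.mode + " mode)\n")
        w("=" * 46 + "\n")
        w(f"source classes:        {len(self.model.class_catalog)}\n")
        w(f"genes:                 {len(self.model.gene_ids)}\n")
        w(f"target cells:          {len(self.target_cell_ids)}\n")
        w(f"epochs:                {self.model.train_config.epochs}\n")
        w(f"prototypes (K):        {self.model.bank.K}\n")
        matched = sum(1 for c in self.model.bank.class_of_prototype if c != PRIVATE)
        w(f"matched prototypes:    {matched}\n")
        w(f"unassigned cells:      {self.pseudo_labels.n_unassigned}\n")
        if last is not None:
            w(f"final mean consensus:  {last['mean_consensus']:.3f}\n")
        if len(self.loss_history):
            first, final = self.loss_history["l"].iloc[0], self.loss_history["l"].iloc[-1]
            w(f"loss first->last step: {first:.3f} -> {final:.3f}\n")
        if self.accuracy is not None:
            w(f"pseudo-label accuracy: {self.accuracy:.3f} (target labels held out)\n")
        return buf.getvalue()


def collapse_tumor_labels(source_tumor: DomainDataset) -> DomainDataset:
    """Collapse all tumor classes into the single class 'tumor'."""
    return DomainDataset(
        matrix=source_tumor.matrix,
        domain="source",
        labels=[TUMOR_CLASS] * source_tumor.n_cells,
        class_catalog=[TUMOR_CLASS],
    )


def _concat_sources(a: DomainDataset, b: DomainDataset) -> DomainDataset:
    if a.matrix.gene_ids != b.matrix.gene_ids:
        raise ValueError("source datasets must share a gene space")
    values = np.vstack([a.matrix.values, b.matrix.values])
    cells = list(a.matrix.cell_ids) + list(b.matrix.cell_ids)
    return DomainDataset(
        matrix=ExpressionMatrix(values, list(a.matrix.gene_ids), cells, normalized=True),
        domain="source",
        labels=list(a.labels) + list(b.labels),
        class_catalog=list(a.class_catalog) + list(b.class_catalog),
    )


def run_background_remover(
    source_tumor: DomainDataset,
    source_blood: DomainDataset,
    target: DomainDataset,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    kernel: KernelSpec | None = None,
) -> tuple["TracerResults", pd.DataFrame]:
    """CTC-vs-blood mode: collapse all tumor classes into one 'tumor' class,
    keep blood subtypes as separate classes, train as usual and call a cell a
    CTC when its prediction is 'tumor'.

    Returns the fit results and a per-cell frame with ``is_CTC`` and the
    softmax tumor-probability ``tumor_score`` (for ROC analysis).
    """
    merged = _concat_sources(collapse_tumor_labels(source_tumor), source_blood)
    model = TracerModel(merged, target, net_config, train_config, kernel)
    results = model.fit()
    calls = results.predict(target.matrix)
    calls["tumor_score"] = calls[f"score_{TUMOR_CLASS}"]
    calls["is_CTC"] = calls["predicted_class"] == TUMOR_CLASS
    return results, calls
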