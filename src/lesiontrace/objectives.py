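"""Training objectives: prototypical regularizer, (class-conditional) maximum
mean discrepancy, source cross-entropy, the composite loss and both schedules.

All losses accept autodiff tensors (gradients flow to the embeddings) or
plain numpy arrays (evaluation only) and return a scalar ``Tensor``.
Reductions follow the printed formulations: the regularizer and the source
cross-entropy are batch sums, not means, which couples their scale to the
batch size (64 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import exp

import numpy as np

from ._autodiff import Tensor, as_tensor, log_softmax, pairwise_sq_dists

log = logging.getLogger(__name__)

__all__ = [
    "PrototypeBank",
    "KernelSpec",
    "LossBreakdown",
    "prototypical_regularizer",
    "mmd_squared",
    "cdd_loss",
    "cross_entropy_source",
    "gamma_weight",
    "total_loss",
    "lr_schedule",
]

PRIVATE = "private"


@dataclass
class PrototypeBank:
    """L2-normalized target cluster centers with their matched source classes.

    Rows matched to no source cluster are labeled "private"; the softmax
    temperature tau defaults to 0.1.
    """

    M: np.ndarray  # K x embed_dim, rows unit-norm
    class_of_prototype: list[str]
    temperature: float = 0.1

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2 or self.M.shape[0] < 1:
            raise ValueError("prototype bank needs at least one row")
        if not np.allclose(np.linalg.norm(self.M, axis=1), 1.0, atol=1e-6):
            raise ValueError("prototype rows must be unit-norm")
        if len(self.class_of_prototype) != self.M.shape[0]:
            raise ValueError("one class per prototype row required")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def K(self) -> int:
        return self.M.shape[0]


@dataclass
class KernelSpec:
    """Kernel used in the discrepancy estimators.

    Gaussian bandwidths default to the median-heuristic multiples
    {sigma/2, sigma, 2*sigma} computed per batch; kernel values are averaged
    over bandwidths.  The linear kernel is kept for closed-form checks.
    """

    family: str = "gaussian"
    bandwidths: list[float] | None = None  # None -> median heuristic multiples
    bandwidth_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    layer_set: tuple[str, ...] = ("embedding",)

    def __post_init__(self):
        if self.family not in ("gaussian", "linear"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian" and self.bandwidths is not None and not self.bandwidths:
            raise ValueError("gaussian kernel needs at least one bandwidth")


def _median_bandwidth(stacked: np.ndarray) -> float:
    d = pairwise_sq_dists(Tensor(stacked), Tensor(stacked)).data
    off = d[~np.eye(d.shape[0], dtype=bool)]
    med = float(np.median(np.sqrt(np.maximum(off, 0.0)))) if off.size else 1.0
    return med if med > 0 else 1.0


def _kernel_matrix(x: Tensor, y: Tensor, kernel: KernelSpec, sigma: float | None = None) -> Tensor:
    if kernel.family == "linear":
        return x @ y.T
    if kernel.bandwidths is not None:
        bws = kernel.bandwidths
    else:
        if sigma is None:
            sigma = _median_bandwidth(np.vstack([x.data, y.data]))
        bws = [m * sigma for m in kernel.bandwidth_multipliers]
    d = pairwise_sq_dists(x, y)
    out = None
    for bw in bws:
        term = (d * (-1.0 / (2.0 * bw * bw))).exp()
        out = term if out is None else out + term
    return out / float(len(bws))


def prototypical_regularizer(
    tgt_emb: Tensor | np.ndarray,
    bank: PrototypeBank,
    cluster_labels: np.ndarray,
) -> Tensor:
    """Sum of temperature-softmax cross-entropies of target cells against
    their own cluster prototypes.

    Embeddings must be L2-normalized; ``cluster_labels`` indexes bank rows.
    """
    v = as_tensor(tgt_emb)
    cluster_labels = np.asarray(cluster_labels, dtype=np.intp)
    if cluster_labels.min(initial=0) < 0 or (
        cluster_labels.size and cluster_labels.max() >= bank.K
    ):
        raise IndexError("cluster label outside the prototype bank")
    logits = (v @ Tensor(bank.M.T)) / bank.temperature
    logp = log_softmax(logits, axis=1)
    onehot = np.zeros((cluster_labels.size, bank.K))
    onehot[np.arange(cluster_labels.size), cluster_labels] = 1.0
    return -(logp * Tensor(onehot)).sum()


def mmd_squared(
    x: Tensor | np.ndarray, y: Tensor | np.ndarray, kernel: KernelSpec | None = None
) -> Tensor:
    """Biased squared MMD estimator (all three double sums keep the diagonal)."""
    kernel = kernel or KernelSpec()
    x, y = as_tensor(x), as_tensor(y)
    ns, nt = x.shape[0], y.shape[0]
    if ns == 0 or nt == 0:
        raise ValueError("both sample sets must be nonempty")
    sigma = _median_bandwidth(np.vstack([x.data, y.data])) if kernel.family == "gaussian" else None
    kxx = _kernel_matrix(x, x, kernel, sigma)
    kyy = _kernel_matrix(y, y, kernel, sigma)
    kxy = _kernel_matrix(x, y, kernel, sigma)
    return kxx.sum() / (ns * ns) + kyy.sum() / (nt * nt) - 2.0 * kxy.sum() / (ns * nt)


def cdd_loss(
    src_emb: Tensor | np.ndarray,
    src_labels: np.ndarray,
    tgt_emb: Tensor | np.ndarray,
    tgt_labels: np.ndarray,
    common_classes: list,
    kernel: KernelSpec | None = None,
) -> Tensor:
    """Contrastive domain discrepancy over the shared classes.

    Intra-class cross-domain discrepancy is averaged over classes and the
    inter-class discrepancy over ordered class pairs; classes missing from
    either domain in the batch are dropped with a warning, and a single
    surviving class makes the inter term an empty mean, defined as 0.
    """
    kernel = kernel or KernelSpec()
    x, y = as_tensor(src_emb), as_tensor(tgt_emb)
    src_labels = np.asarray(src_labels)
    tgt_labels = np.asarray(tgt_labels)
    present = [
        c for c in common_classes
        if np.any(src_labels == c) and np.any(tgt_labels == c)
    ]
    dropped = [c for c in common_classes if c not in present]
    if dropped:
        log.warning("classes missing from the batch dropped from the CDD: %s", dropped)
    if not present:
        return Tensor(0.0)

    sigma = (
        _median_bandwidth(np.vstack([x.data, y.data]))
        if kernel.family == "gaussian" else None
    )
    kss = _kernel_matrix(x, x, kernel, sigma)
    ktt = _kernel_matrix(y, y, kernel, sigma)
    kst = _kernel_matrix(x, y, kernel, sigma)

    def masked_mean(k: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
        mask = np.outer(rows, cols).astype(np.float64)
        return (k * Tensor(mask)).sum() / float(mask.sum())

    def d_hat(c1, c2) -> Tensor:
        s1 = src_labels == c1
        t2 = tgt_labels == c2
        e1 = masked_mean(kss, s1, s1)
        e2 = masked_mean(ktt, t2, t2)
        e3 = masked_mean(kst, s1, t2)
        return e1 + e2 - 2.0 * e3

    intra = None
    for c in present:
        term = d_hat(c, c)
        intra = term if intra is None else intra + term
    intra = intra / float(len(present))

    if len(present) < 2:
        return intra
    inter = None
    for c1 in present:
        for c2 in present:
            if c1 == c2:
                continue
            term = d_hat(c1, c2)
            inter = term if inter is None else inter + term
    inter = inter / float(len(present) * (len(present) - 1))
    return intra - inter


def cross_entropy_source(scores: Tensor | np.ndarray, label_idx: np.ndarray) -> Tensor:
    """Softmax cross-entropy on source class scores, summed over the batch."""
    z = as_tensor(scores)
    label_idx = np.asarray(label_idx, dtype=np.intp)
    n, c = z.shape
    if label_idx.min(initial=0) < 0 or (label_idx.size and label_idx.max() >= c):
        raise IndexError("label index outside the score width")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), label_idx] = 1.0
    return -(log_softmax(z, axis=1) * Tensor(onehot)).sum()


def gamma_weight(i: int, n: int, N: int, d: int, omega: float = 3.0) -> float:
    """Exponentially annealed regularizer weight over global training progress."""
    if d <= 0 or N <= 0:
        raise ValueError("d and N must be positive")
    return exp(-omega * (i + (n - 1) * d) / (N * d))


@dataclass
class LossBreakdown:
    l_ce: float
    l_cdd: float
    l_reg: float
    gamma: float
    lam: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.l_ce + self.lam * self.l_cdd + self.gamma * self.l_reg


def total_loss(
    l_ce: Tensor | float,
    l_cdd: Tensor | float,
    l_reg: Tensor | float,
    lam: float = 0.1,
    gamma: float = 1.0,
) -> Tensor:
    """Composite objective l = l_ce + lambda * l_cdd + gamma * l_reg."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return as_tensor(l_ce) + lam * as_tensor(l_cdd) + gamma * as_tensor(l_reg)


def lr_schedule(
    initial_lr: float,
    i: int,
    n: int,
    N: int,
    d: int,
    gamma_sched: float = 10.0,
    power: float = 0.75,
) -> float:
    """Inverse-decay learning rate over global training progress (capped at 1)."""
    if initial_lr <= 0 or N <= 0 or d <= 0:
        raise ValueError("initial_lr, N and d must be positive")
    progress = min(1.0, (i + (n - 1) * d) / (N * d))
    return initial_lr * (1.0 + gamma_sched * progress) ** (-power)
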