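"""The two differentiable maps of the tracer: a fully connected feature
extractor f (expression -> embedding) and classifier g (embedding -> class
scores), implemented on the package's numpy autodiff engine.

The extractor is four affine layers (n_genes -> 1024 -> 512 -> 512 -> 200 by
default) with ReLU between hidden layers and inverted dropout on hidden
activations during training.  The classifier is three layers
(embed_dim -> 100 -> n_classes) with one ReLU, returning raw pre-softmax
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .core_io import ExpressionMatrix

__all__ = [
    "NetworkConfig",
    "EmbeddingBatch",
    "Linear",
    "FeatureExtractor",
    "Classifier",
    "build_feature_extractor",
    "build_classifier",
    "embed_and_normalize",
]


@dataclass
class NetworkConfig:
    n_genes: int
    n_classes: int
    hidden_widths_extractor: list[int] = field(default_factory=lambda: [1024, 512, 512])
    embed_dim: int = 200
    hidden_width_classifier: int = 100
    dropout_rate: float = 0.5

    def __post_init__(self):
        widths = [self.n_genes, *self.hidden_widths_extractor, self.embed_dim,
                  self.hidden_width_classifier]
        if any(w < 1 for w in widths):
            raise ValueError("all layer widths must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class EmbeddingBatch:
    """A batch of embedding vectors, optionally row-normalized to unit norm."""

    vectors: np.ndarray
    l2_normalized: bool = False

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("embeddings must be 2-D (batch x embed_dim)")
        if self.l2_normalized:
            norms = np.linalg.norm(self.vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("rows declared L2-normalized are not unit-norm")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


class Linear:
    """Affine layer with uniform fan-in initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(1, n_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def n_parameters(self) -> int:
        return self.W.data.size + self.b.data.size


class _MLP:
    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    @property
    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters]

    def n_parameters(self) -> int:
        return sum(l.n_parameters() for l in self.layers)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters, arrays, strict=True):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)


class FeatureExtractor(_MLP):
    """Expression -> embedding map with dropout-regularized hidden layers."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__([cfg.n_genes, *cfg.hidden_widths_extractor, cfg.embed_dim], rng)
        self.dropout_rate = cfg.dropout_rate

    def forward(
        self,
        x: Tensor | np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        p = self.dropout_rate
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = h.relu()
                if training and p > 0:
                    if rng is None:
                        raise ValueError("training-mode forward needs an rng for dropout")
                    mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * Tensor(mask)
        return h

    __call__ = forward


class Classifier(_MLP):
    """Embedding -> raw class scores (three layers, one ReLU hidden)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__([cfg.embed_dim, cfg.hidden_width_classifier, cfg.n_classes], rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        h = self.layers[0](h).relu()
        return self.layers[1](h)

    def penultimate(self, x: Tensor | np.ndarray) -> Tensor:
        """Hidden-layer activations, used for 2-D diagnostics after training."""
        h = x if isinstance(x, Tensor) else Tensor(x)
        return self.layers[0](h).relu()

    __call__ = forward


def build_feature_extractor(cfg: NetworkConfig, seed: int = 0) -> FeatureExtractor:
    return FeatureExtractor(cfg, np.random.default_rng(seed))


def build_classifier(cfg: NetworkConfig, seed: int = 0) -> Classifier:
    return Classifier(cfg, np.random.default_rng(seed + 1))


def embed_and_normalize(f: FeatureExtractor, matrix: ExpressionMatrix) -> EmbeddingBatch:
    """Embed all cells in evaluation mode and L2-normalize every row."""
    emb = f.forward(Tensor(matrix.values), training=False).data
    norms = np.linalg.norm(emb, axis=1)
    if np.any(norms == 0):
        raise ValueError("a cell embedded to the zero vector; cannot normalize")
    return EmbeddingBatch(emb / norms[:, None], l2_normalized=True)
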