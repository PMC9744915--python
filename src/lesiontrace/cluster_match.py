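"""Domain-specific clustering and cycle-consistent cluster matching.

Source "clusters" are the label-defined class groups (one per class, center =
normalized mean embedding).  The target is clustered by spherical k-means
(cosine assignment, centers renormalized each Lloyd step).  Mutually nearest
cluster centers across domains form candidate pairs; each pair is scored by
the domain consensus score — the fraction of its samples whose nearest
opposite-domain center agrees with the pairing, averaged over the two views —
and the target cluster count k is chosen to maximize the mean consensus
score over matched pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .embedding_net import EmbeddingBatch

log = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ConsensusMatch",
    "MatchedPair",
    "PseudoLabelSet",
    "cosine_similarity",
    "spherical_kmeans",
    "cycle_consistent_match",
    "domain_consensus_score",
    "source_class_assignment",
    "optimize_target_k",
    "assign_pseudo_labels",
]

UNASSIGNED = "unassigned"


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-sample cluster index in [0, k)
    centers: np.ndarray  # k x embed_dim, rows unit-norm
    k: int
    objective: float  # within-cluster pairwise squared deviation
    # per-Lloyd-step values of sum_i (1 - x_i . center[label_i]); this is the
    # quantity spherical Lloyd provably never increases
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.shape[0] != self.k:
            raise ValueError("one center per cluster required")
        if self.labels.min(initial=0) < 0 or (self.labels.size and self.labels.max() >= self.k):
            raise ValueError("cluster index out of range")
        counts = np.bincount(self.labels, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("empty cluster in assignment")
        if not np.allclose(np.linalg.norm(self.centers, axis=1), 1.0, atol=1e-6):
            raise ValueError("cluster centers must be row-normalized")


@dataclass
class MatchedPair:
    source_cluster: int
    target_cluster: int
    source_view_score: float
    target_view_score: float
    consensus_score: float


@dataclass
class ConsensusMatch:
    pairs: list[MatchedPair]
    unmatched_source_clusters: list[int] = field(default_factory=list)
    unmatched_target_clusters: list[int] = field(default_factory=list)

    @property
    def mean_consensus(self) -> float:
        if not self.pairs:
            raise ValueError("no matched pairs")
        return float(np.mean([p.consensus_score for p in self.pairs]))

    def target_to_source(self) -> dict[int, int]:
        return {p.target_cluster: p.source_cluster for p in self.pairs}


@dataclass
class PseudoLabelSet:
    labels: list[str]  # per-target-cell class label or "unassigned"
    source_cluster: np.ndarray  # paired source cluster id, -1 if unassigned
    confidence: np.ndarray  # consensus score of the cell's pair, nan if unassigned

    @property
    def n_unassigned(self) -> int:
        return sum(1 for l in self.labels if l == UNASSIGNED)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _pairwise_objective(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Within-cluster pairwise squared deviation: sum_c (1/|S_c|) sum_{x,y in S_c} ||x-y||^2.

    Uses the identity sum_{x,y in S} ||x-y||^2 = 2|S| * sum_{x in S} ||x - mean||^2.
    """
    total = 0.0
    for c in range(k):
        pts = x[labels == c]
        if len(pts) == 0:
            continue
        mu = pts.mean(axis=0)
        total += 2.0 * float(((pts - mu) ** 2).sum())
    return total


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize zero rows")
    return x / norms


def _farthest_point_seed(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding by cosine distance (greedy farthest point)."""
    n = x.shape[0]
    first = int(rng.integers(n))
    centers = [x[first]]
    min_sim = x @ x[first]
    for _ in range(1, k):
        nxt = int(np.argmin(min_sim))  # least similar to any chosen center
        centers.append(x[nxt])
        min_sim = np.maximum(min_sim, x @ x[nxt])
    return np.array(centers)


def spherical_kmeans(
    emb: EmbeddingBatch,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterAssignment:
    """Lloyd iteration with cosine assignment and renormalized centers.

    The reported objective is the within-cluster pairwise squared deviation.
    Deterministic given the seed; empty clusters are reseeded from the sample
    farthest from its center.
    """
    x = emb.vectors
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    if not emb.l2_normalized:
        x = _normalize_rows(x)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        centers = _farthest_point_seed(x, k, rng)
        labels = np.zeros(n, dtype=np.intp)
        history: list[float] = []
        for _ in range(max_iter):
            sims = x @ centers.T
            labels = np.argmax(sims, axis=1)
            # reseed empty clusters from the sample least similar to its center
            for _attempt in range(k):
                counts = np.bincount(labels, minlength=k)
                empty = np.flatnonzero(counts == 0)
                if empty.size == 0:
                    break
                own_sim = sims[np.arange(n), labels]
                farthest = int(np.argmin(own_sim))
                labels[farthest] = empty[0]
                sims[farthest] = np.inf  # exclude from further reseeding
            else:
                raise RuntimeError("persistent empty cluster after reseeding")
            new_centers = np.array([x[labels == c].mean(axis=0) for c in range(k)])
            centers = _normalize_rows(new_centers)
            sph_obj = float(np.sum(1.0 - (x @ centers.T)[np.arange(n), labels]))
            history.append(sph_obj)
            if len(history) >= 2 and history[-2] - sph_obj <= tol * max(history[-2], 1e-12):
                break
        obj = _pairwise_objective(x, labels, k)
        if best is None or obj < best[0] - 1e-12:
            best = (obj, labels.copy(), centers.copy(), history)
    obj, labels, centers, history = best
    return ClusterAssignment(
        labels=labels, centers=centers, k=k, objective=obj, objective_history=history
    )


def source_class_assignment(emb: EmbeddingBatch, label_idx: np.ndarray, n_classes: int) -> ClusterAssignment:
    """Label-defined source clusters: one per class, center = normalized mean embedding."""
    x = emb.vectors
    label_idx = np.asarray(label_idx, dtype=np.intp)
    present = np.bincount(label_idx, minlength=n_classes)
    if np.any(present == 0):
        raise ValueError("every source class needs at least one cell")
    centers = _normalize_rows(
        np.array([x[label_idx == c].mean(axis=0) for c in range(n_classes)])
    )
    return ClusterAssignment(
        labels=label_idx,
        centers=centers,
        k=n_classes,
        objective=_pairwise_objective(x, label_idx, n_classes),
    )


def cycle_consistent_match(
    src: ClusterAssignment, tgt: ClusterAssignment
) -> list[tuple[int, int]]:
    """Mutual-nearest cluster center pairs (c, k) by cosine similarity.

    Ties are broken toward the lowest index for determinism.
    """
    sims = src.centers @ tgt.centers.T  # centers are unit-norm
    nearest_tgt = np.argmax(sims, axis=1)  # argmax takes the first (lowest) index on ties
    nearest_src = np.argmax(sims, axis=0)
    return [
        (c, int(nearest_tgt[c]))
        for c in range(src.k)
        if int(nearest_src[nearest_tgt[c]]) == c
    ]


def domain_consensus_score(
    pair: tuple[int, int],
    src_samples: np.ndarray,
    tgt_samples: np.ndarray,
    src_centers: np.ndarray,
    tgt_centers: np.ndarray,
) -> tuple[float, float, float]:
    """Two-view consensus score of a matched cluster pair.

    The source view is the fraction of the pair's source samples whose most
    cosine-similar target center is the paired one; the target view is
    symmetric over source centers; the pair score is their mean.
    """
    c, k = pair
    if len(src_samples) == 0 or len(tgt_samples) == 0:
        raise ValueError("consensus score undefined for an empty cluster")
    s_view = float(np.mean(np.argmax(_normalize_rows(src_samples) @ tgt_centers.T, axis=1) == k))
    t_view = float(np.mean(np.argmax(_normalize_rows(tgt_samples) @ src_centers.T, axis=1) == c))
    return s_view, t_view, (s_view + t_view) / 2.0


def _score_match(
    src: ClusterAssignment,
    tgt: ClusterAssignment,
    src_emb: np.ndarray,
    tgt_emb: np.ndarray,
) -> ConsensusMatch:
    candidates = cycle_consistent_match(src, tgt)
    pairs = []
    for c, k in candidates:
        s, t, mean = domain_consensus_score(
            (c, k),
            src_emb[src.labels == c],
            tgt_emb[tgt.labels == k],
            src.centers,
            tgt.centers,
        )
        pairs.append(MatchedPair(c, k, s, t, mean))
    matched_src = {p.source_cluster for p in pairs}
    matched_tgt = {p.target_cluster for p in pairs}
    return ConsensusMatch(
        pairs=pairs,
        unmatched_source_clusters=[c for c in range(src.k) if c not in matched_src],
        unmatched_target_clusters=[k for k in range(tgt.k) if k not in matched_tgt],
    )


def optimize_target_k(
    src: ClusterAssignment,
    src_emb: EmbeddingBatch,
    tgt_emb: EmbeddingBatch,
    k_grid: list[int],
    seed: int = 0,
    **kmeans_kwargs,
) -> tuple[int, ClusterAssignment, ConsensusMatch]:
    """Choose the target cluster count maximizing the mean domain consensus score.

    Every k in the grid is clustered, matched by CCM and scored; ties go to
    the smaller k.  Raises if no k produces any matched pair.
    """
    valid = [k for k in sorted(set(k_grid)) if k <= tgt_emb.n]
    if not valid:
        raise ValueError("k_grid contains no feasible k")
    best = None
    for k in valid:
        try:
            tgt = spherical_kmeans(tgt_emb, k, seed=seed, **kmeans_kwargs)
        except RuntimeError as err:  # degenerate data cannot sustain this k
            log.debug("k=%d infeasible: %s", k, err)
            continue
        match = _score_match(src, tgt, src_emb.vectors, tgt_emb.vectors)
        if not match.pairs:
            continue
        score = match.mean_consensus
        log.debug("k=%d mean consensus %.4f (%d pairs)", k, score, len(match.pairs))
        if best is None or score > best[0] + 1e-12:
            best = (score, k, tgt, match)
    if best is None:
        raise RuntimeError("no domain consensus: no k in the grid produced a matched pair")
    _, k, tgt, match = best
    return k, tgt, match


def assign_pseudo_labels(
    match: ConsensusMatch,
    tgt: ClusterAssignment,
    src_class_of_cluster: dict[int, str],
) -> PseudoLabelSet:
    """Propagate matched source classes to target cells; unmatched clusters
    become "unassigned"."""
    t2s = match.target_to_source()
    conf = {p.target_cluster: p.consensus_score for p in match.pairs}
    labels, src_cluster, confidence = [], [], []
    for cl in tgt.labels:
        cl = int(cl)
        if cl in t2s:
            labels.append(src_class_of_cluster[t2s[cl]])
            src_cluster.append(t2s[cl])
            confidence.append(conf[cl])
        else:
            labels.append(UNASSIGNED)
            src_cluster.append(-1)
            confidence.append(np.nan)
    return PseudoLabelSet(
        labels=labels,
        source_cluster=np.array(src_cluster, dtype=np.intp),
        confidence=np.array(confidence, dtype=np.float64),
    )
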