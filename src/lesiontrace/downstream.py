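"""Downstream analysis: CTC marker genes, gene-set enrichment and 2-D
embedding diagnostics.

Marker detection runs a per-gene two-sided Wilcoxon rank-sum test between
the CTC and primary groups, with the fold change computed on the linear TPM
scale (log2 of the pseudocount-protected ratio of linear means).  Genes pass
the marker filter when raw p < 0.05 and |logFC| > 4; the top up-regulated
markers feed a one-tailed hypergeometric enrichment against user-supplied
gene sets (GMT), Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix
from .objectives import KernelSpec, mmd_squared

__all__ = [
    "identify_markers",
    "top_markers",
    "read_gmt",
    "enrichment_test",
    "embed_2d",
    "domain_distance_mmd",
]

_EPS = 1e-9


def identify_markers(
    ctc: ExpressionMatrix,
    primary: ExpressionMatrix,
    p_cut: float = 0.05,
    lfc_cut: float = 4.0,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-gene differential expression between CTC and primary cells.

    Returns one row per gene with group means (log scale), linear-scale
    log2 fold change (CTC vs primary), test statistic, raw and BH-adjusted
    p-values, direction, and the boolean ``flagged`` marker filter
    (p < p_cut and |logFC| > lfc_cut).
    """
    if ctc.gene_ids != primary.gene_ids:
        raise ValueError("matrices must be gene-aligned")
    if ctc.n_cells < 2 or primary.n_cells < 2:
        raise ValueError("need at least 2 cells per group")
    a, b = ctc.values, primary.values
    if test == "wilcoxon":
        stat, p = stats.ranksums(a, b, axis=0)
    elif test == "t":
        stat, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    # constant genes yield nan statistics; treat them as non-significant
    p = np.where(np.isnan(p), 1.0, p)
    stat = np.where(np.isnan(stat), 0.0, stat)
    lin_a = (2.0 ** a - 1.0).mean(axis=0)
    lin_b = (2.0 ** b - 1.0).mean(axis=0)
    lfc = np.log2((lin_a + _EPS) / (lin_b + _EPS))
    table = pd.DataFrame(
        {
            "gene": ctc.gene_ids,
            "mean_ctc": a.mean(axis=0),
            "mean_primary": b.mean(axis=0),
            "logFC": lfc,
            "statistic": stat,
            "pvalue": p,
            "padj": multipletests(p, method="fdr_bh")[1],
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    )
    table["flagged"] = (table["pvalue"] < p_cut) & (table["logFC"].abs() > lfc_cut)
    return table


def top_markers(table: pd.DataFrame, n: int = 30, direction: str = "up") -> list[str]:
    """Top flagged markers of one direction, ranked by fold change."""
    sub = table[table["flagged"] & (table["direction"] == direction)]
    sub = sub.sort_values(["logFC", "pvalue"], ascending=[False, True])
    return sub["gene"].head(n).tolist()


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def _storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    pi0 = (p > lam).mean() / (1.0 - lam)
    return float(min(max(pi0, 0.0), 1.0)) or 1.0


def enrichment_test(
    query_genes: list[str],
    gene_sets: dict[str, set[str]],
    universe: list[str],
    min_size: int = 10,
    max_size: int = 200,
    p_adj_cut: float = 0.05,
    q_cut: float = 0.2,
) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation test per gene set.

    Sets are first restricted to the universe and filtered to
    [min_size, max_size] genes.  P-values are BH-adjusted, and q-values use
    a Storey-style pi0 estimate on top of the BH ladder.  ``significant``
    marks sets with adjusted p < p_adj_cut and q < q_cut.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes) & universe_set
    if set(query_genes) - universe_set:
        raise ValueError("query genes must be contained in the universe")
    rows = []
    for name, genes in gene_sets.items():
        genes = genes & universe_set
        if not (min_size <= len(genes) <= max_size):
            continue
        overlap = len(query & genes)
        # upper tail: P(X >= overlap) for X ~ Hypergeom(N, K, n)
        p = stats.hypergeom.sf(
            overlap - 1, len(universe_set), len(genes), len(query)
        )
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "set_size": len(genes),
                "query_size": len(query),
                "universe_size": len(universe_set),
                "pvalue": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    p = table["pvalue"].to_numpy()
    table["padj"] = multipletests(p, method="fdr_bh")[1]
    table["qvalue"] = np.minimum(table["padj"] * _storey_pi0(p), 1.0)
    table["significant"] = (table["padj"] < p_adj_cut) & (table["qvalue"] < q_cut)
    return table.sort_values("pvalue").reset_index(drop=True)


def embed_2d(vectors: np.ndarray, method: str = "tsne", seed: int = 0) -> np.ndarray:
    """Embed rows into 2-D with t-SNE or UMAP; deterministic given the seed."""
    vectors = np.asarray(vectors, dtype=np.float64)
    n = vectors.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples for a 2-D embedding")
    if method == "tsne":
        perplexity = min(30.0, (n - 1) / 3.0)
        return TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(vectors)
    if method == "umap":
        import umap  # deferred: heavy import

        return umap.UMAP(n_components=2, random_state=seed).fit_transform(vectors)
    raise ValueError(f"unknown method {method!r}")


def domain_distance_mmd(
    coords_src: np.ndarray,
    coords_tgt: np.ndarray,
    kernel: KernelSpec | None = None,
) -> float:
    """Squared MMD between two 2-D embedding point sets (delegates to the
    training-objective estimator)."""
    return float(mmd_squared(np.asarray(coords_src), np.asarray(coords_tgt), kernel).item())
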