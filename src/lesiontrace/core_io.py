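"""Expression-matrix ingestion, log2(TPM+1) normalization and gene alignment.

All matrices are oriented cells x genes internally.  Two on-disk formats are
supported: delimited text (header row of gene ids, first column cell ids) and
MatrixMarket coordinate triplets with ``genes.txt`` / ``barcodes.txt``
sidecars in the same directory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DomainDataset",
    "read_expression_matrix",
    "write_expression_matrix",
    "normalize_log2_tpm",
    "align_genes",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen, dups = set(), []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {', '.join(sorted(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers.

    When ``normalized`` is set the values are on the log2(TPM+1) scale and
    must be finite and non-negative.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.normalized:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("normalized matrix contains non-finite values")
            if np.any(self.values < 0):
                raise ValueError("normalized matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols], list(genes), list(self.cell_ids), self.normalized
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class DomainDataset:
    """An expression matrix with a domain tag and (for the source) labels."""

    matrix: ExpressionMatrix
    domain: str
    labels: list[str] | None = None
    class_catalog: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.domain not in ("source", "target"):
            raise ValueError("domain must be 'source' or 'target'")
        if self.domain == "source" and self.labels is None:
            raise ValueError("source datasets must carry labels")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != self.matrix.n_cells:
                raise ValueError("one label per cell required")
            if not self.class_catalog:
                # first-appearance order keeps class indices reproducible
                self.class_catalog = list(dict.fromkeys(self.labels))
            unknown = set(self.labels) - set(self.class_catalog)
            if unknown:
                raise ValueError(f"labels outside class catalog: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def label_indices(self) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.class_catalog)}
        return np.array([pos[l] for l in self.labels], dtype=np.intp)


def read_expression_matrix(
    path: str | Path,
    format: str = "delimited",
    orientation: str = "cells-by-genes",
) -> ExpressionMatrix:
    """Read a matrix from delimited text or MatrixMarket triplets.

    ``orientation`` describes the file layout; the returned matrix is always
    cells x genes (a genes-by-cells file is transposed on read).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("cells-by-genes", "genes-by-cells"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.select_dtypes(exclude=[np.number])
        if bad.shape[1]:
            col = bad.columns[0]
            row = bad[col][pd.to_numeric(bad[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric entry at row {row!r}, column {col!r}")
        values = df.to_numpy(dtype=np.float64)
        row_ids, col_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    elif format == "matrixmarket-triplet":
        folder = path.parent
        genes_file, cells_file = folder / "genes.txt", folder / "barcodes.txt"
        for f in (genes_file, cells_file):
            if not f.exists():
                raise FileNotFoundError(f"missing MatrixMarket sidecar {f}")
        mat = scipy.io.mmread(path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        col_ids = [l.strip() for l in genes_file.read_text().splitlines() if l.strip()]
        row_ids = [l.strip() for l in cells_file.read_text().splitlines() if l.strip()]
        if orientation == "genes-by-cells":
            row_ids, col_ids = col_ids, row_ids
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "genes-by-cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, gene_ids=col_ids, cell_ids=row_ids)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "delimited"
) -> None:
    path = Path(path)
    if format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        m.to_dataframe().to_csv(path, sep=sep)
    elif format == "matrixmarket-triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        (path.parent / "genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        (path.parent / "barcodes.txt").write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def normalize_log2_tpm(
    m: ExpressionMatrix,
    input_scale: str = "tpm",
    gene_lengths: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Transform expression to log2(TPM+1).

    ``input_scale='tpm'`` log-transforms values already on the TPM scale;
    ``'raw_counts'`` first converts counts to TPM with per-gene lengths (bp).
    Already-normalized matrices are returned unchanged with a warning.
    """
    if m.normalized:
        warnings.warn("matrix already normalized; returning unchanged", stacklevel=2)
        return m
    if np.any(m.values < 0):
        raise ValueError("negative expression values cannot be normalized")
    if input_scale == "tpm":
        tpm = m.values
    elif input_scale == "raw_counts":
        if gene_lengths is None:
            raise ValueError("raw counts require gene_lengths")
        gene_lengths = np.asarray(gene_lengths, dtype=np.float64)
        if gene_lengths.shape != (m.n_genes,) or np.any(gene_lengths <= 0):
            raise ValueError("gene_lengths must be positive, one per gene")
        rpk = m.values / (gene_lengths / 1e3)
        denom = rpk.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0  # empty cells stay all-zero
        tpm = rpk / denom * 1e6
    else:
        raise ValueError(f"unknown input_scale {input_scale!r}")
    return ExpressionMatrix(
        np.log2(tpm + 1.0), list(m.gene_ids), list(m.cell_ids), normalized=True
    )


def align_genes(
    source: DomainDataset,
    target: DomainDataset,
    min_overlap: float = 0.30,
) -> tuple[DomainDataset, DomainDataset]:
    """Restrict both datasets to shared genes, ordered as in the source.

    The overlap fraction is reported relative to each gene list; if the
    smaller fraction falls below ``min_overlap`` the reference is judged
    incompatible and an error is raised.
    """
    for d in (source, target):
        if not d.matrix.normalized:
            raise ValueError("align_genes requires normalized matrices")
    tgt_genes = set(target.matrix.gene_ids)
    shared = [g for g in source.matrix.gene_ids if g in tgt_genes]
    frac_src = len(shared) / source.matrix.n_genes
    frac_tgt = len(shared) / target.matrix.n_genes
    log.info(
        "gene overlap: %d genes (%.3f of source, %.3f of target)",
        len(shared), frac_src, frac_tgt,
    )
    if min(frac_src, frac_tgt) < min_overlap:
        raise ValueError(
            f"gene overlap {min(frac_src, frac_tgt):.3f} below floor {min_overlap}; "
            "the reference feature space likely does not match the query"
        )
    out = []
    for d in (source, target):
        out.append(
            DomainDataset(
                matrix=d.matrix.subset_genes(shared),
                domain=d.domain,
                labels=d.labels,
                class_catalog=list(d.class_catalog),
            )
        )
    return out[0], out[1]
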