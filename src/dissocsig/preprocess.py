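"""Cell-level QC filtering, CP10K log-normalisation, and the
subclustering-eligibility rule.

Normalisation follows the single-cell toolkit convention downstream module
scores assume: counts scaled to ``scale`` (default 10,000) per cell, then
``ln(1 + x)``. Raw counts are never mutated; a new sparse matrix is
returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CellAnnotations, CountMatrix, NormalizedMatrix

DEFAULT_MITO_PREFIXES = ("mt-", "MT-")


@dataclass
class QCThresholds:
    """Per-cell QC thresholds; all are required (no hidden defaults).

    A cell is kept iff genes_detected >= min_genes_per_cell,
    min_umis <= total UMIs <= max_umis, and mito fraction <= max_mito_fraction.
    """

    min_genes_per_cell: int
    min_umis: int
    max_umis: float
    max_mito_fraction: float

    def __post_init__(self) -> None:
        if self.min_umis > self.max_umis:
            raise ValidationError("min_umis must be <= max_umis")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0, 1]")
        if self.min_genes_per_cell < 0 or self.min_umis < 0:
            raise ValidationError("QC thresholds must be non-negative")


def mito_gene_mask(
    genes: Sequence[str], prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES
) -> np.ndarray:
    """Boolean mask of mitochondrial genes by case-insensitive prefix match."""
    lowered = tuple(p.lower() for p in prefixes)
    return np.array([g.lower().startswith(lowered) for g in genes], dtype=bool)


def cell_qc_metrics(
    m: CountMatrix, mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES
) -> pd.DataFrame:
    """Per-cell genes detected, total UMIs, and mito fraction."""
    csc = m.counts.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel()
    genes_per_cell = np.diff(csc.indptr)  # stored entries are >= 1
    mito = mito_gene_mask(m.genes, mito_prefixes)
    mito_counts = np.asarray(csc[mito, :].sum(axis=0)).ravel()
    frac = mito_counts / np.maximum(totals, 1)
    return pd.DataFrame(
        {
            "barcode": m.barcodes,
            "genes_detected": genes_per_cell,
            "total_umis": totals,
            "mito_fraction": frac,
        }
    ).set_index("barcode")


def qc_filter(
    m: CountMatrix,
    ann: CellAnnotations,
    t: QCThresholds,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
) -> tuple[CountMatrix, CellAnnotations, pd.DataFrame]:
    """Remove cells failing any QC criterion.

    Returns the filtered matrix/annotations and a report of cells removed
    per criterion and per sample (a cell failing several criteria is counted
    under each). The gene set is unchanged. Raises if no cell survives.
    """
    metrics = cell_qc_metrics(m, mito_prefixes)
    fails = pd.DataFrame(
        {
            "low_genes": metrics["genes_detected"] < t.min_genes_per_cell,
            "low_umis": metrics["total_umis"] < t.min_umis,
            "high_umis": metrics["total_umis"] > t.max_umis,
            "high_mito": metrics["mito_fraction"] > t.max_mito_fraction,
        },
        index=metrics.index,
    )
    keep = ~fails.any(axis=1)
    if not keep.any():
        raise ValidationError(
            "QC removed every cell; review the thresholds against the "
            "per-cell metrics"
        )
    sample_of = ann.subset(m.barcodes).df["sample_id"]
    report = fails.groupby(sample_of.to_numpy()).sum()
    report.index.name = "sample_id"
    report["n_input"] = fails.groupby(sample_of.to_numpy()).size()
    report["n_removed"] = (~keep).groupby(sample_of.to_numpy()).sum()
    report["n_kept"] = report["n_input"] - report["n_removed"]
    report = report.reset_index()

    keep_arr = keep.to_numpy()
    m2 = m.subset_cells(keep_arr)
    ann2 = ann.subset(m2.barcodes)
    return m2, ann2, report


def log_normalize(m: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """CP-``scale`` log-normalisation: value = ln(1 + scale * count / cell total).

    Sparse zeros are preserved exactly. Cells with zero total counts are an
    error (run QC first).
    """
    csc = m.counts.tocsc().astype(np.float64)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cell {m.barcodes[zero[0]]!r} has zero total counts; apply QC first"
        )
    per_entry_total = np.repeat(totals, np.diff(csc.indptr))
    csc.data = np.log1p(scale * csc.data / per_entry_total)
    return NormalizedMatrix(list(m.genes), list(m.barcodes), csc.tocsr())


def class_eligibility(
    ann: CellAnnotations, min_per_replicate: int = 80, min_total: int = 300
) -> list[str]:
    """Cell classes eligible for subclustering.

    A class qualifies only with strictly more than ``min_per_replicate``
    cells in every replicate (sample) and strictly more than ``min_total``
    cells overall; a class absent from any replicate is ineligible.
    """
    if "cell_class" not in ann.df.columns:
        raise ValidationError("annotations have no 'cell_class' column")
    tab = pd.crosstab(ann.df["cell_class"], ann.df["sample_id"])
    eligible = tab.index[
        (tab.to_numpy() > min_per_replicate).all(axis=1)
        & (tab.sum(axis=1).to_numpy() > min_total)
    ]
    return sorted(eligible)
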