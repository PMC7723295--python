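"""Gene/cell quality-control filters and log-normalization.

Genes are removed when detected in fewer cells than *either* an absolute
floor (default 10 cells) or a fraction of all cells (default 0.2%) — i.e.
below the maximum of the two bounds, the only reading under which both
numbers can bind.  Cells are removed when their mitochondrial count
fraction exceeds a cap (default 2%), mitochondrial genes being recognised
by an ID prefix (default ``MT-``).  Normalization is the usual
library-size log transform: log(1 + count * scale / cell_total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import CountMatrix, NormMatrix

__all__ = ["QCParams", "filter_genes", "filter_cells_mito", "lognormalize", "run_qc"]


@dataclass
class QCParams:
    """Thresholds for the QC filters.

    min_cell_frac : gene kept only if detected in at least this fraction of cells
    min_cells     : ... and in at least this many cells (the binding bound is
                    ``max(min_cell_frac * n_cells, min_cells)``)
    max_mito_frac : cell removed if mito counts / total counts exceed this
    mito_prefix   : gene-ID prefix marking mitochondrial genes
    scale_total   : per-cell count target for normalization
    detect_min_count : a gene counts as "detected" in a cell at >= this count
    """

    min_cell_frac: float = 0.002
    min_cells: int = 10
    max_mito_frac: float = 0.02
    mito_prefix: str = "MT-"
    scale_total: float = 1e4
    detect_min_count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_cell_frac <= 1.0:
            raise ValueError("min_cell_frac must be in [0, 1]")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in [0, 1]")
        if self.min_cells < 0:
            raise ValueError("min_cells must be >= 0")
        if self.scale_total <= 0:
            raise ValueError("scale_total must be > 0")


def filter_genes(
    cm: CountMatrix, p: QCParams | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove genes detected in too few cells.

    Returns the filtered matrix and a removal report (one row per removed
    gene: detection count, the binding threshold, and which rule fired).
    """
    p = p or QCParams()
    detected = np.asarray(
        (cm.counts >= p.detect_min_count).sum(axis=1)
    ).ravel()
    frac_bound = p.min_cell_frac * cm.n_cells
    threshold = max(frac_bound, float(p.min_cells))
    keep = detected >= threshold
    rule = "fraction" if frac_bound > p.min_cells else "absolute"
    report = pd.DataFrame(
        {
            "gene": [g for g, k in zip(cm.gene_ids, keep) if not k],
            "n_cells_detected": detected[~keep],
            "threshold": threshold,
            "rule": rule,
        }
    )
    return cm.subset_genes(keep), report


def filter_cells_mito(
    cm: CountMatrix, p: QCParams | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells with a high mitochondrial count fraction.

    Zero-total cells are removed too and reported separately (reason
    ``zero_total``); without mito-prefixed genes in the matrix no cell is
    removed by the mito rule.
    """
    p = p or QCParams()
    totals = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    is_mito = np.array([g.startswith(p.mito_prefix) for g in cm.gene_ids])
    mito = (
        np.asarray(cm.counts[is_mito, :].sum(axis=0)).ravel().astype(float)
        if is_mito.any()
        else np.zeros(cm.n_cells)
    )
    zero_total = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero_total, 0.0, mito / np.where(zero_total, 1.0, totals))
    too_mito = frac > p.max_mito_frac
    keep = ~(zero_total | too_mito)
    removed = np.flatnonzero(~keep)
    report = pd.DataFrame(
        {
            "barcode": [cm.barcodes[i] for i in removed],
            "mito_frac": frac[removed],
            "total_counts": totals[removed].astype(int),
            "reason": ["zero_total" if zero_total[i] else "mito" for i in removed],
        }
    )
    return cm.subset_cells(keep), report


def lognormalize(cm: CountMatrix, p: QCParams | None = None) -> NormMatrix:
    """log(1 + count * scale_total / cell_total); zeros stay zero.

    Requires every cell to have at least one count (run the filters first).
    """
    p = p or QCParams()
    totals = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError(
            f"{int((totals == 0).sum())} cell(s) with zero total counts; "
            "run filter_cells_mito first"
        )
    csc = cm.counts.tocsc().astype(float)
    scale = p.scale_total / totals
    # scale each cell (column) then log1p on stored entries only
    csc = csc @ sp.diags(scale)
    csc.data = np.log1p(csc.data)
    return NormMatrix(list(cm.gene_ids), list(cm.barcodes), csc.tocsr())


def run_qc(
    cm: CountMatrix, p: QCParams | None = None, genes_first: bool = True
) -> tuple[NormMatrix, dict[str, pd.DataFrame]]:
    """Full QC chain: gene filter and mito cell filter (genes first by
    default; ``genes_first=False`` swaps the order) then log-normalize."""
    p = p or QCParams()
    if genes_first:
        cm, gene_report = filter_genes(cm, p)
        cm, cell_report = filter_cells_mito(cm, p)
    else:
        cm, cell_report = filter_cells_mito(cm, p)
        cm, gene_report = filter_genes(cm, p)
    return lognormalize(cm, p), {"genes": gene_report, "cells": cell_report}
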