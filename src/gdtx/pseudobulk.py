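"""Pseudo-bulk aggregation and cross-tissue comparison.

A pseudo-bulk profile sums each gene's counts over all cells of a
cluster, giving one bulk-like expression vector per cluster.  Cross-tissue
comparison scales each profile to counts-per-million (removing
cluster-size differences) before taking per-gene log2 ratios with a
pseudocount of 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_core import CountMatrix, NormMatrix

logger = logging.getLogger(__name__)

__all__ = ["pseudobulk", "average_expression", "cpm", "cross_tissue_compare"]


def pseudobulk(cm: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Clusters x genes matrix of summed counts; conserves total counts.

    Every barcode must carry a cluster label.
    """
    if "cluster" not in meta.columns:
        raise ValueError("meta must have a 'cluster' column")
    missing = [b for b in cm.barcodes if b not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} barcode(s) missing from meta, "
                         f"e.g. {missing[0]!r}")
    labels = meta.loc[cm.barcodes, "cluster"]
    if labels.isna().any():
        raise ValueError("unlabeled barcodes present")
    clusters = sorted(set(labels))
    rows = {}
    dense_cols = {cl: np.flatnonzero((labels == cl).to_numpy()) for cl in clusters}
    for cl in clusters:
        rows[cl] = np.asarray(
            cm.counts[:, dense_cols[cl]].sum(axis=1)
        ).ravel().astype(np.int64)
    return pd.DataFrame(rows, index=pd.Index(cm.gene_ids, name="gene")).T


def average_expression(
    nm: NormMatrix, meta: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Clusters x genes table of mean normalized expression for the listed
    genes; absent genes are dropped with a warning."""
    if "cluster" not in meta.columns:
        raise ValueError("meta must have a 'cluster' column")
    gi = nm.gene_index()
    present = [g for g in genes if g in gi]
    absent = [g for g in genes if g not in gi]
    if absent:
        logger.warning("%d gene(s) absent, dropped: %s", len(absent),
                       ", ".join(absent[:10]))
    labels = meta.loc[nm.barcodes, "cluster"]
    dense = nm.to_dense()
    clusters = sorted(set(labels.dropna()))
    out = pd.DataFrame(index=clusters, columns=present, dtype=float)
    for cl in clusters:
        cols = np.flatnonzero((labels == cl).to_numpy())
        for g in present:
            out.loc[cl, g] = float(dense[gi[g], cols].mean())
    return out


def cpm(pb: pd.DataFrame) -> pd.DataFrame:
    """Scale each pseudo-bulk profile (row) to counts per million."""
    totals = pb.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise ValueError("cluster with zero total counts")
    return pb.div(totals, axis=0) * 1e6


def cross_tissue_compare(
    pb_a: pd.DataFrame, pb_b: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene log2 CPM ratios between every cluster pair of two tissues.

    Both pseudo-bulks are CPM-scaled, then for every (cluster in a,
    cluster in b) pair and every shared listed gene the table reports
    log2((cpm_a + 1) / (cpm_b + 1)).  Antisymmetric under swapping a and b.
    """
    shared = [g for g in (genes if genes is not None else pb_a.columns)
              if g in pb_a.columns and g in pb_b.columns]
    if genes is not None and not shared:
        raise ValueError("no listed gene shared between the two pseudo-bulks")
    a = cpm(pb_a)[shared]
    b = cpm(pb_b)[shared]
    rows = []
    for ca in a.index:
        for cb in b.index:
            ratio = np.log2((a.loc[ca].to_numpy() + 1.0)
                            / (b.loc[cb].to_numpy() + 1.0))
            for g, r in zip(shared, ratio):
                rows.append({"gene": g, "cluster_a": ca, "cluster_b": cb,
                             "log2_ratio": float(r)})
    return pd.DataFrame(rows)
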