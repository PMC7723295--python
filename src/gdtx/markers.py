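"""Cluster marker extraction, signature construction, and clustering
robustness statistics.

Markers are found by a per-gene two-sided Wilcoxon rank-sum test of the
target cluster against a background cluster set on log-normalized values,
with Benjamini-Hochberg adjustment over tested genes.  A hurdle-model
contrast would weight the detection and expression components separately;
here the signatures are consumed downstream only as (gene, logFC) lists,
for which the rank-sum contrast with a log-ratio-of-means effect size is
an adequate, dependency-free substitute.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .io_core import GeneSignature, NormMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "rank_sum_markers",
    "build_signature",
    "signatures_for_clusters",
    "adjusted_rand_index",
    "subsample_consistency",
    "phase_composition",
    "LOG_FC_EPS",
]

LOG_FC_EPS = 1e-9  # pseudomean added before the log ratio, avoids log(0)


def _cluster_mask(meta: pd.DataFrame, barcodes: list[str], clusters: set[str]):
    labels = meta.loc[barcodes, "cluster"]
    return labels.isin(clusters).to_numpy()


def rank_sum_markers(
    nm: NormMatrix,
    meta: pd.DataFrame,
    target: str,
    background: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene rank-sum contrast of ``target`` cluster vs ``background``.

    ``meta`` must carry a ``cluster`` column indexed by barcode;
    ``background`` defaults to every other cluster.  Returns a table with
    columns gene, cluster, log_fc, p, q, pct_in, pct_out where ``log_fc``
    is the natural-log ratio of (pseudocounted) mean normalized expression
    and ``q`` is BH-adjusted across genes.
    """
    if "cluster" not in meta.columns:
        raise ValueError("meta must have a 'cluster' column")
    all_clusters = set(meta.loc[nm.barcodes, "cluster"].dropna())
    if background is None:
        background = all_clusters - {target}
    background = set(background)
    if target in background:
        raise ValueError("target cluster cannot be in the background set")
    if not background:
        raise ValueError("background cluster set is empty")

    in_mask = _cluster_mask(meta, nm.barcodes, {target})
    out_mask = _cluster_mask(meta, nm.barcodes, background)
    if in_mask.sum() == 0:
        raise ValueError(f"target cluster {target!r} has no cells")
    if out_mask.sum() == 0:
        raise ValueError("background clusters have no cells")

    dense = nm.to_dense()
    x = dense[:, in_mask]
    y = dense[:, out_mask]

    mean_in = x.mean(axis=1)
    mean_out = y.mean(axis=1)
    log_fc = np.log(mean_in + LOG_FC_EPS) - np.log(mean_out + LOG_FC_EPS)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant across both groups carry no information: p = 1
    constant = (x.min(axis=1) == x.max(axis=1)) & (y.min(axis=1) == y.max(axis=1)) \
        & (x[:, 0] == y[:, 0])
    p[constant] = 1.0
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene": nm.gene_ids,
            "cluster": target,
            "log_fc": np.where(constant, 0.0, log_fc),
            "p": p,
            "q": q,
            "pct_in": (x > 0).mean(axis=1),
            "pct_out": (y > 0).mean(axis=1),
        }
    )


def build_signature(
    mt: pd.DataFrame,
    q_max: float = 0.05,
    lfc_min: float = 0.25,
    max_genes: int | None = None,
    name: str | None = None,
) -> GeneSignature:
    """Turn a marker table into an up/down :class:`GeneSignature`.

    Up side: q <= q_max and log_fc >= lfc_min; down side: q <= q_max and
    log_fc <= -lfc_min; weights are the log fold changes.  Each side is
    truncated to ``max_genes`` by |log_fc| descending (ties broken by gene
    ID).  An empty signature is legal and returned with a warning.
    """
    sig_name = name or (str(mt["cluster"].iloc[0]) if len(mt) else "signature")
    passing = mt[mt["q"] <= q_max]
    up_rows = passing[passing["log_fc"] >= lfc_min]
    down_rows = passing[passing["log_fc"] <= -lfc_min]

    def _truncate(rows: pd.DataFrame) -> pd.DataFrame:
        rows = rows.assign(_abs=rows["log_fc"].abs()).sort_values(
            ["_abs", "gene"], ascending=[False, True], kind="mergesort"
        )
        return rows.head(max_genes) if max_genes is not None else rows

    up = {r.gene: float(r.log_fc) for r in _truncate(up_rows).itertuples()}
    down = {r.gene: float(r.log_fc) for r in _truncate(down_rows).itertuples()}
    if not up and not down:
        logger.warning("signature %r is empty under q<=%g, |lfc|>=%g",
                       sig_name, q_max, lfc_min)
    return GeneSignature(sig_name, up, down)


def signatures_for_clusters(
    nm: NormMatrix,
    meta: pd.DataFrame,
    clusters: list[str] | None = None,
    background: set[str] | None = None,
    q_max: float = 0.05,
    lfc_min: float = 0.25,
    max_genes: int | None = None,
) -> tuple[list[GeneSignature], pd.DataFrame]:
    """Marker tables and signatures for every listed cluster (default: all)."""
    if clusters is None:
        clusters = sorted(set(meta.loc[nm.barcodes, "cluster"].dropna()))
    tables, sigs = [], []
    for cl in clusters:
        bg = background - {cl} if background else None
        mt = rank_sum_markers(nm, meta, cl, bg)
        tables.append(mt)
        sigs.append(build_signature(mt, q_max, lfc_min, max_genes, name=cl))
    return sigs, pd.concat(tables, ignore_index=True)


def adjusted_rand_index(a, b) -> float:
    """Permutation-model adjusted Rand index between two labelings of the
    same items (1 = identical up to renaming, ~0 = independent)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    return float(adjusted_rand_score(a, b))


def subsample_consistency(
    nm: NormMatrix,
    meta: pd.DataFrame,
    proportions: list[float],
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Clustering stability under cell subsampling.

    For each proportion, cells are repeatedly sampled without replacement
    and each sampled cell is assigned to the nearest full-data cluster
    centroid (Euclidean distance on normalized values); accuracy is the
    fraction agreeing with the original label.  Each cell is excluded from
    its own cluster's centroid (leave-one-out), otherwise the cell's own
    contribution inflates agreement even for unstructured data.
    Proportions yielding fewer cells than clusters are skipped with a
    warning.
    """
    labels = meta.loc[nm.barcodes, "cluster"].to_numpy()
    cluster_names = sorted(set(labels))
    dense = nm.to_dense().T  # cells x genes
    sums = np.stack([dense[labels == cl].sum(axis=0) for cl in cluster_names])
    sizes = np.array([(labels == cl).sum() for cl in cluster_names])
    if (sizes < 2).any():
        raise ValueError("every cluster needs >= 2 cells for leave-one-out")
    centroids = sums / sizes[:, None]
    rng = np.random.default_rng(seed)
    rows = []
    for prop in proportions:
        if not 0.0 < prop <= 1.0:
            raise ValueError(f"proportion {prop} outside (0, 1]")
        n_sub = int(round(prop * nm.n_cells))
        if n_sub < len(cluster_names):
            logger.warning("proportion %g gives %d cells < %d clusters; skipped",
                           prop, n_sub, len(cluster_names))
            continue
        accs = []
        name_to_row = {cl: i for i, cl in enumerate(cluster_names)}
        for _ in range(n_reps):
            idx = rng.choice(nm.n_cells, size=n_sub, replace=False)
            sub = dense[idx]
            d2 = ((sub[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            # leave-one-out: recompute distance to the cell's own centroid
            for j, cell in enumerate(idx):
                r = name_to_row[labels[cell]]
                loo = (sums[r] - dense[cell]) / (sizes[r] - 1)
                d2[j, r] = ((dense[cell] - loo) ** 2).sum()
            assigned = np.asarray(cluster_names)[d2.argmin(axis=1)]
            accs.append(float((assigned == labels[idx]).mean()))
        rows.append(
            {
                "proportion": prop,
                "n_cells": n_sub,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if n_reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def phase_composition(meta: pd.DataFrame) -> pd.DataFrame:
    """Cluster x cell-cycle-phase fraction table (rows sum to 1).

    Empty clusters do not appear; missing phase labels are an error since
    phases are pipeline inputs here.
    """
    for col in ("cluster", "phase"):
        if col not in meta.columns:
            raise ValueError(f"meta must have a {col!r} column")
    if meta["phase"].isna().any():
        raise ValueError("phase missing for some cells")
    tab = pd.crosstab(meta["cluster"], meta["phase"], normalize="index")
    for ph in ("G1", "S", "G2M"):
        if ph not in tab.columns:
            tab[ph] = 0.0
    return tab[["G1", "S", "G2M"]]
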