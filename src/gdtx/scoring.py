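"""Per-cell signature and gene-set enrichment scoring.

The signature score is the equal-weight up/down enrichment score: after
per-gene min-max normalization across cells, a cell's score for a
signature is the mean normalized expression of the signature's
up-regulated genes minus that of its down-regulated genes.  A positive
score marks a cell expressing the up genes and not the down genes; on a
min-max normalized matrix the score is bounded in [-1, 1].  Curated-set
scores are the plain mean over the set's genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_core import CuratedGeneSet, GeneSignature, NormMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "minmax_normalize_genes",
    "scid_score",
    "geneset_score",
    "score_signatures",
    "score_gene_sets",
    "threshold_scores",
    "score_specificity",
]


def minmax_normalize_genes(nm: NormMatrix) -> NormMatrix:
    """Scale each gene to [0, 1] across cells: (x - min) / (max - min).

    Constant genes map to 0 everywhere (declared convention; they carry no
    between-cell information).  Idempotent.  Requires >= 2 cells.
    """
    if nm.n_cells < 2:
        raise ValueError("min-max normalization needs at least 2 cells")
    dense = nm.to_dense().astype(float)
    mins = dense.min(axis=1, keepdims=True)
    maxs = dense.max(axis=1, keepdims=True)
    span = maxs - mins
    out = np.zeros_like(dense)
    nonconst = span.ravel() > 0
    out[nonconst] = (dense[nonconst] - mins[nonconst]) / span[nonconst]
    return NormMatrix(list(nm.gene_ids), list(nm.barcodes), out)


def _present_rows(nm: NormMatrix, genes, what: str) -> list[int]:
    gi = nm.gene_index()
    present = [gi[g] for g in genes if g in gi]
    missing = [g for g in genes if g not in gi]
    if missing:
        logger.warning("%s: %d gene(s) absent from matrix, dropped: %s",
                       what, len(missing), ", ".join(sorted(missing)[:10]))
    return present


def scid_score(nmm: NormMatrix, sig: GeneSignature) -> pd.Series:
    """Equal-weight up/down score per cell: mean(up genes) - mean(down genes).

    ``nmm`` must already be min-max normalized.  Signature genes absent
    from the matrix are dropped with a warning; an empty down side
    contributes 0.  Errors if no signature gene is present.
    """
    up_rows = _present_rows(nmm, sig.up, f"signature {sig.name!r} (up)")
    down_rows = _present_rows(nmm, sig.down, f"signature {sig.name!r} (down)")
    if not up_rows and not down_rows:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    dense = nmm.to_dense()
    score = np.zeros(nmm.n_cells)
    if up_rows:
        score += dense[up_rows].mean(axis=0)
    if down_rows:
        score -= dense[down_rows].mean(axis=0)
    return pd.Series(score, index=nmm.barcodes, name=sig.name)


def geneset_score(nmm: NormMatrix, gs: CuratedGeneSet) -> pd.Series:
    """Mean normalized expression of a curated set's (present) genes per cell."""
    rows = _present_rows(nmm, sorted(gs.genes), f"gene set {gs.name!r}")
    if not rows:
        raise ValueError(f"no gene of set {gs.name!r} present in matrix")
    return pd.Series(nmm.to_dense()[rows].mean(axis=0), index=nmm.barcodes,
                     name=gs.name)


def score_signatures(nmm: NormMatrix, sigs) -> pd.DataFrame:
    """Cells x signatures score table."""
    return pd.DataFrame({s.name: scid_score(nmm, s) for s in sigs})


def score_gene_sets(nmm: NormMatrix, sets) -> pd.DataFrame:
    """Cells x curated-sets score table."""
    return pd.DataFrame({s.name: geneset_score(nmm, s) for s in sets})


def _two_means_split(values: np.ndarray) -> float:
    """Exact 1-D two-cluster split: the boundary value maximising the
    between-cluster separation (minimum within-cluster SSE), found by
    enumerating all split points on the sorted values.  Returns the upper
    bound of the lower cluster; ties at the boundary go to the lower one."""
    srt = np.sort(values)
    n = len(srt)
    if n < 2 or srt[0] == srt[-1]:
        return srt[-1]  # no structure: everything lower
    cum = np.cumsum(srt)
    cum2 = np.cumsum(srt ** 2)
    best_sse, best_i = np.inf, 1
    for i in range(1, n):  # lower = srt[:i], upper = srt[i:]
        if srt[i] == srt[i - 1]:
            continue  # a tie cannot straddle the boundary
        sse_lo = cum2[i - 1] - cum[i - 1] ** 2 / i
        sse_hi = (cum2[-1] - cum2[i - 1]) - (cum[-1] - cum[i - 1]) ** 2 / (n - i)
        sse = sse_lo + sse_hi
        if sse < best_sse:
            best_sse, best_i = sse, i
    return srt[best_i - 1]


def threshold_scores(
    st: pd.Series, method: str = "fixed_zero", param: float | None = None
) -> set[str]:
    """Select score-positive ids.

    fixed_zero : positive iff score > 0 (default for up/down signatures)
    quantile   : positive iff score > the ``param``-quantile of the scores
    two_means  : 1-D two-cluster split; positive = upper cluster, boundary
                 ties assigned to the lower cluster
    """
    values = st.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    if method == "fixed_zero":
        mask = values > 0
    elif method == "quantile":
        if param is None or not 0.0 <= param <= 1.0:
            raise ValueError("quantile method needs param in [0, 1]")
        mask = values > np.quantile(values, param)
    elif method == "two_means":
        mask = values > _two_means_split(values)
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return set(st.index[mask])


def score_specificity(st: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cluster comparison of one score: two-sided rank-sum test
    per cluster pair, BH-adjusted across pairs.

    Clusters with fewer than 2 scored cells are excluded with a warning;
    with fewer than two usable clusters the table is empty.
    """
    if "cluster" not in meta.columns:
        raise ValueError("meta must have a 'cluster' column")
    labels = meta.loc[st.index, "cluster"]
    groups = {}
    for cl, vals in st.groupby(labels):
        if len(vals) < 2:
            logger.warning("cluster %r has <2 cells; excluded", cl)
            continue
        groups[cl] = vals.to_numpy()
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = scipy.stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided"
                )
            p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
            rows.append({
                "cluster_a": a, "cluster_b": b,
                "mean_a": float(groups[a].mean()),
                "mean_b": float(groups[b].mean()),
                "statistic": float(res.statistic), "p": p,
            })
    out = pd.DataFrame(rows,
                       columns=["cluster_a", "cluster_b", "mean_a", "mean_b",
                                "statistic", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out
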