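"""Bulk-cohort survival stratification by signature enrichment.

The chain mirrors the standard tumour-cohort workflow: keep samples in a
tumour-purity window (default the closed interval [0.6, 0.7], wide enough
to retain immune infiltrate but not so impure that non-tumour signal
dominates), score each sample as the logFC-weighted average of a
signature's genes on per-gene z-scored expression, split the cohort into
bottom and top thirds by score, and compare the two groups with a
Kaplan-Meier estimate and a 1-df log-rank test.  The estimator and test
are implemented here directly.

The Kaplan-Meier product-limit estimate steps only at event times:
S(t) = prod_{t_i <= t} (1 - d_i / n_i) with d_i events and n_i at risk at
t_i; censored observations leave the curve flat but shrink the risk set.
The log-rank statistic accumulates, over event times of the pooled
sample, the group-1 observed-minus-expected event count under the
hypergeometric model, and refers (O - E)^2 / V to a chi-square with 1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import BulkSample, GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "LogRankResult",
    "purity_filter",
    "bulk_signature_score",
    "cytolytic_score",
    "tertile_groups",
    "km_curve",
    "logrank_test",
    "survival_pipeline",
    "group_covariate_compare",
    "cohort_expression",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate: survival value after each distinct
    event time, with the at-risk count just before it."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S = 1 before first event."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    n1: int
    n2: int
    df: int = 1


def purity_filter(
    samples: Sequence[BulkSample], lo: float = 0.6, hi: float = 0.7
) -> list[BulkSample]:
    """Keep samples with purity in the closed interval [lo, hi]."""
    if lo > hi:
        raise ValueError(f"purity window lo={lo} > hi={hi}")
    return [s for s in samples if lo <= s.purity <= hi]


def cohort_expression(samples: Sequence[BulkSample]) -> pd.DataFrame:
    """Genes x samples expression matrix assembled from BulkSample records."""
    genes = sorted({g for s in samples for g in s.expr})
    return pd.DataFrame(
        {s.sample_id: [s.expr.get(g, 0.0) for g in genes] for s in samples},
        index=pd.Index(genes, name="gene"),
    )


def bulk_signature_score(
    samples: Sequence[BulkSample],
    sig: GeneSignature,
    standardize: bool = True,
) -> pd.Series:
    """Weighted-average signature enrichment score per sample.

    score(s) = sum_g w_g * x_gs / sum_g |w_g| over the signature genes
    present in the cohort, with the signed logFC weights (up positive,
    down negative).  With ``standardize`` (default) expression is z-scored
    per gene across the cohort first, so no single highly expressed gene
    dominates the average and the score is invariant to per-gene affine
    rescaling.
    """
    expr = cohort_expression(samples)
    weights = sig.weights
    present = {g: w for g, w in weights.items() if g in expr.index}
    missing = set(weights) - set(present)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in cohort")
    if missing:
        logger.warning("signature %r: %d gene(s) absent from cohort, dropped",
                       sig.name, len(missing))
    sub = expr.loc[list(present)].astype(float)
    if standardize:
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
        sd = sd.replace(0.0, 1.0)  # constant genes contribute 0
        sub = sub.sub(mu, axis=0).div(sd, axis=0)
    w = np.array([present[g] for g in sub.index])
    scores = (sub.to_numpy() * w[:, None]).sum(axis=0) / np.abs(w).sum()
    return pd.Series(scores, index=sub.columns, name=sig.name)


def cytolytic_score(
    samples: Sequence[BulkSample], offset: float = 0.01
) -> pd.Series:
    """Cytolytic activity: geometric mean of PRF1 and GZMA expression,
    sqrt((PRF1 + offset) * (GZMA + offset)); the small offset keeps zero
    expression from annihilating the score."""
    for gene in ("PRF1", "GZMA"):
        if any(gene not in s.expr for s in samples):
            raise ValueError(f"gene {gene!r} missing from some samples")
    vals = [
        float(np.sqrt((s.expr["PRF1"] + offset) * (s.expr["GZMA"] + offset)))
        for s in samples
    ]
    return pd.Series(vals, index=[s.sample_id for s in samples],
                     name="cytolytic_score")


def tertile_groups(st: pd.Series) -> tuple[list[str], list[str]]:
    """Bottom and top thirds of samples by score.

    Sorting is by score ascending, ties broken by sample id (stable);
    low = first floor(n/3) ids, high = last floor(n/3); the middle third
    is discarded.
    """
    n = len(st)
    if n < 3:
        raise ValueError("tertile split needs at least 3 samples")
    order = st.reset_index()
    order.columns = ["id", "score"]
    order = order.sort_values(["score", "id"], kind="mergesort")
    k = n // 3
    ids = order["id"].tolist()
    return ids[:k], ids[-k:]


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``events`` is 1 for an observed event, 0 for right-censoring.  Tied
    event and censoring times follow the usual convention: events at t are
    counted with the risk set including observations censored at t.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be 1-D of equal length")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = len(t)
    event_times, surv, at_risk = [], [], []
    s = 1.0
    for ut in np.unique(t[e == 1]):
        n_i = int(np.sum(t >= ut))
        d_i = int(np.sum((t == ut) & (e == 1)))
        s *= 1.0 - d_i / n_i
        event_times.append(ut)
        surv.append(s)
        at_risk.append(n_i)
    return KMCurve(
        event_times=np.array(event_times),
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n=n,
    )


def logrank_test(
    g1: tuple[Sequence[float], Sequence[int]],
    g2: tuple[Sequence[float], Sequence[int]],
) -> LogRankResult:
    """Unweighted two-group log-rank test (1 df).

    At each distinct pooled event time, the group-1 event count is
    compared with its hypergeometric expectation given the risk sets;
    chi2 = (sum O - sum E)^2 / sum V, p from the chi-square upper tail.
    """
    t1 = np.asarray(g1[0], dtype=float)
    e1 = np.asarray(g1[1], dtype=int)
    t2 = np.asarray(g2[0], dtype=float)
    e2 = np.asarray(g2[1], dtype=int)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be nonempty")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    # risk sets and event counts at each pooled event time, vectorised
    n1 = (t1[:, None] >= event_times[None, :]).sum(axis=0).astype(float)
    n2 = (t2[:, None] >= event_times[None, :]).sum(axis=0).astype(float)
    d1 = ((t1[:, None] == event_times[None, :]) & (e1[:, None] == 1)).sum(axis=0)
    d2 = ((t2[:, None] == event_times[None, :]) & (e2[:, None] == 1)).sum(axis=0)
    n = n1 + n2
    d = (d1 + d2).astype(float)
    expected = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(
            n > 1, d * (n1 / n) * (n2 / n) * (n - d) / (n - 1), 0.0
        )
    o_minus_e = float((d1 - expected).sum())
    v = float(var.sum())
    chi2 = 0.0 if v == 0 else o_minus_e ** 2 / v
    p = float(scipy.stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    return LogRankResult(chi2=chi2, p=max(p, np.finfo(float).tiny),
                         n1=len(t1), n2=len(t2))


@dataclass
class SurvivalResult:
    signature: str
    km_low: KMCurve
    km_high: KMCurve
    logrank: LogRankResult
    low_ids: list[str]
    high_ids: list[str]
    scores: pd.Series


def survival_pipeline(
    samples: Sequence[BulkSample],
    signatures: Sequence[GeneSignature],
    purity_lo: float = 0.6,
    purity_hi: float = 0.7,
    standardize: bool = True,
) -> dict[str, SurvivalResult]:
    """Purity filter -> signature score -> tertile split -> KM + log-rank,
    one result per signature."""
    kept = purity_filter(samples, purity_lo, purity_hi)
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} samples in purity window [{purity_lo}, "
            f"{purity_hi}]; need >= 3"
        )
    by_id = {s.sample_id: s for s in kept}
    results: dict[str, SurvivalResult] = {}
    for sig in signatures:
        scores = bulk_signature_score(kept, sig, standardize=standardize)
        low_ids, high_ids = tertile_groups(scores)
        lo = [by_id[i] for i in low_ids]
        hi = [by_id[i] for i in high_ids]
        km_lo = km_curve([s.time for s in lo], [s.event for s in lo])
        km_hi = km_curve([s.time for s in hi], [s.event for s in hi])
        lr = logrank_test(
            ([s.time for s in lo], [s.event for s in lo]),
            ([s.time for s in hi], [s.event for s in hi]),
        )
        results[sig.name] = SurvivalResult(
            signature=sig.name, km_low=km_lo, km_high=km_hi, logrank=lr,
            low_ids=low_ids, high_ids=high_ids, scores=scores,
        )
    return results


def group_covariate_compare(
    samples: Sequence[BulkSample],
    groups: tuple[Sequence[str], Sequence[str]],
    features: list[str] | dict[str, pd.Series],
) -> pd.DataFrame:
    """Rank-sum comparison of per-sample features between two groups.

    ``features`` is either a list of gene names (values taken from sample
    expression) or a mapping name -> per-sample Series (e.g. a cytolytic
    score table).  Absent features are dropped with a warning; p-values
    are BH-adjusted across features.
    """
    from statsmodels.stats.multitest import multipletests

    by_id = {s.sample_id: s for s in samples}
    ids_a = [i for i in groups[0] if i in by_id]
    ids_b = [i for i in groups[1] if i in by_id]
    if not ids_a or not ids_b:
        raise ValueError("both groups must contain known sample ids")

    def values_for(feature) -> pd.Series | None:
        if isinstance(features, dict):
            return features[feature]
        if any(feature not in by_id[i].expr for i in ids_a + ids_b):
            return None
        return pd.Series({i: by_id[i].expr[feature] for i in ids_a + ids_b})

    rows = []
    names = list(features)
    for name in names:
        vals = values_for(name)
        if vals is None:
            logger.warning("feature %r absent from some samples; dropped", name)
            continue
        a = vals.loc[ids_a].to_numpy(dtype=float)
        b = vals.loc[ids_b].to_numpy(dtype=float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
            p = float(res.pvalue)
        rows.append({"feature": name, "mean_low": float(a.mean()),
                     "mean_high": float(b.mean()), "p": p})
    out = pd.DataFrame(rows, columns=["feature", "mean_low", "mean_high", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out
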