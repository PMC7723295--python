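"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's three data modalities:

* ``simulate_counts`` — a negative-binomial (gamma-Poisson) count matrix
  with planted clusters and marker genes.  Gene baseline means are
  lognormal, each cell's expected library size is scaled by a lognormal
  factor, and each cluster's marker genes have their mean multiplied by a
  fold change in that cluster only.  Overdispersion follows the droplet
  convention var = mu + alpha * mu^2 with a single scalar alpha.  A block
  of ``MT-``-prefixed genes exercises the mitochondrial QC filter.
* ``simulate_vdj_reads`` — 3' reads drawn from TR segment references with
  per-cluster positivity rates, substitution errors, and an optional
  fraction of reads from a planted shared (ambiguous) region; per-cell
  truth is recorded.
* ``simulate_bulk_cohort`` — a bulk cohort whose exponential hazard
  depends on a latent per-sample score expressed through a gene
  signature, with independent exponential censoring and uniform purity.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import BulkSample, CountMatrix, DesignError, GeneSignature
from .vdj import ReadRecord, SegmentRef, revcomp

__all__ = [
    "SimDesign",
    "SimTruth",
    "simulate_counts",
    "simulate_vdj_reads",
    "simulate_bulk_cohort",
    "make_synthetic_segments",
]


@dataclass
class SimDesign:
    """Design of a planted-cluster count simulation.

    Defaults give three clusters of 100 cells over 300 genes (plus a small
    mitochondrial block), 10 markers per cluster at 4-fold enrichment, and
    moderate droplet-like overdispersion (alpha = 0.3) with a mean library
    of ~2,000 counts — a desk-scale caricature of a sorted-PBMC run.
    """

    n_clusters: int = 3
    cells_per_cluster: int = 100
    n_genes: int = 300
    markers_per_cluster: int = 10
    marker_fold_change: float = 4.0
    nb_dispersion: float = 0.3
    mito_gene_count: int = 5
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise DesignError("need at least 2 clusters")
        if self.cells_per_cluster < 10:
            raise DesignError("need at least 10 cells per cluster")
        if self.n_genes < 50:
            raise DesignError("need at least 50 genes")
        if self.markers_per_cluster < 2:
            raise DesignError("need at least 2 markers per cluster")
        if self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise DesignError("more planted markers than genes")
        if self.marker_fold_change < 1.0:
            raise DesignError("marker_fold_change must be >= 1")
        if self.nb_dispersion <= 0:
            raise DesignError("nb_dispersion must be > 0")
        if self.mito_gene_count < 0:
            raise DesignError("mito_gene_count must be >= 0")
        if self.library_size_mean <= 0:
            raise DesignError("library_size_mean must be > 0")


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    cluster_of: dict[str, str] = field(default_factory=dict)
    marker_genes_of: dict[str, set[str]] = field(default_factory=dict)
    segment_of: dict[str, tuple[str, ...]] = field(default_factory=dict)
    read_truth: list[str] = field(default_factory=list)
    beta: float | None = None
    signature_score_true: dict[str, float] = field(default_factory=dict)
    gene_means: np.ndarray | None = None


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + alpha * mu^2."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam)


def simulate_counts(
    design: SimDesign,
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Planted-cluster NB count matrix, cell metadata, and ground truth.

    The metadata table carries cluster labels (``c1`` ...), a two-donor
    split, and uniform random cell-cycle phases so the composition
    summaries downstream have input to work on.
    """
    rng = np.random.default_rng(design.seed)
    n_cells = design.n_clusters * design.cells_per_cluster
    n_main = design.n_genes
    gene_ids = [f"GENE{i:04d}" for i in range(n_main)] + [
        f"MT-{i + 1}" for i in range(design.mito_gene_count)
    ]
    n_genes = len(gene_ids)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # mito block kept small (~1% of counts on average)
    if design.mito_gene_count:
        main_mass = base[:n_main].sum()
        base[n_main:] *= 0.01 * main_mass / base[n_main:].sum()
    base = base / base.sum() * design.library_size_mean

    clusters = [f"c{i + 1}" for i in range(design.n_clusters)]
    labels = np.repeat(clusters, design.cells_per_cluster)
    marker_of: dict[str, set[str]] = {}
    marker_rows: dict[str, np.ndarray] = {}
    for i, cl in enumerate(clusters):
        rows = np.arange(
            i * design.markers_per_cluster, (i + 1) * design.markers_per_cluster
        )
        marker_rows[cl] = rows
        marker_of[cl] = {gene_ids[r] for r in rows}

    sigma = design.library_size_sigma
    lib = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=n_cells)

    mu = np.tile(base[:, None], (1, n_cells)) * lib[None, :]
    for cl in clusters:
        cols = np.flatnonzero(labels == cl)
        mu[np.ix_(marker_rows[cl], cols)] *= design.marker_fold_change

    counts = _nb_draw(rng, mu, design.nb_dispersion)
    barcodes = [f"BC{i:05d}" for i in range(n_cells)]
    cm = CountMatrix(gene_ids, barcodes, sp.csr_matrix(counts))
    meta = pd.DataFrame(
        {
            "donor": np.where(rng.random(n_cells) < 0.5, "D1", "D2"),
            "cluster": labels,
            "phase": rng.choice(["G1", "S", "G2M"], size=n_cells),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    truth = SimTruth(
        cluster_of=dict(zip(barcodes, labels)),
        marker_genes_of=marker_of,
        gene_means=mu,
    )
    return cm, meta, truth


# ---------------------------------------------------------------------------
# VDJ read simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_synthetic_segments(
    seed: int = 0,
    length: int = 300,
    shared_len: int = 120,
) -> tuple[list[SegmentRef], tuple[str, int, int]]:
    """Synthetic stand-in for a TR segment reference set.

    Random sequences named after real TR segments (TRDC, TRDV2, TRGV9,
    TRDV1, TRDV3); TRDV1 and TRDV3 share an identical ``shared_len`` block
    (the planted ambiguity).  Returns the references and the shared region
    as (segment_name, start, end) on TRDV1.
    """
    rng = np.random.default_rng(seed)
    names = ["TRDC", "TRDV2", "TRGV9"]
    refs = [SegmentRef(n, _random_seq(rng, length)) for n in names]
    shared = _random_seq(rng, shared_len)
    a = _random_seq(rng, length - shared_len)
    b = _random_seq(rng, length - shared_len)
    start = (length - shared_len) // 2
    refs.append(SegmentRef("TRDV1", a[:start] + shared + a[start:]))
    refs.append(SegmentRef("TRDV3", b[:start] + shared + b[start:]))
    return refs, ("TRDV1", start, start + shared_len)


def simulate_vdj_reads(
    refs: Sequence[SegmentRef],
    positivity: dict[str, dict[str, float]],
    meta: pd.DataFrame,
    read_len: int = 90,
    err_rate: float = 0.005,
    reads_per_positive_cell: int = 5,
    shared_read_frac: float = 0.0,
    shared_region: tuple[str, int, int] | None = None,
    seed: int = 0,
) -> tuple[list[ReadRecord], SimTruth]:
    """Draw 3' reads from segment references with known per-cell truth.

    ``positivity[cluster][segment]`` is the probability that a cell of
    that cluster expresses the segment; positive cells emit
    ``reads_per_positive_cell`` reads from uniform start positions, with
    per-base substitution errors at ``err_rate``.  A ``shared_read_frac``
    fraction of reads is instead drawn from the planted shared region
    (``shared_region`` = (segment, start, end)); such reads are truth-
    labelled ``SHARED``.  Reads are emitted on a random strand.
    """
    min_len = min(len(r.sequence) for r in refs)
    if read_len > min_len:
        raise DesignError(f"read_len {read_len} exceeds shortest segment {min_len}")
    if not 0.0 <= err_rate <= 1.0:
        raise DesignError("err_rate must be in [0, 1]")
    if not 0.0 <= shared_read_frac <= 1.0:
        raise DesignError("shared_read_frac must be in [0, 1]")
    for cl, seg_rates in positivity.items():
        for seg, rate in seg_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise DesignError(f"positivity[{cl!r}][{seg!r}]={rate} not in [0,1]")
    if shared_read_frac > 0 and shared_region is None:
        raise DesignError("shared_read_frac > 0 requires shared_region")

    rng = np.random.default_rng(seed)
    by_name = {r.name: r.sequence for r in refs}
    if shared_region is not None:
        seg, lo, hi = shared_region
        shared_seq = by_name[seg][lo:hi]
        if hi - lo < read_len:
            raise DesignError("shared region shorter than read_len")

    reads: list[ReadRecord] = []
    truth = SimTruth()
    for barcode, row in meta.iterrows():
        seg_rates = positivity.get(row["cluster"], {})
        positives = tuple(
            seg for seg, rate in sorted(seg_rates.items()) if rng.random() < rate
        )
        truth.segment_of[barcode] = positives
        for seg in positives:
            seq = by_name[seg]
            for _ in range(reads_per_positive_cell):
                if shared_read_frac > 0 and rng.random() < shared_read_frac:
                    src, label = shared_seq, "SHARED"
                else:
                    src, label = seq, seg
                start = rng.integers(0, len(src) - read_len + 1)
                frag = np.array(list(src[start : start + read_len]))
                errs = np.flatnonzero(rng.random(read_len) < err_rate)
                for i in errs:
                    frag[i] = rng.choice(_BASES[_BASES != frag[i]])
                read_seq = "".join(frag)
                if rng.random() < 0.5:
                    read_seq = revcomp(read_seq)
                umi = _random_seq(rng, 10)
                reads.append(ReadRecord(barcode, umi, read_seq))
                truth.read_truth.append(label)
    return reads, truth


# ---------------------------------------------------------------------------
# Bulk cohort simulation
# ---------------------------------------------------------------------------

def simulate_bulk_cohort(
    n: int,
    sig: GeneSignature,
    beta: float,
    h0: float = 1e-3,
    censor_rate: float = 3e-4,
    purity_range: tuple[float, float] = (0.6, 0.7),
    n_background_genes: int = 20,
    seed: int = 0,
    base_expr: float = 10.0,
    noise_sd: float = 0.5,
    decoy_sigs: Sequence[GeneSignature] = (),
) -> tuple[list[BulkSample], SimTruth]:
    """Bulk cohort with survival driven by a planted signature score.

    Each sample carries a latent score z ~ N(0, 1); every signature gene's
    expression is the common baseline shifted by z times the sign of its
    weight (plus Gaussian noise), so the weighted-average signature score
    recovers z.  Survival time is exponential with hazard h0 * exp(beta*z)
    (beta < 0: high-score samples live longer); censoring is independent
    exponential at ``censor_rate``; purity is uniform on ``purity_range``
    (default: already inside the analysis window).  Background genes —
    always including PRF1 and GZMA so the cytolytic score is computable —
    are unrelated to z.  ``decoy_sigs`` are expressed the same way but
    driven by independent latent scores with no effect on the hazard.
    """
    if n < 10:
        raise DesignError("need n >= 10 samples")
    if h0 <= 0:
        raise DesignError("h0 must be > 0")
    if censor_rate < 0:
        raise DesignError("censor_rate must be >= 0")
    lo, hi = purity_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise DesignError("purity_range must be within [0, 1] with lo <= hi")

    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    sig_genes = {**sig.up, **sig.down}
    z_decoy = {d.name: rng.normal(size=n) for d in decoy_sigs}
    background = [f"BG{i:03d}" for i in range(max(n_background_genes - 2, 0))]
    background += [g for g in ("PRF1", "GZMA") if g not in sig_genes]
    bg_base = rng.uniform(1.0, 20.0, size=len(background))

    samples: list[BulkSample] = []
    truth = SimTruth(beta=beta)
    for i in range(n):
        sid = f"S{i:04d}"
        expr: dict[str, float] = {}
        for g, w in sig_genes.items():
            val = base_expr + np.sign(w) * z[i] + rng.normal(0.0, noise_sd)
            expr[g] = float(max(val, 0.0))
        for d in decoy_sigs:
            for g, w in d.weights.items():
                if g in expr:
                    continue
                val = base_expr + np.sign(w) * z_decoy[d.name][i] \
                    + rng.normal(0.0, noise_sd)
                expr[g] = float(max(val, 0.0))
        for g, b in zip(background, bg_base):
            expr[g] = float(max(b + rng.normal(0.0, 1.0), 0.0))
        hazard = h0 * np.exp(beta * z[i])
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / censor_rate) if censor_rate > 0 else np.inf
        time = float(max(min(t_event, t_cens), 1e-6))
        event = int(t_event <= t_cens)
        purity = float(rng.uniform(lo, hi))
        samples.append(BulkSample(sid, expr, purity, time, event))
        truth.signature_score_true[sid] = float(z[i])
    return samples, truth
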