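# gdtx — γδ T-cell transcriptomics toolkit

`gdtx` is a tested, reusable implementation of the analysis chain used to
characterise γδ T-cell subtypes from droplet single-cell RNA-seq and to
ask whether those subtypes matter clinically in a bulk tumour cohort. It
is aimed at computational immunologists who have cluster-labelled 10x
count matrices (clustering itself is upstream and out of scope) and want
the downstream biology: QC, marker signatures, per-cell enrichment
scores, TCR segment positivity from 3′ reads, pseudo-bulk tissue
comparison, and signature-based survival stratification — each stage
verifiable at desk scale against built-in synthetic data with known
ground truth.

## What it computes

* **QC + normalization** — a gene is dropped when detected in fewer than
  `max(0.002 · n_cells, 10)` cells; a cell is dropped when its
  mitochondrial count fraction exceeds 2% (`MT-` prefix); expression is
  log-normalized: `log(1 + count · 10⁴ / cell_total)`.
* **Markers and signatures** — per-gene two-sided Wilcoxon rank-sum
  contrast of a cluster against background clusters with BH adjustment;
  a signature is the (gene, logFC) list passing `q ≤ 0.05`,
  `|logFC| ≥ 0.25`, split into up and down sides.
* **Per-cell enrichment score** — after per-gene min-max normalization,
  `score(cell) = mean(up genes) − mean(down genes)` with equal weights;
  positive ⇒ the cell expresses the up genes and not the down genes.
  Curated effector programs (IFNγ, IL17, cytotoxicity, antigen
  presentation, innate) ship with the package and are scored as plain
  means.
* **TR segment annotation** — short 3′ reads are assigned to TCR γ/δ
  segments only when unambiguous: a k-mer (k = 21, either strand) found
  in exactly one reference segment is *diagnostic*, and a read needs ≥ 3
  diagnostic k-mers for one segment and none for any other. Per-cell
  positivity counts distinct UMIs.
* **Pseudo-bulk** — per-cluster count sums, CPM-scaled log2 ratios
  between tissues.
* **Survival** — samples kept in the tumour-purity window [0.6, 0.7];
  each sample scored as `Σ w_g x_gs / Σ |w_g|` over signature genes on
  per-gene z-scores; bottom vs top score tertiles compared with a
  Kaplan–Meier estimate and a 1-df log-rank test, both implemented in
  the package (not wrapped). The cytolytic score is
  `√(PRF1 · GZMA)` per sample.
* **Synthetic data** — negative-binomial count matrices with planted
  clusters/markers, 3′ reads from segment references with a planted
  shared (ambiguous) block, and bulk cohorts whose exponential hazard
  depends on a planted signature score.

## Worked example

```python
import numpy as np
from gdtx import GeneSignature, simulate_bulk_cohort, survival_pipeline

sig = GeneSignature("gd_T_subtype",
                    up={f"UP{i}": 1.0 for i in range(15)},
                    down={f"DN{i}": -1.0 for i in range(15)})
samples, truth = simulate_bulk_cohort(300, sig, beta=-0.8, seed=4)
res = survival_pipeline(samples, [sig])["gd_T_subtype"]
t_med = float(np.median([s.time for s in samples]))
print(res.logrank.n1, res.logrank.n2)
print(round(res.logrank.chi2, 2), f"{res.logrank.p:.3g}")
print(round(res.km_low.survival_at(t_med), 3),
      round(res.km_high.survival_at(t_med), 3))
```

prints

```
100 100
94.09 3.01e-22
0.341 0.865
```

meaning: of 300 simulated patients, the bottom and top score tertiles
(100 each) were compared; the log-rank test strongly rejects equal
survival (χ² = 94.1, p ≈ 3 × 10⁻²²), and at median follow-up 86.5% of
high-score patients survive versus 34.1% of low-score patients — the
direction expected for a protective (β = −0.8) signature.

The `examples/` directory has one narrative script per capability
(`01_qc_and_markers.py` … `05_pseudobulk_comparison.py`); each builds a
small input, runs the method, and prints what the numbers mean. A thin
CLI mirrors the stages (`gdtx simulate|qc|markers|vdj|score|pseudobulk|
survive|all`); `gdtx all --config run.yaml` chains every stage from one
YAML file and writes a manifest with output hashes.

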