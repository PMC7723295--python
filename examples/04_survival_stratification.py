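"""Bulk-cohort survival stratification by signature enrichment.

Simulates a cohort whose hazard decreases with a latent score expressed
through a gene signature (beta = -0.8, protective), keeps samples in the
purity window [0.6, 0.7], scores each sample by the logFC-weighted
average of the signature genes, splits into score tertiles, and compares
bottom vs top thirds with a Kaplan-Meier estimate and log-rank test.
"""

import numpy as np

from gdtx import (
    GeneSignature, cytolytic_score, simulate_bulk_cohort, survival_pipeline,
)

sig = GeneSignature(
    "gd_T_subtype",
    up={f"UP{i}": 1.0 for i in range(15)},
    down={f"DN{i}": -1.0 for i in range(15)},
)
samples, truth = simulate_bulk_cohort(300, sig, beta=-0.8, seed=4)
print(f"cohort: {len(samples)} samples, "
      f"{sum(s.event for s in samples)} events")

res = survival_pipeline(samples, [sig])["gd_T_subtype"]
t_med = float(np.median([s.time for s in samples]))
print(f"tertiles: {res.logrank.n1} low vs {res.logrank.n2} high")
print(f"log-rank: chi2 = {res.logrank.chi2:.2f}, p = {res.logrank.p:.3g}")
print(f"S(median follow-up): low = {res.km_low.survival_at(t_med):.3f}, "
      f"high = {res.km_high.survival_at(t_med):.3f}")
# With a protective signature the high-score tertile's survival curve sits
# above the low tertile's and the log-rank test is strongly significant.

cyt = cytolytic_score(samples)
print(f"\ncytolytic score (geometric mean of PRF1, GZMA): "
      f"median = {cyt.median():.2f} across {len(cyt)} samples")
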