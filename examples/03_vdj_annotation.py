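"""TR segment annotation from 3' reads with diagnostic k-mers.

Builds a k-mer index over synthetic TR segment references (TRDV1 and
TRDV3 share a planted 120 bp block), screens which segments short reads
can identify unambiguously, assigns simulated 90 bp reads, and tabulates
per-cluster positivity against the planted rates.
"""

import pandas as pd

from gdtx import (
    AMBIGUOUS, UNMAPPED, assign_read, build_segment_index, call_cells,
    cluster_positivity, make_synthetic_segments, screen_unambiguous_segments,
    simulate_vdj_reads,
)

refs, shared = make_synthetic_segments(seed=7)
print("identifiability of each segment from error-free 90 bp reads:")
report = screen_unambiguous_segments(refs, read_len=90, k=21)
print(report[["segment", "length", "n_windows", "n_bad_windows",
              "identifiable"]].to_string(index=False))
# TRDV1/TRDV3 share a 120 bp block, so reads from inside it cannot be
# placed: those two segments are not fully identifiable.

meta = pd.DataFrame(
    {"cluster": ["Vd2"] * 150 + ["other"] * 150},
    index=pd.Index([f"BC{i:04d}" for i in range(300)], name="barcode"),
)
reads, truth = simulate_vdj_reads(
    refs, {"Vd2": {"TRDV2": 0.6, "TRGV9": 0.6}}, meta,
    err_rate=0.01, seed=8,
)
idx = build_segment_index(refs, k=21)
assigned = [(r, a) for r in reads
            if (a := assign_read(r, idx)) not in (AMBIGUOUS, UNMAPPED)]
calls = call_cells(assigned)
print(f"\n{len(reads)} reads -> {len(assigned)} uniquely assigned -> "
      f"{len(calls)} cell/segment calls")
print(cluster_positivity(calls, meta).to_string(index=False))
# The Vd2 cluster recovers ~60% positivity for TRDV2/TRGV9 (the planted
# rate); the other cluster is negative throughout.
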