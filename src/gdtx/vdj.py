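"""TCR segment annotation from 3' barcoded reads via diagnostic k-mers.

Short 3' transcript reads cannot distinguish TR segments that share long
identical stretches; aligner workflows handle this by keeping only reads
with high mapping quality (unique placements).  Here the same contract —
assign a read only when its placement is unambiguous — is realised with a
deterministic k-mer uniqueness criterion: a k-mer occurring (on either
strand) in exactly one reference segment is *diagnostic* for it, and a
read is assigned to a segment only when it carries enough diagnostic
k-mers for that segment and none for any other.  Per-cell positivity is
then called on distinct UMIs, the molecule unit of 10x 3' data.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "AMBIGUOUS",
    "UNMAPPED",
    "SegmentRef",
    "SegmentIndex",
    "ReadRecord",
    "SegmentCall",
    "build_segment_index",
    "assign_read",
    "screen_unambiguous_segments",
    "call_cells",
    "cluster_positivity",
    "read_segment_fasta",
    "write_segment_fasta",
    "read_reads_fastq",
    "write_reads_fastq",
    "read_reads_paired_fastq",
    "revcomp",
]

AMBIGUOUS = "AMBIGUOUS"
UNMAPPED = "UNMAPPED"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SegmentRef:
    """One reference TR gene segment (e.g. TRDC, TRDV2, TRGV9)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"segment {self.name!r} has empty sequence")
        bad = set(self.sequence.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"segment {self.name!r}: invalid bases {sorted(bad)}")


@dataclass(frozen=True)
class ReadRecord:
    """A barcoded, UMI-tagged read."""

    barcode: str
    umi: str
    sequence: str


@dataclass(frozen=True)
class SegmentCall:
    """Per-cell positivity call for one segment."""

    barcode: str
    segment: str
    n_unique_reads: int  # distinct UMIs supporting the call


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class SegmentIndex:
    """Canonical k-mer -> owner map; owner is a segment name or AMBIGUOUS.

    K-mers are stored in canonical (lexicographically smaller of the two
    strands) form so that lookups are strand-symmetric.
    """

    k: int
    owners: dict[str, str]
    segment_names: list[str]

    def owner(self, kmer: str) -> str | None:
        """Ownership of a k-mer (either strand); None if absent."""
        if len(kmer) != self.k or "N" in kmer:
            return None
        return self.owners.get(_canonical(kmer))


def build_segment_index(refs: Sequence[SegmentRef], k: int = 21) -> SegmentIndex:
    """Index every k-mer of every segment (both strands).

    A k-mer seen in exactly one segment is owned by it (diagnostic); one
    shared between segments is marked AMBIGUOUS.  Requires k >= 11 (below
    that, genomic k-mers are rarely unique) and k no longer than the
    shortest segment.
    """
    if not refs:
        raise ValueError("no reference segments given")
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate segment names")
    min_len = min(len(r.sequence) for r in refs)
    if k > min_len:
        raise ValueError(f"k={k} exceeds shortest segment length {min_len}")
    if k < 11:
        raise ValueError("k must be >= 11")
    owners: dict[str, str] = {}
    for ref in refs:
        seq = ref.sequence.upper()
        seen_here: set[str] = set()
        for i in range(len(seq) - k + 1):
            canon = _canonical(seq[i : i + k])
            if canon in seen_here:
                continue
            seen_here.add(canon)
            prev = owners.get(canon)
            if prev is None:
                owners[canon] = ref.name
            elif prev != ref.name:
                owners[canon] = AMBIGUOUS
    return SegmentIndex(k=k, owners=owners, segment_names=names)


def assign_read(
    read: ReadRecord, idx: SegmentIndex, min_diag: int = 3
) -> str:
    """Classify one read by its diagnostic k-mer content.

    Counts diagnostic k-mer hits per segment over the read (k-mers with N
    are skipped).  The read is assigned to segment s only when it has
    >= min_diag diagnostic hits for s and none for any other segment;
    diagnostic hits to two or more segments give AMBIGUOUS; no diagnostic
    hits — or too few to meet min_diag — give UNMAPPED.
    """
    seq = read.sequence.upper()
    if len(seq) < idx.k:
        return UNMAPPED
    hits: dict[str, int] = defaultdict(int)
    for i in range(len(seq) - idx.k + 1):
        owner = idx.owner(seq[i : i + idx.k])
        if owner is not None and owner != AMBIGUOUS:
            hits[owner] += 1
    if not hits:
        return UNMAPPED
    if len(hits) > 1:
        return AMBIGUOUS
    (segment, n), = hits.items()
    return segment if n >= min_diag else UNMAPPED


def screen_unambiguous_segments(
    refs: Sequence[SegmentRef],
    read_len: int,
    k: int = 21,
    min_diag: int = 3,
) -> pd.DataFrame:
    """Which segments are identifiable from error-free reads of a given length?

    A segment is identifiable iff every read_len window of it contains at
    least ``min_diag`` diagnostic k-mers (so every possible error-free read
    would be assigned).  The report lists, per segment, the number of
    windows failing that bound and their start offsets.
    """
    if read_len < k:
        raise ValueError("read_len must be >= k")
    idx = build_segment_index(refs, k)
    rows = []
    for ref in refs:
        seq = ref.sequence.upper()
        n_kmers = len(seq) - k + 1
        diag = np.array(
            [idx.owner(seq[i : i + k]) == ref.name for i in range(n_kmers)],
            dtype=int,
        )
        cum = np.concatenate([[0], np.cumsum(diag)])
        kmers_per_window = read_len - k + 1
        n_windows = max(len(seq) - read_len + 1, 0)
        bad_starts = [
            s
            for s in range(n_windows)
            if cum[s + kmers_per_window] - cum[s] < min_diag
        ]
        rows.append(
            {
                "segment": ref.name,
                "length": len(seq),
                "n_windows": n_windows,
                "n_bad_windows": len(bad_starts),
                "identifiable": n_windows > 0 and not bad_starts,
                "bad_window_starts": bad_starts,
            }
        )
    return pd.DataFrame(rows)


def call_cells(
    assignments: Iterable[tuple[ReadRecord, str]], min_reads: int = 1
) -> list[SegmentCall]:
    """Collapse read assignments to per-cell segment calls.

    A cell is positive for a segment when the number of *distinct UMIs*
    assigned to that segment reaches ``min_reads`` (reads sharing a UMI are
    one molecule).  AMBIGUOUS/UNMAPPED assignments must be excluded first.
    """
    umis: dict[tuple[str, str], set[str]] = defaultdict(set)
    for read, segment in assignments:
        if segment in (AMBIGUOUS, UNMAPPED):
            raise ValueError("assignments must exclude AMBIGUOUS/UNMAPPED reads")
        umis[(read.barcode, segment)].add(read.umi)
    return [
        SegmentCall(barcode=bc, segment=seg, n_unique_reads=len(u))
        for (bc, seg), u in sorted(umis.items())
        if len(u) >= min_reads
    ]


def cluster_positivity(
    calls: Sequence[SegmentCall], meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster segment positivity: percent and count of positive cells.

    ``meta`` carries a ``cluster`` column indexed by barcode; calls whose
    barcode is absent from meta are excluded with a warning.  Clusters with
    no cells are omitted.
    """
    if "cluster" not in meta.columns:
        raise ValueError("meta must have a 'cluster' column")
    known = set(meta.index)
    kept = [c for c in calls if c.barcode in known]
    dropped = len(calls) - len(kept)
    if dropped:
        logger.warning("%d call(s) with barcodes absent from meta excluded", dropped)
    sizes = meta["cluster"].value_counts()
    segments = sorted({c.segment for c in kept})
    rows = []
    for cluster, size in sizes.items():
        if size == 0:
            continue
        in_cluster = set(meta.index[meta["cluster"] == cluster])
        for seg in segments:
            pos = {c.barcode for c in kept if c.segment == seg} & in_cluster
            rows.append(
                {
                    "cluster": cluster,
                    "segment": seg,
                    "n_cells": int(size),
                    "n_positive": len(pos),
                    "percent_positive": 100.0 * len(pos) / size,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def read_segment_fasta(path: Path | str) -> list[SegmentRef]:
    refs = [
        SegmentRef(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not refs:
        raise ValueError(f"{path}: no FASTA records")
    return refs


def write_segment_fasta(refs: Sequence[SegmentRef], path: Path | str) -> None:
    with open(path, "wt") as fh:
        for r in refs:
            fh.write(f">{r.name}\n{r.sequence}\n")


def read_reads_fastq(path: Path | str) -> list[ReadRecord]:
    """Read FASTQ with barcode/UMI encoded as ``BC:<bc> UMI:<umi>`` header tags."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        tags = dict(
            t.split(":", 1) for t in rec.description.split() if ":" in t
        )
        if "BC" not in tags or "UMI" not in tags:
            raise ValueError(f"{path}: read {rec.id!r} lacks BC:/UMI: header tags")
        reads.append(ReadRecord(tags["BC"], tags["UMI"], str(rec.seq).upper()))
    return reads


def write_reads_fastq(reads: Sequence[ReadRecord], path: Path | str) -> None:
    with open(path, "wt") as fh:
        for i, r in enumerate(reads):
            fh.write(
                f"@read{i} BC:{r.barcode} UMI:{r.umi}\n{r.sequence}\n+\n"
                f"{'I' * len(r.sequence)}\n"
            )


def read_reads_paired_fastq(
    r1_path: Path | str, r2_path: Path | str, bc_len: int = 16, umi_len: int = 10
) -> list[ReadRecord]:
    """10x v2 convention: R1 carries barcode (16 nt) + UMI (10 nt), R2 the cDNA."""
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 have different read counts")
    reads = []
    for a, b in zip(r1, r2):
        s1 = str(a.seq)
        if len(s1) < bc_len + umi_len:
            raise ValueError(f"R1 read {a.id!r} shorter than barcode+UMI")
        reads.append(
            ReadRecord(s1[:bc_len], s1[bc_len : bc_len + umi_len],
                       str(b.seq).upper())
        )
    return reads
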