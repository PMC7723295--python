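import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gdtx import (
    AMBIGUOUS,
    UNMAPPED,
    ReadRecord,
    SegmentRef,
    assign_read,
    build_segment_index,
    call_cells,
    cluster_positivity,
    make_synthetic_segments,
    screen_unambiguous_segments,
    simulate_vdj_reads,
)
from gdtx.vdj import (
    read_reads_fastq,
    read_reads_paired_fastq,
    read_segment_fasta,
    revcomp,
    write_reads_fastq,
    write_segment_fasta,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_ownership(refs, k):
    """Ownership of every k-mer by exhaustive scan over all segments and
    strands (quadratic; independent of the index construction)."""
    owners = {}
    for kmer in {
        s[i : i + k]
        for ref in refs
        for s in (ref.sequence, revcomp(ref.sequence))
        for i in range(len(s) - k + 1)
    }:
        hits = {
            ref.name
            for ref in refs
            if kmer in ref.sequence or kmer in revcomp(ref.sequence)
        }
        owners[kmer] = next(iter(hits)) if len(hits) == 1 else AMBIGUOUS
    return owners


class TestSegmentIndex:
    def test_identical_segments_all_ambiguous(self, rng):
        seq = random_seq(rng, 60)
        idx = build_segment_index(
            [SegmentRef("A", seq), SegmentRef("B", seq)], k=21
        )
        assert set(idx.owners.values()) == {AMBIGUOUS}

    def test_disjoint_segments_all_diagnostic(self):
        idx = build_segment_index(
            [SegmentRef("A", "A" * 30), SegmentRef("B", "C" * 30)], k=21
        )
        assert set(idx.owners.values()) == {"A", "B"}

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        refs, _ = make_synthetic_segments(seed=seed, length=150, shared_len=60)
        k = 21
        idx = build_segment_index(refs, k=k)
        expect = brute_force_ownership(refs, k)
        for kmer, owner in expect.items():
            assert idx.owner(kmer) == owner, kmer

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="shortest"):
            build_segment_index([SegmentRef("A", "ACGT" * 5)], k=25)


@pytest.fixture(scope="module")
def family():
    refs, shared = make_synthetic_segments(seed=3)
    return refs, shared, build_segment_index(refs, k=21)


class TestAssignRead:

    def test_clean_read_assigned(self, family):
        refs, _, idx = family
        trdv2 = next(r for r in refs if r.name == "TRDV2")
        read = ReadRecord("BC1", "U1", trdv2.sequence[10:100])
        assert assign_read(read, idx) == "TRDV2"

    def test_shared_region_read_unmapped(self, family):
        refs, (seg, lo, hi), idx = family
        src = next(r for r in refs if r.name == seg)
        read = ReadRecord("BC1", "U1", src.sequence[lo : lo + 90])
        assert assign_read(read, idx) in (UNMAPPED, AMBIGUOUS)
        # a wholly shared read has no diagnostic k-mers at all -> UNMAPPED
        assert assign_read(read, idx) == UNMAPPED

    def test_chimeric_read_ambiguous(self, family):
        refs, _, idx = family
        a = next(r for r in refs if r.name == "TRDC").sequence[:45]
        b = next(r for r in refs if r.name == "TRGV9").sequence[:45]
        assert assign_read(ReadRecord("BC1", "U1", a + b), idx) == AMBIGUOUS

    def test_strand_symmetry(self, family):
        refs, _, idx = family
        rng = np.random.default_rng(0)
        for ref in refs:
            for _ in range(5):
                start = rng.integers(0, len(ref.sequence) - 90 + 1)
                seq = ref.sequence[start : start + 90]
                fwd = assign_read(ReadRecord("b", "u", seq), idx)
                rev = assign_read(ReadRecord("b", "u", revcomp(seq)), idx)
                assert fwd == rev

    def test_n_containing_kmers_skipped(self, family):
        refs, _, idx = family
        trdc = next(r for r in refs if r.name == "TRDC")
        seq = "N" * 30 + trdc.sequence[:60]
        assert assign_read(ReadRecord("b", "u", seq), idx) == "TRDC"

    def test_accuracy_at_one_percent_error(self):
        refs, _ = make_synthetic_segments(seed=8)
        meta = pd.DataFrame(
            {"cluster": ["c1"] * 150},
            index=pd.Index([f"BC{i}" for i in range(150)], name="barcode"),
        )
        reads, truth = simulate_vdj_reads(
            refs, {"c1": {"TRDV2": 0.5, "TRGV9": 0.5, "TRDC": 0.5}},
            meta, err_rate=0.01, seed=9,
        )
        idx = build_segment_index(refs, k=21)
        assigned = [assign_read(r, idx) for r in reads]
        usable = [
            (a, t) for a, t in zip(assigned, truth.read_truth)
            if a not in (AMBIGUOUS, UNMAPPED)
        ]
        assert len(usable) > 0.8 * len(reads)
        acc = sum(a == t for a, t in usable) / len(usable)
        assert acc >= 0.99


def brute_force_window_scan(refs, read_len, k, min_diag):
    """Identifiability by literally extracting every window and checking
    each of its k-mers against every segment on both strands."""
    result = {}
    for ref in refs:
        seq = ref.sequence
        ok = len(seq) >= read_len
        for start in range(len(seq) - read_len + 1):
            window = seq[start : start + read_len]
            n_diag = 0
            for i in range(read_len - k + 1):
                kmer = window[i : i + k]
                hits = {
                    other.name
                    for other in refs
                    if kmer in other.sequence or revcomp(kmer) in other.sequence
                }
                if hits == {ref.name}:
                    n_diag += 1
            if n_diag < min_diag:
                ok = False
                break
        result[ref.name] = ok
    return result


class TestScreenUnambiguousSegments:
    def test_fully_shared_segment_not_identifiable(self, rng):
        seq = random_seq(rng, 120)
        report = screen_unambiguous_segments(
            [SegmentRef("A", seq), SegmentRef("B", seq + random_seq(rng, 40))],
            read_len=90, k=21,
        )
        assert not report.set_index("segment").loc["A", "identifiable"]

    def test_unique_segment_identifiable(self):
        refs, _ = make_synthetic_segments(seed=2)
        report = screen_unambiguous_segments(refs, read_len=90, k=21)
        rep = report.set_index("segment")
        for name in ("TRDC", "TRDV2", "TRGV9"):
            assert rep.loc[name, "identifiable"]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_window_scan(self, seed):
        # shared block longer than a read: windows inside it cannot be placed
        refs, _ = make_synthetic_segments(seed=seed, length=200, shared_len=100)
        report = screen_unambiguous_segments(refs, read_len=90, k=21, min_diag=3)
        expect = brute_force_window_scan(refs, 90, 21, 3)
        got = dict(zip(report.segment, report.identifiable))
        assert got == expect
        # the sharing pair cannot be fully identifiable at this geometry
        assert not expect["TRDV1"] and not expect["TRDV3"]
        for name in ("TRDC", "TRDV2", "TRGV9"):
            assert expect[name]

    def test_sharing_pair_bad_windows_sit_in_shared_block(self):
        refs, (seg, lo, hi) = make_synthetic_segments(
            seed=5, length=200, shared_len=100
        )
        report = screen_unambiguous_segments(
            refs, read_len=90, k=21, min_diag=3
        ).set_index("segment")
        bad = report.loc["TRDV1", "bad_window_starts"]
        assert bad  # some windows unplaceable
        for start in bad:
            # such a window lies (almost) wholly inside the shared block
            assert start >= lo - 25 and start + 90 <= hi + 25


class TestCallCells:
    def test_single_read_positive(self):
        calls = call_cells([(ReadRecord("B1", "U1", "A" * 30), "TRDV2")])
        assert len(calls) == 1
        assert calls[0].barcode == "B1" and calls[0].segment == "TRDV2"
        assert calls[0].n_unique_reads == 1

    def test_umi_collapsing(self):
        reads = [
            (ReadRecord("B1", "U1", "A" * 30), "TRDV2"),
            (ReadRecord("B1", "U1", "C" * 30), "TRDV2"),  # same molecule
        ]
        assert call_cells(reads, min_reads=2) == []
        assert call_cells(reads, min_reads=1)[0].n_unique_reads == 1

    def test_rejects_unassigned(self):
        with pytest.raises(ValueError):
            call_cells([(ReadRecord("B1", "U1", "A"), AMBIGUOUS)])

    def test_matches_brute_force_group_by(self, rng):
        reads = [
            (ReadRecord(f"B{rng.integers(5)}", f"U{rng.integers(8)}", "A"),
             f"SEG{rng.integers(3)}")
            for _ in range(200)
        ]
        calls = {(c.barcode, c.segment): c.n_unique_reads
                 for c in call_cells(reads, min_reads=2)}
        expect = {}
        for r, s in reads:
            expect.setdefault((r.barcode, s), set()).add(r.umi)
        expect = {k: len(v) for k, v in expect.items() if len(v) >= 2}
        assert calls == expect


class TestClusterPositivity:
    def _meta(self, n, cluster="c1"):
        return pd.DataFrame(
            {"cluster": [cluster] * n},
            index=pd.Index([f"B{i}" for i in range(n)], name="barcode"),
        )

    def test_simple_percentage(self):
        meta = self._meta(10)
        calls = call_cells(
            [(ReadRecord(f"B{i}", f"U{i}", "A"), "TRDV2") for i in range(4)]
        )
        tab = cluster_positivity(calls, meta)
        row = tab.iloc[0]
        assert row.percent_positive == 40.0 and row.n_positive == 4

    def test_unknown_barcode_excluded(self):
        meta = self._meta(5)
        calls = call_cells([(ReadRecord("UNKNOWN", "U", "A"), "TRDV2")])
        tab = cluster_positivity(calls, meta)
        assert tab.empty or (tab.n_positive == 0).all()

    def test_recovers_planted_rate_within_ci(self):
        refs, _ = make_synthetic_segments(seed=4)
        n = 200
        rate = 0.6
        meta = self._meta(n)
        reads, truth = simulate_vdj_reads(
            refs, {"c1": {"TRDV2": rate}}, meta, err_rate=0.005, seed=5
        )
        idx = build_segment_index(refs, k=21)
        assigned = [
            (r, a) for r in reads
            if (a := assign_read(r, idx)) not in (AMBIGUOUS, UNMAPPED)
        ]
        tab = cluster_positivity(call_cells(assigned), meta)
        got = tab.set_index("segment").loc["TRDV2", "percent_positive"] / 100
        ci_half = 2.6 * np.sqrt(rate * (1 - rate) / n)  # ~99% binomial CI
        assert abs(got - rate) <= ci_half


class TestFastaFastqIO:
    def test_fasta_round_trip(self, tmp_path):
        refs, _ = make_synthetic_segments(seed=0, length=60, shared_len=30)
        write_segment_fasta(refs, tmp_path / "refs.fa")
        back = read_segment_fasta(tmp_path / "refs.fa")
        assert back == refs

    def test_fastq_header_tags_round_trip(self, tmp_path):
        reads = [ReadRecord("ACGT" * 4, "TTTTGGGGCC", "ACGTACGTACGTACGTACGTA")]
        write_reads_fastq(reads, tmp_path / "r.fq")
        assert read_reads_fastq(tmp_path / "r.fq") == reads

    def test_paired_fastq_10x_layout(self, tmp_path):
        bc, umi, cdna = "A" * 16, "C" * 10, "ACGT" * 25
        (tmp_path / "r1.fq").write_text(f"@r1\n{bc}{umi}\n+\n{'I' * 26}\n")
        (tmp_path / "r2.fq").write_text(f"@r1\n{cdna}\n+\n{'I' * 100}\n")
        (rec,) = read_reads_paired_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert rec.barcode == bc and rec.umi == umi and rec.sequence == cdna
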