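import numpy as np
import pytest

from risclip import PipelineConfig, Read, align_dangling, align_full, ingest_sam
from risclip.align import ReferenceIndex

from .conftest import random_seq
from .oracles import dangling_oracle, scan_alignments


class TestAlignFull:
    def test_unique_planted_match(self, cfg, small_reference):
        tx_id, seq = next(iter(small_reference.transcripts.items()))
        read = Read("r1", seq[37:57])
        (aln,) = align_full([read], small_reference.transcripts, cfg)
        assert (aln.reference_id, aln.start, aln.length, aln.n_hits) == (tx_id, 37, 20, 1)

    def test_read_matching_two_references_has_n_hits_two(self, cfg):
        refs = {"a": "T" * 10 + "ACGTACGTACGTACGTACGT" + "T" * 10,
                "b": "G" * 5 + "ACGTACGTACGTACGTACGT"}
        read = Read("r", "ACGTACGTACGTACGTACGT")
        alignments = align_full([read], refs, cfg)
        assert len(alignments) >= 2
        assert all(a.n_hits == len(alignments) for a in alignments)

    def test_empty_reference_rejected(self, cfg):
        with pytest.raises(ValueError):
            align_full([Read("r", "ACGT" * 5)], {}, cfg)

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_exhaustive_scan_oracle(self, small_reference, max_mm):
        """Planted reads (with up to max_mm mutations) recover every offset the
        brute-force scan of all references finds, and nothing else."""
        cfg = PipelineConfig(max_mismatches=max_mm)
        rng = np.random.default_rng(21)
        tx_ids = sorted(small_reference.transcripts)
        reads = []
        for i in range(120):
            tx = tx_ids[int(rng.integers(0, len(tx_ids)))]
            seq = small_reference.transcripts[tx]
            length = int(rng.integers(18, 40))
            start = int(rng.integers(0, len(seq) - length))
            fragment = list(seq[start : start + length])
            for _ in range(int(rng.integers(0, max_mm + 1))):
                pos = int(rng.integers(0, length))
                fragment[pos] = str(rng.choice([b for b in "ACGT" if b != fragment[pos]]))
            reads.append(Read(f"r{i}", "".join(fragment)))
        alignments = align_full(reads, small_reference.transcripts, cfg)
        by_read = {}
        for aln in alignments:
            by_read.setdefault(aln.read_id, []).append((aln.reference_id, aln.start, aln.mismatches))
        for read in reads:
            expected = scan_alignments(read.sequence, small_reference.transcripts, max_mm)
            assert sorted(by_read.get(read.id, [])) == expected

    def test_result_invariant_to_read_order(self, cfg, small_reference):
        rng = np.random.default_rng(3)
        tx_ids = sorted(small_reference.transcripts)
        reads = []
        for i in range(40):
            seq = small_reference.transcripts[tx_ids[i % len(tx_ids)]]
            start = int(rng.integers(0, len(seq) - 25))
            reads.append(Read(f"r{i}", seq[start : start + 25]))
        forward = align_full(reads, small_reference.transcripts, cfg)
        backward = align_full(reads[::-1], small_reference.transcripts, cfg)
        assert sorted(map(repr, forward)) == sorted(map(repr, backward))


class TestReferenceIndex:
    def test_short_query_falls_back_to_brute_scan(self, small_reference):
        index = ReferenceIndex(small_reference.transcripts)
        tx_id, seq = next(iter(small_reference.transcripts.items()))
        hits = index.find_full(seq[10:18], 0)
        assert (tx_id, 10, 0) in hits
        assert hits == scan_alignments(seq[10:18], small_reference.transcripts, 0)


class TestAlignDangling:
    def test_planted_chimera_geometry(self, cfg, small_reference):
        rng = np.random.default_rng(8)
        tx_id = sorted(small_reference.transcripts)[0]
        seq = small_reference.transcripts[tx_id]
        foreign = random_seq(rng, 20)
        while scan_alignments(foreign, small_reference.transcripts, 0):
            foreign = random_seq(rng, 20)
        # guard the junction: the base 5' of the fragment must not extend the match
        start = 100
        while seq[start - 1] == foreign[-1]:
            start += 1
        read = Read("chimera", foreign + seq[start : start + 30])
        (d,) = align_dangling([read], small_reference.transcripts, cfg)
        assert d.reference_id == tx_id
        assert d.aligned_length == 30
        assert d.start == start
        assert d.dangling_side == "five_prime"
        assert d.dangling_seq == foreign

    def test_fully_matching_read_has_empty_dangling(self, cfg, small_reference):
        tx_id = sorted(small_reference.transcripts)[1]
        seq = small_reference.transcripts[tx_id]
        read = Read("r", seq[50:90])
        (d,) = align_dangling([read], small_reference.transcripts, cfg)
        assert d.aligned_length == 40
        assert d.dangling_seq == ""

    def test_unalignable_read_absent(self, cfg, small_reference):
        rng = np.random.default_rng(13)
        while True:
            seq = random_seq(rng, 40)
            if dangling_oracle(seq, small_reference.transcripts, cfg.min_length, 0) is None:
                break
        assert align_dangling([Read("r", seq)], small_reference.transcripts, cfg) == []

    def test_junctions_match_anchored_oracle(self, cfg, small_reference):
        """Random planted chimeras: the split point equals the exhaustive
        anchored-longest-match oracle's split in every case."""
        rng = np.random.default_rng(31)
        tx_ids = sorted(small_reference.transcripts)
        reads = []
        for i in range(60):
            tx = tx_ids[int(rng.integers(0, len(tx_ids)))]
            seq = small_reference.transcripts[tx]
            frag_len = int(rng.integers(20, 40))
            start = int(rng.integers(1, len(seq) - frag_len))
            foreign = random_seq(rng, int(rng.integers(18, 24)))
            reads.append(Read(f"c{i}", foreign + seq[start : start + frag_len]))
        results = {d.read_id: d for d in align_dangling(reads, small_reference.transcripts, cfg)}
        for read in reads:
            expected = dangling_oracle(
                read.sequence, small_reference.transcripts, cfg.min_length, cfg.max_mismatches
            )
            if expected is None:
                assert read.id not in results
                continue
            exp_len, exp_side = expected
            assert results[read.id].aligned_length == exp_len
            assert results[read.id].dangling_side == exp_side


class TestIngestSam:
    SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:tx1\tLN:200\n"

    def _write(self, tmp_path, body):
        path = tmp_path / "a.sam"
        path.write_text(self.SAM_HEADER + body)
        return path

    def test_one_based_pos_converted(self, tmp_path):
        path = self._write(tmp_path, "r1\t0\ttx1\t101\t255\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n")
        (aln,) = ingest_sam(path)
        assert aln.start == 100 and aln.length == 30

    def test_unmapped_and_reverse_skipped(self, tmp_path):
        body = (
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
            "r2\t16\ttx1\t11\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\n"
        )
        assert ingest_sam(self._write(tmp_path, body)) == []

    def test_soft_clip_becomes_dangling(self, tmp_path):
        seq = "G" * 20 + "A" * 30
        path = self._write(tmp_path, f"r1\t0\ttx1\t51\t255\t20S30M\t*\t0\t0\t{seq}\t*\n")
        alignments, danglings = ingest_sam(path, with_dangling=True)
        assert alignments == []
        (d,) = danglings
        assert d.dangling_side == "five_prime"
        assert d.dangling_seq == "G" * 20
        assert d.start == 50 and d.aligned_length == 30

    def test_unknown_reference_rejected(self, tmp_path):
        path = self._write(tmp_path, "r1\t0\ttx1\t11\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\n")
        with pytest.raises(ValueError, match="tx1"):
            ingest_sam(path, known_references=["tx2"])
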