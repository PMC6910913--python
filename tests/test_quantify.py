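import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from risclip import (
    Alignment,
    HairpinAnnotation,
    PipelineConfig,
    Read,
    align_dangling,
    align_full,
    build_smallrna_count_list,
    count_mirna_occupancy,
    length_filter,
    resolve_chimeras,
    seed_match_scan,
    top_targets,
    trim_adapter,
)
from risclip.footprints import Footprint
from risclip.quantify import reverse_complement
from risclip.synthetic import SimulationParams, simulate_library

from .conftest import random_seq
from .oracles import seed_sites_oracle

HAIRPIN = HairpinAnnotation("hp1", 90, (("hp1-5p", (3, 25)), ("hp1-3p", (62, 84))))


class TestOccupancy:
    def test_read_on_mature_site_counted(self, cfg):
        aln = Alignment("r1", "hp1", 3, 22)
        (count,) = count_mirna_occupancy([aln], [HAIRPIN], cfg)
        assert (count.mature_id, count.count, count.rank) == ("hp1-5p", 1.0, 1)

    def test_loop_read_not_counted(self, cfg):
        aln = Alignment("r1", "hp1", 30, 20)  # overlaps neither site by >= 10
        assert count_mirna_occupancy([aln], [HAIRPIN], cfg) == []

    def test_larger_overlap_wins_within_hairpin(self, cfg):
        # read spans end of 5p site (5 nt) and start of loop; below threshold
        aln = Alignment("r1", "hp1", 20, 22)  # overlap 5p = 5, 3p = 0
        assert count_mirna_occupancy([aln], [HAIRPIN], cfg) == []
        aln2 = Alignment("r2", "hp1", 10, 22)  # overlap 5p = 15
        (count,) = count_mirna_occupancy([aln2], [HAIRPIN], cfg)
        assert count.mature_id == "hp1-5p"

    def test_unknown_hairpin_rejected(self, cfg):
        with pytest.raises(ValueError, match="unknown hairpin"):
            count_mirna_occupancy([Alignment("r", "hpX", 0, 22)], [HAIRPIN], cfg)

    def test_ranks_descending_with_lexicographic_ties(self, cfg):
        alignments = [Alignment(f"a{i}", "hp1", 3, 22) for i in range(3)] + [
            Alignment(f"b{i}", "hp1", 62, 22) for i in range(3)
        ]
        counts = count_mirna_occupancy(alignments, [HAIRPIN], cfg)
        assert [(c.mature_id, c.rank) for c in counts] == [("hp1-3p", 1), ("hp1-5p", 2)]

    def test_planted_abundances_recovered_exactly(self, cfg):
        """A pure miRNA library: occupancy counting must return the planted
        per-miRNA read numbers exactly at zero mismatches."""
        params = SimulationParams(seed=5, n_footprint_sites=0, n_mirna_reads=2000, n_hairpins=10)
        from risclip import simulate_reference

        reference = simulate_reference(params)
        reads, truth = simulate_library(reference, params)
        kept, _ = length_filter([trim_adapter(r, cfg) for r in reads], cfg)
        alignments = align_full([t.read for t in kept], reference.hairpins, cfg)
        recovered = {c.mature_id: c.count for c in
                     count_mirna_occupancy(alignments, reference.hairpin_annotations, cfg)}
        planted = {k: float(v) for k, v in truth.mirna_abundances.items() if v > 0}
        assert recovered == planted


class TestSmallRnaCounts:
    def test_exact_copies_counted(self, cfg):
        matures = {"m1": "ACGTACGTACGTACGTACGTAC", "m2": "GGGTTTCCCAAAGGGTTTCCCA"}
        reads = [Read(f"r{i}", matures["m1"]) for i in range(5)] + [
            Read(f"s{i}", matures["m2"]) for i in range(2)
        ]
        table = build_smallrna_count_list(reads, matures, cfg)
        counts = dict(zip(table.mature_id, table["count"]))
        assert counts["m1"] == 5 and counts["m2"] == 2 and counts["_unassigned"] == 0

    def test_unmatched_reads_pooled_as_unassigned(self, cfg):
        matures = {"m1": "ACGTACGTACGTACGTACGTAC"}
        table = build_smallrna_count_list([Read("r", "T" * 22)], matures, cfg)
        assert dict(zip(table.mature_id, table["count"]))["_unassigned"] == 1

    def test_dirichlet_mixture_recovered(self, cfg):
        """Planted mixture proportions recovered with Spearman >= 0.99."""
        rng = np.random.default_rng(4)
        matures = {f"m{i:02d}": random_seq(rng, 22) for i in range(20)}
        props = rng.dirichlet(np.ones(20))
        counts = rng.multinomial(5000, props)
        reads = []
        for (mid, seq), n in zip(sorted(matures.items()), counts):
            reads.extend(Read(f"{mid}_{j}", seq) for j in range(n))
        table = build_smallrna_count_list(reads, matures, cfg)
        recovered = dict(zip(table.mature_id, table["count"]))
        planted = dict(zip(sorted(matures), counts))
        ids = sorted(matures)
        rho = spearmanr([planted[i] for i in ids], [recovered[i] for i in ids]).statistic
        assert rho >= 0.99
        assert all(recovered[i] == planted[i] for i in ids)


class TestResolveChimeras:
    def _setup(self, cfg, rng):
        hairpin_seq = random_seq(rng, 90)
        hairpins = {"hp1": hairpin_seq}
        annotations = [HAIRPIN]
        return hairpins, annotations

    def test_planted_chimera_resolved(self, cfg, rng):
        hairpins, annotations = self._setup(cfg, rng)
        mature = hairpins["hp1"][3:25]
        from risclip.align import DanglingAlignment

        d = DanglingAlignment("r1", "tx9", 140, 30, "five_prime", mature)
        (call,) = resolve_chimeras([d], hairpins, annotations, cfg)
        assert (call.mature_id, call.transcript_id, call.target_start) == ("hp1-5p", "tx9", 140)

    def test_short_dangling_end_dropped(self, cfg, rng):
        hairpins, annotations = self._setup(cfg, rng)
        from risclip.align import DanglingAlignment

        d = DanglingAlignment("r1", "tx9", 140, 30, "five_prime", hairpins["hp1"][3:13])
        assert resolve_chimeras([d], hairpins, annotations, cfg) == []

    def test_output_read_ids_subset_of_input(self, cfg, small_reference):
        params = SimulationParams(seed=6, n_footprint_sites=0, n_chimeras=50)
        from risclip import simulate_reference

        reference = simulate_reference(params)
        reads, _truth = simulate_library(reference, params)
        kept, _ = length_filter([trim_adapter(r, cfg) for r in reads], cfg)
        dangling = [d for d in align_dangling([t.read for t in kept], reference.transcripts, cfg)
                    if d.dangling_seq]
        calls = resolve_chimeras(dangling, reference.hairpins, reference.hairpin_annotations, cfg)
        assert {c.read_id for c in calls} <= {d.read_id for d in dangling}


class TestTopTargets:
    def test_highest_weight_first(self, cfg):
        fps = [Footprint("f1", "tx1", (0, 10), 10.0, 0), Footprint("f2", "tx2", (0, 10), 3.0, 0)]
        table = top_targets(fps, [], 1)
        assert list(table.transcript_id) == ["tx1"]

    def test_tie_broken_by_footprint_count(self, cfg):
        fps = [
            Footprint("f1", "tx1", (0, 10), 6.0, 0),
            Footprint("f2", "tx2", (0, 10), 3.0, 0),
            Footprint("f3", "tx2", (50, 60), 3.0, 50),
        ]
        table = top_targets(fps, [], 2)
        assert list(table.transcript_id) == ["tx2", "tx1"]

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            top_targets([], [], 0)

    def test_matches_groupby_oracle(self, cfg, rng):
        fps = []
        for i in range(200):
            tx = f"tx{int(rng.integers(0, 20)):02d}"
            fps.append(Footprint(f"f{i}", tx, (i * 10, i * 10 + 10), float(rng.integers(1, 9)), i * 10))
        frame = pd.DataFrame([(f.transcript_id, f.weight) for f in fps], columns=["tx", "w"])
        agg = frame.groupby("tx").agg(total=("w", "sum"), n=("w", "size")).reset_index()
        expected = list(
            agg.sort_values(["total", "n", "tx"], ascending=[False, False, True]).tx[:10]
        )
        assert list(top_targets(fps, [], 10).transcript_id) == expected


class TestSeedMatchScan:
    def _footprint(self, lo, hi):
        return Footprint("f", "tx", (lo, hi), 1.0, lo)

    def test_planted_7mer_m8(self, rng):
        mature = random_seq(rng, 22)
        site = reverse_complement(mature[1:8])
        transcript = random_seq(rng, 60) + site + "C" + random_seq(rng, 40)
        hits = seed_match_scan(self._footprint(55, 75), transcript, mature, flank=0)
        assert (60, "7mer-m8") in hits

    def test_no_hits_in_mismatched_sequence(self):
        mature = "C" * 22
        transcript = "A" * 100
        assert seed_match_scan(self._footprint(0, 100), transcript, mature) == []

    def test_matches_window_scan_oracle(self, rng):
        """Random transcripts and miRNAs: site set equals the brute-force scan."""
        for _ in range(50):
            mature = random_seq(rng, 22)
            transcript = random_seq(rng, 300)
            lo = int(rng.integers(0, 250))
            hi = lo + int(rng.integers(10, 50))
            fp = self._footprint(lo, min(hi, 300))
            flank = int(rng.integers(0, 20))
            got = seed_match_scan(fp, transcript, mature, flank)
            w_lo, w_hi = max(0, lo - flank), min(len(transcript), fp.bin[1] + flank)
            assert got == seed_sites_oracle(transcript, w_lo, w_hi, mature)
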