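"""SAM ingestion filters and the exhaustive oracle aligner."""

import numpy as np
import pytest

from alignbench import (
    AlignmentRecord,
    AlignmentSet,
    GenomicRegion,
    QualityScenario,
    ReferenceGenome,
    find_all_hits,
    ingest_sam,
    mapq_histogram,
    oracle_align,
    read_fastq,
    reverse_complement,
    simulate_reads,
    write_sam,
)
from _oracles import naive_hits

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def _sam_line(name, flag, pos_1based, mapq=37, nm=None, seq="ACGTACGTAC"):
    fields = [
        name, str(flag), "chr1" if not flag & 4 else "*",
        str(pos_1based if not flag & 4 else 0), str(mapq),
        f"{len(seq)}M" if not flag & 4 else "*",
        "*", "0", "0", seq, "I" * len(seq),
    ]
    if nm is not None:
        fields.append(f"NM:i:{nm}")
    return "\t".join(fields) + "\n"


class TestIngestSam:
    def _write(self, tmp_path, lines):
        p = tmp_path / "input.sam"
        p.write_text(SAM_HEADER + "".join(lines))
        return p

    def test_filters_and_coordinate_conversion(self, tmp_path):
        path = self._write(tmp_path, [
            _sam_line("ok", 0, 1001, nm=1),
            _sam_line("too_many_mm", 0, 500, nm=3),
            _sam_line("unmapped", 4, 0),
            _sam_line("minus", 16, 2000, nm=0),
        ])
        aset = ingest_sam(path, max_mismatches=2)
        assert aset.n_total == 4
        ok = aset.records["ok"]
        assert ok.status == "aligned" and ok.pos == 1000  # SAM POS 1001 -> 0-based
        assert aset.records["too_many_mm"].status == "unaligned"
        assert aset.records["unmapped"].status == "unaligned"
        assert aset.records["minus"].strand == "-"

    def test_missing_nm_kept_and_counted(self, tmp_path):
        path = self._write(tmp_path, [_sam_line("no_nm", 0, 100)])
        aset = ingest_sam(path, max_mismatches=2)
        assert aset.records["no_nm"].status == "aligned"
        assert aset.records["no_nm"].n_mismatches is None
        assert aset.n_missing_nm == 1

    def test_mapq_floor(self, tmp_path):
        path = self._write(tmp_path, [
            _sam_line("high_q", 0, 100, mapq=37, nm=0),
            _sam_line("low_q", 0, 200, mapq=3, nm=0),
        ])
        aset = ingest_sam(path, max_mismatches=2, mapq_min=10)
        assert aset.records["high_q"].status == "aligned"
        assert aset.records["low_q"].status == "unaligned"

    def test_secondary_records_ignored_but_counted(self, tmp_path):
        path = self._write(tmp_path, [
            _sam_line("dup", 0, 100, nm=0),
            _sam_line("dup", 256, 900, nm=0),  # secondary
        ])
        aset = ingest_sam(path)
        assert aset.n_total == 1
        assert aset.n_secondary_ignored == 1


class TestOracleAlign:
    def test_exact_unique_read_found_at_origin_in_both_modes(self, unique_genome):
        genome, _ = unique_genome
        seq = genome.sequences["chr1"][1234:1284]
        for mode in ("random_one", "unique_only"):
            aset = oracle_align([("r1", seq)], genome, 2, mode=mode, seed=0)
            rec = aset.records["r1"]
            assert rec.status == "aligned"
            assert (rec.chrom, rec.pos, rec.strand) == ("chr1", 1234, "+")
            assert rec.n_hits == 1 and rec.n_mismatches == 0

    def test_minus_strand_read_reported_leftmost(self, unique_genome):
        genome, _ = unique_genome
        seq = reverse_complement(genome.sequences["chr1"][5000:5050])
        aset = oracle_align([("r1", seq)], genome, 0, seed=0)
        rec = aset.records["r1"]
        assert (rec.pos, rec.strand) == (5000, "-")

    def test_repeat_read_suppressed_in_unique_only(self, repeat_genome):
        genome, annot = repeat_genome
        chrom, s, e = annot.intervals[0]
        seq = genome.sequences[chrom][s : s + 50]
        aset = oracle_align([("r1", seq)], genome, 2, mode="unique_only", seed=0)
        rec = aset.records["r1"]
        assert rec.status == "suppressed"
        assert rec.n_hits == 2

    def test_unique_scope_budget_vs_best(self):
        # copy B differs from copy A at one base: an exact read from A has a
        # 0-mismatch hit at A and a 1-mismatch hit at B
        rng = np.random.default_rng(6)
        unit = "".join(rng.choice(list("ACGT"), 50))
        unit_b = "T" + unit[1:] if unit[0] != "T" else "A" + unit[1:]
        filler = "".join(rng.choice(list("ACGT"), 200))
        genome = ReferenceGenome({"chr1": filler + unit + filler + unit_b + filler})
        read = ("r1", unit)
        budget = oracle_align([read], genome, 2, mode="unique_only", seed=0)
        assert budget.records["r1"].status == "suppressed"
        best = oracle_align(
            [read], genome, 2, mode="unique_only", seed=0, unique_scope="best"
        )
        assert best.records["r1"].status == "aligned"
        assert best.records["r1"].pos == 200

    def test_no_hit_is_unaligned(self, unique_genome):
        genome, _ = unique_genome
        aset = oracle_align([("r1", "A" * 50)], genome, 0, seed=0)
        assert aset.records["r1"].status == "unaligned"

    def test_read_longer_than_genome_is_unaligned(self):
        genome = ReferenceGenome({"chr1": "ACGTACGTACGT"})
        aset = oracle_align([("r1", "A" * 20)], genome, 2, seed=0)
        assert aset.records["r1"].status == "unaligned"

    def test_random_one_tie_break_is_uniform_over_copies(self, repeat_genome):
        """10,000 seeded draws on a 2-copy exact repeat: each copy chosen
        about half the time (binomial +/- 2%)."""
        genome, annot = repeat_genome
        chrom, s, e = annot.intervals[0]
        seq = genome.sequences[chrom][s : s + 50]
        # one call, 10,000 reads of the same sequence: the tie-break RNG is
        # derived per read from (seed, read_id), so each is an independent draw
        reads = [(f"r{i}", seq) for i in range(10_000)]
        aset = oracle_align(reads, genome, 0, mode="random_one", seed=11)
        picks = [rec.pos for rec in aset.records.values()]
        assert set(picks) == {iv[1] for iv in annot.intervals}
        frac = picks.count(s) / len(picks)
        assert abs(frac - 0.5) <= 0.02

    def test_hits_match_independent_naive_scan(self, repeat_genome):
        """The pigeonhole-seeded search enumerates exactly the hit set a full
        sliding-window scan finds, with identical minimal distances."""
        genome, annot = repeat_genome
        small = ReferenceGenome(
            {"chr1": genome.sequences["chr1"][:30_000]
             + genome.sequences["chr1"][80_000:100_000]}
        )
        rng = np.random.default_rng(8)
        reads = []
        text = small.sequences["chr1"]
        bases = list("ACGT")
        for i in range(40):
            pos = int(rng.integers(0, len(text) - 50))
            seq = list(text[pos : pos + 50])
            for _ in range(int(rng.integers(0, 3))):  # 0-2 mutations
                off = int(rng.integers(0, 50))
                seq[off] = bases[int(rng.integers(0, 4))]
            read = "".join(seq)
            if rng.integers(0, 2):
                read = reverse_complement(read)
            reads.append(read)
        for read in reads:
            assert find_all_hits(read, small, 2) == naive_hits(read, small, 2)

    def test_minimality_of_reported_hit(self, repeat_genome):
        genome, _ = repeat_genome
        regions = [GenomicRegion("chr1", 0, 100_000)]
        reads = simulate_reads(
            genome, regions, QualityScenario.make(2, "high"), n_reads=60, seed=3
        )
        aset = oracle_align(reads, genome, 2, mode="random_one", seed=1)
        for read in reads:
            rec = aset.records[read.read_id]
            hits = naive_hits(read.sequence, genome, 2)
            assert rec.n_mismatches == min(h[3] for h in hits)

    def test_unique_only_agrees_with_random_one_on_unique_hits(
        self, unique_genome, unique_regions
    ):
        genome, _ = unique_genome
        reads = simulate_reads(
            genome, unique_regions, QualityScenario.make(1, "high"), n_reads=100, seed=4
        )
        rnd = oracle_align(reads, genome, 2, mode="random_one", seed=2)
        uniq = oracle_align(reads, genome, 2, mode="unique_only", seed=2)
        for read_id, urec in uniq.records.items():
            if urec.status == "aligned":
                rrec = rnd.records[read_id]
                assert (urec.chrom, urec.pos, urec.strand) == (
                    rrec.chrom, rrec.pos, rrec.strand,
                )

    def test_mixed_read_lengths_rejected(self, unique_genome):
        genome, _ = unique_genome
        with pytest.raises(ValueError):
            oracle_align([("a", "ACGTACGTAA"), ("b", "ACGT")], genome, 2, seed=0)


class TestSamRoundTrip:
    def test_oracle_sam_survives_ingestion(self, tmp_path, unique_genome, mm1_high_reads):
        genome, _ = unique_genome
        aset = oracle_align(mm1_high_reads, genome, 2, mode="random_one", seed=7)
        path = tmp_path / "oracle.sam"
        write_sam(aset, mm1_high_reads, genome, path)
        back = ingest_sam(path, max_mismatches=2, label="roundtrip")
        assert back.n_total == aset.n_total
        for read_id, rec in aset.records.items():
            brec = back.records[read_id]
            if rec.status == "aligned":
                assert (brec.chrom, brec.pos, brec.strand, brec.n_mismatches) == (
                    rec.chrom, rec.pos, rec.strand, rec.n_mismatches,
                )
            else:
                assert brec.status == "unaligned"


class TestMapqHistogram:
    def _set(self, mapqs):
        aset = AlignmentSet(label="x", mode="random_one")
        for i, q in enumerate(mapqs):
            aset.add(AlignmentRecord(f"r{i}", "aligned", chrom="chr1", pos=i,
                                     strand="+", mapq=q))
        return aset

    def test_single_bin(self):
        hist, missing = mapq_histogram(self._set([37, 37, 37]))
        assert hist == {37: 3} and missing == 0

    def test_mixed_bins_and_missing(self):
        aset = self._set([37, 37, 37, 0])
        aset.add(AlignmentRecord("nomapq", "aligned", chrom="chr1", pos=9,
                                 strand="+", mapq=None))
        aset.add(AlignmentRecord("off", "unaligned"))
        hist, missing = mapq_histogram(aset)
        assert hist == {0: 1, 37: 3}
        assert missing == 1
        assert sum(hist.values()) + missing == aset.n_aligned


def test_duplicate_read_id_rejected():
    aset = AlignmentSet(label="x", mode="random_one")
    aset.add(AlignmentRecord("r1", "unaligned"))
    with pytest.raises(ValueError):
        aset.add(AlignmentRecord("r1", "unaligned"))
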