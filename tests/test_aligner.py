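"""Seed index, ungapped/gapped mapping and accuracy assessment."""

import numpy as np
import pytest

from modipkit.aligner import (
    GapScoring,
    MappingPolicy,
    assess_mapping_accuracy,
    build_index,
    map_read_gapped,
    map_read_ungapped,
)
from modipkit.core_io import (
    AlignmentRecord,
    ConfigError,
    DataError,
    GenomicInterval,
    MockRead,
    Modification,
    ValidationError,
    revcomp,
)
from oracles import exhaustive_ungapped_scan


def _pairwise_fit_score(query, window, sc: GapScoring):
    """Independent fitting-alignment score via Biopython's PairwiseAligner."""
    import warnings

    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = sc.match
    aligner.mismatch_score = sc.mismatch
    aligner.open_gap_score = sc.gap_open
    aligner.extend_gap_score = sc.gap_extend
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gap-attribute rename deprecations
        # window-local: target end gaps are free
        aligner.target_left_open_gap_score = 0
        aligner.target_left_extend_gap_score = 0
        aligner.target_right_open_gap_score = 0
        aligner.target_right_extend_gap_score = 0
    return aligner.score(window, query)


class TestSeedIndex:
    def test_kmer_positions_exhaustive_example(self):
        index = build_index({"c": "ACGTACGT"}, 4)
        occ = index.occurrences("ACGT")
        assert [p for _, p in occ["+"]] == [0, 4]
        # ACGT is its own reverse complement, so both strands agree
        assert occ["-"] == occ["+"]

    def test_k_equal_to_chromosome_length(self):
        index = build_index({"c": "ACGTAA"}, 6)
        assert index.lookup("ACGTAA") == [("c", 0)]

    def test_absent_kmer_empty(self):
        index = build_index({"c": "ACGTACGT"}, 4)
        assert index.lookup("TTTT") == []

    def test_k_exceeding_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            build_index({"c": "ACGT"}, 5)


class TestUngapped:
    def test_verbatim_read_maps_unique_at_truth(self, ref, dataset):
        index = build_index(ref, 5)
        # a tiled read comes from a region kept clear of repeats/duplications
        read = dataset[0]
        rec = map_read_ungapped(index, read)
        assert rec.status == "unique"
        assert rec.interval == read.origin
        assert rec.mismatches == 0 and rec.strand == "+"

    def test_duplicated_locus_read_is_multi(self, ref):
        a, _b = ref.duplicated_loci[0]
        read = MockRead("dup", ref.fetch(GenomicInterval(a.chrom, a.start,
                                                         a.start + 25)),
                        GenomicInterval(a.chrom, a.start, a.start + 25))
        index = build_index(ref, 5)
        rec = map_read_ungapped(index, read)
        assert rec.status == "multi"

    def test_two_seed_mismatches_unaligned(self):
        rng = np.random.default_rng(23)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        genome = {"c": rng.choice(bases, 300).tobytes().decode()}
        truth = genome["c"][50:75]
        # corrupt positions 0 and 2, inside the first 5 bases
        sub = lambda b: "A" if b != "A" else "C"
        bad = sub(truth[0]) + truth[1] + sub(truth[2]) + truth[3:]
        index = build_index(genome, 5)
        rec = map_read_ungapped(index, ("r", bad))  # total 2 <= cap, seed 2 > 1
        assert rec.status == "unaligned"

    def test_reverse_strand_read(self, ref, dataset):
        read = dataset[3]
        index = build_index(ref, 5)
        rec = map_read_ungapped(index, ("rc", revcomp(read.seq)))
        assert rec.status == "unique"
        assert rec.interval == read.origin
        assert rec.strand == "-"

    def test_empty_read_rejected(self, ref):
        index = build_index(ref, 5)
        with pytest.raises(ValidationError):
            map_read_ungapped(index, ("r", ""))

    def test_agrees_with_exhaustive_scan_small_genome(self):
        """Spot-check oracle equivalence (the full 500-read suite runs in the
        acceptance tests)."""
        rng = np.random.default_rng(17)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        genome = {"c1": rng.choice(bases, 800).tobytes().decode(),
                  "c2": rng.choice(bases, 600).tobytes().decode()}
        index = build_index(genome, 5)
        policy = MappingPolicy()
        for _ in range(40):
            chrom = "c1" if rng.integers(2) else "c2"
            start = int(rng.integers(0, len(genome[chrom]) - 25))
            seq = list(genome[chrom][start:start + 25])
            for pos in rng.choice(25, size=int(rng.integers(0, 4)),
                                  replace=False):
                seq[pos] = "ACGT"[int(rng.integers(4))]
            read_seq = "".join(seq)
            if rng.integers(2):
                read_seq = revcomp(read_seq)
            got = map_read_ungapped(index, ("r", read_seq), policy)
            status, locus, mm = exhaustive_ungapped_scan(
                genome, read_seq, policy.seed_len,
                policy.max_seed_mismatches, policy.max_total_mismatches)
            assert got.status == status
            if status == "unique":
                assert (got.interval.chrom, got.interval.start,
                        got.strand) == locus
                assert got.mismatches == mm

    def test_monotonic_in_total_mismatch_cap(self, ref, modified):
        index = build_index(ref, 5)
        reads = modified[:40]
        aligned_at = []
        for cap in (0, 1, 2, 3):
            policy = MappingPolicy(max_total_mismatches=cap)
            n = sum(
                map_read_ungapped(index, r, policy).status != "unaligned"
                for r in reads
            )
            aligned_at.append(n)
        assert aligned_at == sorted(aligned_at)


class TestGapped:
    def test_deletion_read_recovered_at_truth_with_one_gap(self, ref, modified):
        index = build_index(ref, 5)
        sc = GapScoring()
        dels = [r for r in modified
                if r.modification and r.modification.kind == "deletion"]
        assert dels
        read = dels[0]
        rec = map_read_gapped(index, read, scoring=sc)
        assert rec.status == "unique"
        assert rec.interval.start == read.origin.start
        # score must equal the independent DP oracle on the truth window
        window = ref.fetch(read.origin)
        assert rec.score == _pairwise_fit_score(read.seq, window, sc)

    def test_unmodified_read_consistent_with_ungapped(self, ref, dataset):
        index = build_index(ref, 5)
        for read in dataset[:10]:
            ug = map_read_ungapped(index, read)
            gp = map_read_gapped(index, read)
            if ug.status == "unique":
                assert gp.status == "unique"
                assert gp.interval.start == ug.interval.start
                assert gp.strand == ug.strand

    def test_engineered_insertion_mismaps_to_better_motif(self):
        """Inserting 5 bases can create a motif matching a second locus
        exactly; the gapped aligner then prefers the exact second locus."""
        rng = np.random.default_rng(3)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        flank = lambda n: rng.choice(bases, n).tobytes().decode()
        original = flank(25)
        modified_seq = original[:12] + "ACGTC" + original[12:]  # 30 bp
        genome = {"c": flank(100) + original + flank(100) + modified_seq
                  + flank(100)}
        locus_b_start = 100 + 25 + 100
        index = build_index(genome, 5)
        rec = map_read_gapped(index, ("ins", modified_seq))
        assert rec.status == "unique"
        assert rec.interval.start == locus_b_start
        assert rec.mismatches == 0 and rec.score == 60  # 30 exact matches

    def test_small_band_warns(self, ref, dataset):
        index = build_index(ref, 5)
        with pytest.warns(UserWarning, match="band"):
            map_read_gapped(index, dataset[0], scoring=GapScoring(band=3))


class TestAccuracy:
    def _truth(self, n=4):
        return {
            f"r{i}": MockRead(f"r{i}", "A" * 25,
                              GenomicInterval("chr1", 100 * i + 10, 100 * i + 35))
            for i in range(n)
        }

    def test_three_of_four_correct(self):
        truth = self._truth()
        alignments = [
            AlignmentRecord(f"r{i}", "unique",
                            GenomicInterval("chr1", 100 * i + 10, 100 * i + 35))
            for i in range(3)
        ] + [AlignmentRecord("r3", "unique", GenomicInterval("chr1", 999, 1024))]
        report = assess_mapping_accuracy(alignments, truth)
        assert report.n_correct == 3
        assert report.accuracy == 0.75

    def test_no_unique_alignments_flagged_zero(self):
        truth = self._truth(2)
        alignments = [AlignmentRecord("r0", "multi"),
                      AlignmentRecord("r1", "unaligned")]
        report = assess_mapping_accuracy(alignments, truth)
        assert report.n_unique == 0 and report.accuracy == 0.0

    def test_indel_reads_get_start_tolerance(self):
        truth = {"r0": MockRead("r0", "A" * 30,
                                GenomicInterval("chr1", 100, 125),
                                Modification("insertion", 12, "ACGTC"))}
        rec = AlignmentRecord("r0", "unique", GenomicInterval("chr1", 97, 127))
        assert assess_mapping_accuracy([rec], truth).n_correct == 1

    def test_missing_truth_read_named(self):
        with pytest.raises(DataError, match="ghost"):
            assess_mapping_accuracy(
                [AlignmentRecord("ghost", "unaligned")], self._truth(1))

    def test_per_base_depth_counts_unique_coverage(self):
        truth = self._truth(2)
        alignments = [
            AlignmentRecord("r0", "unique", GenomicInterval("chr1", 10, 35)),
            AlignmentRecord("r1", "unique", GenomicInterval("chr1", 30, 55)),
        ]
        depth = assess_mapping_accuracy(alignments, truth).per_base_depth
        assert depth[("chr1", 32)] == 2
        assert depth[("chr1", 10)] == 1
        assert ("chr1", 55) not in depth
        assert sum(depth.values()) == 50

    def test_counts_partition_total(self, ref, modified):
        index = build_index(ref, 5)
        alignments = [map_read_ungapped(index, r) for r in modified]
        report = assess_mapping_accuracy(
            alignments, {r.read_id: r for r in modified})
        assert (report.n_unique + report.n_multi + report.n_unaligned
                == report.n_total == len(modified))
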