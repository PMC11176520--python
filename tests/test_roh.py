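import numpy as np
import pytest

import divkit as dk
from divkit.roh import (
    ROHParams,
    ROHSegment,
    classify_lengths,
    detect_roh,
    froh,
    froh_table,
    segments_frame,
    summarize_roh,
)
from conftest import random_dataset
from oracle_utils import brute_force_roh


def one_individual(pos, calls, chrom="1"):
    pos = np.asarray(pos)
    calls = np.asarray(calls, dtype=np.int8).reshape(1, -1)
    return dk.GenotypeDataset(
        dk.make_sample_table(["f"], ["i0"]),
        dk.make_marker_table([f"m{i}" for i in range(len(pos))], [chrom] * len(pos), pos),
        calls,
    )


class TestDetection:
    def test_qualifying_run_detected_with_exact_coordinates(self):
        # 20 homozygous SNPs spaced 100 kb apart: span 1.9 Mb
        pos = 1_000_000 + np.arange(20) * 100_000
        segs = detect_roh(one_individual(pos, np.zeros(20)))
        assert len(segs) == 1
        s = segs[0]
        assert (s.start_bp, s.end_bp, s.n_snp) == (1_000_000, 2_900_000, 20)
        assert s.length_bp == 1_900_000

    def test_fourteen_snps_fail_min_snp(self):
        pos = 1_000_000 + np.arange(14) * 100_000  # 1.3 Mb but only 14 SNPs
        assert detect_roh(one_individual(pos, np.zeros(14))) == []

    def test_short_span_fails_min_length(self):
        pos = 1_000_000 + np.arange(20) * 40_000  # 20 SNPs but 0.76 Mb
        assert detect_roh(one_individual(pos, np.zeros(20))) == []

    def test_large_gap_splits_run(self):
        # two 1.5 Mb blocks of 16 SNPs separated by a 300 kb gap
        left = 1_000_000 + np.arange(16) * 100_000
        right = left[-1] + 300_000 + np.arange(16) * 100_000
        pos = np.concatenate([left, right])
        segs = detect_roh(one_individual(pos, np.zeros(32)))
        assert [(s.start_bp, s.end_bp) for s in segs] == [
            (int(left[0]), int(left[-1])),
            (int(right[0]), int(right[-1])),
        ]

    def test_gap_exactly_at_allowance_does_not_split(self):
        left = 1_000_000 + np.arange(16) * 100_000
        right = left[-1] + 250_000 + np.arange(16) * 100_000
        pos = np.concatenate([left, right])
        segs = detect_roh(one_individual(pos, np.zeros(32)))
        assert len(segs) == 1 and segs[0].n_snp == 32

    def test_heterozygote_breaks_run(self):
        pos = 1_000_000 + np.arange(31) * 100_000
        calls = np.zeros(31)
        calls[15] = 1
        segs = detect_roh(one_individual(pos, calls))
        # both halves hold 15 SNPs spanning 1.4 Mb
        assert [(s.start_bp, s.end_bp, s.n_snp) for s in segs] == [
            (1_000_000, 2_400_000, 15),
            (2_600_000, 4_000_000, 15),
        ]

    def test_missing_breaks_run_at_default(self):
        pos = 1_000_000 + np.arange(40) * 100_000
        calls = np.zeros(40)
        calls[20] = dk.MISSING
        segs = detect_roh(one_individual(pos, calls))
        assert [(s.n_snp) for s in segs] == [20, 19]

    def test_one_missing_allowed_when_budgeted(self):
        pos = 1_000_000 + np.arange(40) * 100_000
        calls = np.zeros(40)
        calls[20] = dk.MISSING
        segs = detect_roh(one_individual(pos, calls), ROHParams(max_missing=1))
        assert len(segs) == 1 and segs[0].n_snp == 39

    def test_mixed_homozygotes_allowed_by_default(self):
        pos = 1_000_000 + np.arange(20) * 100_000
        calls = np.where(np.arange(20) % 2 == 0, 0, 2)
        segs = detect_roh(one_individual(pos, calls))
        assert len(segs) == 1 and segs[0].n_snp == 20

    def test_same_allele_mode_breaks_at_transition(self):
        pos = 1_000_000 + np.arange(40) * 100_000
        calls = np.concatenate([np.zeros(20), np.full(20, 2)])
        segs = detect_roh(one_individual(pos, calls), ROHParams(same_allele=True))
        assert [(s.start_bp, s.n_snp) for s in segs] == [
            (1_000_000, 20),
            (3_000_000, 20),
        ]

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(31)
        ds = random_dataset(rng, 6, 300, n_chroms=2)
        swapped = ds.calls.copy()
        swapped[swapped != dk.MISSING] = 2 - swapped[swapped != dk.MISSING]
        ds2 = dk.GenotypeDataset(ds.samples, ds.markers, swapped)
        params = ROHParams(min_snp=4, max_gap_bp=500_000, min_length_bp=50_000)
        assert detect_roh(ds, params) == detect_roh(ds2, params)

    def test_unsorted_positions_rejected(self):
        ds = one_individual([300, 100, 200], [0, 0, 0])
        with pytest.raises(ValueError, match="sorted"):
            detect_roh(ds)


class TestOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        pos = np.sort(rng.choice(np.arange(1, 4_000_000), size=n, replace=False))
        # homozygote-rich calls so runs actually occur
        calls = rng.choice(
            np.array([0, 1, 2, dk.MISSING], dtype=np.int8),
            size=(3, n),
            p=[0.44, 0.08, 0.44, 0.04],
        )
        params = ROHParams(min_snp=5, max_gap_bp=120_000, min_length_bp=60_000)
        ds = dk.GenotypeDataset(
            dk.make_sample_table(["f"] * 3, ["a", "b", "c"]),
            dk.make_marker_table([f"m{i}" for i in range(n)], ["1"] * n, pos),
            calls,
        )
        got = detect_roh(ds, params)
        idx_of = {int(p): i for i, p in enumerate(pos)}
        for s_id, row in zip(ds.sample_ids(), calls):
            expect = brute_force_roh(
                row, pos, params.min_snp, params.max_gap_bp, params.min_length_bp
            )
            mine = {
                (idx_of[s.start_bp], idx_of[s.end_bp], s.n_snp)
                for s in got
                if s.individual == s_id
            }
            assert mine == expect

    def test_stricter_params_give_subset(self):
        rng = np.random.default_rng(40)
        ds = random_dataset(rng, 5, 400, n_chroms=1)
        loose = detect_roh(ds, ROHParams(min_snp=3, max_gap_bp=1_000_000, min_length_bp=10_000))
        tight = detect_roh(ds, ROHParams(min_snp=6, max_gap_bp=1_000_000, min_length_bp=10_000))
        loose_keys = {(s.individual, s.start_bp, s.end_bp) for s in loose}
        assert all((s.individual, s.start_bp, s.end_bp) in loose_keys for s in tight)


class TestClassifyAndSummaries:
    @staticmethod
    def seg(ind, chrom, start, length_bp, n_snp=20):
        return ROHSegment(ind, chrom, start, start + length_bp, n_snp)

    def test_boundary_two_mb_falls_in_second_class(self):
        table = classify_lengths([self.seg("a", "1", 10, 2_000_000)])
        assert table.set_index("class_mb")["count"]["2-4"] == 1
        assert table["count"].sum() == 1

    def test_class_counts_and_percent(self):
        segs = [
            self.seg("a", "1", 10, 1_500_000),
            self.seg("a", "1", 3_000_000, 1_200_000),
            self.seg("a", "2", 10, 5_000_000),
            self.seg("b", "1", 10, 17_000_000),
        ]
        table = classify_lengths(segs).set_index("class_mb")
        assert table["count"].tolist() == [2, 0, 1, 0, 1]
        assert table["percent"]["1-2"] == pytest.approx(50.0)

    def test_summary_counts_zero_roh_individuals(self):
        segs = [
            self.seg("a", "1", 10, 2_000_000),
            self.seg("a", "2", 10, 1_000_000),
            self.seg("b", "1", 10, 3_000_000),
        ]
        summary = summarize_roh(segs, ["a", "b", "c"], ["1", "2"])
        # per-individual counts 2, 1, 0
        assert summary.n_roh_mean == pytest.approx(1.0)
        assert summary.n_roh_sd == pytest.approx(1.0)
        per_ind = summary.per_individual.set_index("individual")
        assert per_ind["n_roh"]["c"] == 0
        # per-chromosome counts 2, 1
        assert summary.nc_roh_mean == pytest.approx(1.5)
        # mean segment length in Mb
        assert summary.l_roh_mean_mb == pytest.approx(2.0)
        assert summary.total_segments == 3

    def test_segments_frame_columns(self):
        frame = segments_frame([self.seg("a", "1", 100, 1_000_000)])
        assert frame.loc[0, "length_bp"] == 1_000_000
        assert frame.loc[0, "length_mb"] == pytest.approx(1.0)


class TestFroh:
    def test_froh_arithmetic(self):
        segs = [
            ROHSegment("a", "1", 1_000_000, 21_400_000, 100),
            ROHSegment("a", "2", 1_000_000, 21_400_000, 100),
        ]
        # 40.8 Mb / 2.4 Gb = 0.017
        assert froh(segs, "a") == pytest.approx(0.017)

    def test_custom_genome_length(self):
        segs = [ROHSegment("a", "1", 0, 1_000_000, 20)]
        assert froh(segs, "a", genome_length_bp=10_000_000) == pytest.approx(0.1)

    def test_missing_individual_is_zero(self):
        assert froh([], "nobody") == 0.0

    def test_overlapping_segments_rejected(self):
        segs = [
            ROHSegment("a", "1", 1_000_000, 3_000_000, 20),
            ROHSegment("a", "1", 2_500_000, 4_000_000, 20),
        ]
        with pytest.raises(ValueError, match="overlap"):
            froh(segs, "a")

    def test_table_covers_universe(self):
        segs = [ROHSegment("a", "1", 0, 2_400_000, 20)]
        table = froh_table(segs, ["a", "b"]).set_index("individual")
        assert table["froh"]["a"] == pytest.approx(0.001)
        assert table["froh"]["b"] == 0.0


class TestEndToEndPlanted:
    def test_planted_roh_recovered_exactly(self):
        ds, _ = dk.sim_structured(
            dk.StructuredSimConfig(
                n_pops=1, n_per_pop=10, n_loci=3000, n_autosomes=2,
                chrom_length_bp=55_000_000, seed=50,
            )
        )
        spec = dk.PlantedROHSpec(
            chrom="1", start_bp=10_000_000, end_bp=14_000_000,
            carrier_fraction=0.5, seed=50,
        )
        planted, truth = dk.plant_roh(ds, spec)
        segs = detect_roh(planted)
        planted_keys = {
            (t["individual"], t["chrom"], t["start_bp"], t["end_bp"]) for t in truth["segments"]
        }
        found_keys = {(s.individual, s.chrom, s.start_bp, s.end_bp) for s in segs}
        # every planted segment is found (possibly extended by flanking
        # homozygous markers, so compare by containment)
        for ind, chrom, start, end in planted_keys:
            assert any(
                s.individual == ind and s.chrom == chrom
                and s.start_bp <= start and s.end_bp >= end
                for s in segs
            ), (ind, chrom, start, end, sorted(found_keys))
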