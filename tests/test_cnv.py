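"""Joint coverage+BAF CNV caller: normalization, binary segmentation,
the event-class mapping, breakpoint-union partitioning, and arm rollups."""

import numpy as np
import pandas as pd
import pytest

from gliomapairs.allelic_imbalance import (
    AISegment,
    detect_ai,
    normal_folded_baseline,
    select_het_sites,
)
from gliomapairs.cnv import (
    arm_level_calls,
    call_cnv,
    classify_event,
    normalize_coverage,
    segment_bins,
    segment_log2,
    union_segments,
)
from gliomapairs.resources import load_arm_table
from gliomapairs.simulate import TrueSegment, simulate_tracks

ARMS = load_arm_table()
CHR1 = ARMS.query("chrom == 'chr1'").reset_index(drop=True)


def flat_track(n=200, depth=100, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": np.arange(1, n + 1) * 1000,
            "tumor_depth": [depth] * n,
        }
    )


class TestNormalizeCoverage:
    def test_identical_tracks_give_zero_log_ratio(self):
        t = flat_track()
        bins = normalize_coverage(t, t.copy(), bin_size=10)
        assert np.allclose(bins["log2_ratio"], 0.0)

    def test_constant_depth_offset_cancels_by_median_scaling(self):
        t = flat_track(depth=100)
        n = flat_track(depth=50)
        bins = normalize_coverage(t, n, bin_size=10)
        assert np.allclose(bins["log2_ratio"], 0.0)

    def test_doubled_tumor_region_scores_log2_of_two(self):
        t = flat_track(n=300)
        t.loc[200:, "tumor_depth"] = 200  # focal region; median stays 100
        bins = normalize_coverage(t, flat_track(n=300), bin_size=10)
        assert np.allclose(bins["log2_ratio"].iloc[-5:], 1.0)

    def test_low_normal_depth_bins_dropped(self):
        t = flat_track(n=100)
        n = flat_track(n=100)
        n.loc[:19, "tumor_depth"] = 3
        bins = normalize_coverage(t, n, bin_size=10, min_normal_depth=10)
        assert len(bins) == 8

    def test_mismatched_positions_rejected(self):
        t = flat_track()
        n = flat_track()
        n.loc[0, "pos"] = 999999
        with pytest.raises(ValueError, match="share positions"):
            normalize_coverage(t, n)


class TestSegmentLog2:
    def test_constant_signal_is_one_segment(self):
        segs = segment_log2(np.zeros(100))
        assert len(segs) == 1
        assert segs[0] == (0, 100, 0.0)

    def test_single_step_breakpoint_localized(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.zeros(50), -np.ones(50)]) + rng.normal(0, 0.1, 100)
        segs = segment_log2(x)
        assert len(segs) == 2
        assert abs(segs[0][1] - 50) <= 2

    def test_two_steps_yield_three_segments(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.zeros(60), np.ones(60), np.zeros(60)])
        x += rng.normal(0, 0.1, 180)
        segs = segment_log2(x)
        assert len(segs) == 3

    def test_pure_noise_rarely_splits(self):
        rng = np.random.default_rng(3)
        n_split = sum(
            len(segment_log2(rng.normal(0, 0.1, 100))) > 1 for _ in range(50)
        )
        assert n_split <= 2


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "cov,ai,expected",
        [
            ("gain", "imbalanced", "amplification"),
            ("gain", "balanced", "amplification"),
            ("loss", "imbalanced", "deletion"),
            ("loss", "balanced", "deletion"),
            ("neutral", "imbalanced", "cnLOH"),
            ("neutral", "balanced", "none"),
        ],
    )
    def test_total_deterministic_mapping(self, cov, ai, expected):
        assert classify_event(cov, ai) == expected

    def test_unknown_states_rejected(self):
        with pytest.raises(ValueError):
            classify_event("gain", "weird")


def ai_seg(chrom, start, end):
    return AISegment(chrom=chrom, arm="q", start=start, end=end,
                     n_sites=30, mean_folded_dev=0.3, q_value=0.001)


class TestUnionSegments:
    def test_breakpoint_union_produces_expected_cells(self):
        cov = pd.DataFrame(
            [{"chrom": "chr5", "start": 0, "end": 100, "n_bins": 10, "mean_log2": -1.0}]
        )
        events = union_segments(cov, [ai_seg("chr5", 50, 150)])
        intervals = [(e.start, e.end) for e in events]
        assert intervals == [(0, 50), (50, 100), (100, 150)]
        assert [e.event_class for e in events] == ["deletion", "deletion", "cnLOH"]

    def test_no_ai_reduces_to_coverage_segmentation(self):
        cov = pd.DataFrame(
            [
                {"chrom": "chr5", "start": 0, "end": 100, "n_bins": 10, "mean_log2": 0.0},
                {"chrom": "chr5", "start": 100, "end": 300, "n_bins": 20, "mean_log2": 1.0},
            ]
        )
        events = union_segments(cov, [])
        assert [(e.start, e.end) for e in events] == [(0, 100), (100, 300)]
        assert [e.event_class for e in events] == ["none", "amplification"]

    def test_identical_breakpoints_collapse_to_one_partition(self):
        cov = pd.DataFrame(
            [{"chrom": "chr5", "start": 10, "end": 90, "n_bins": 8, "mean_log2": 0.0}]
        )
        events = union_segments(cov, [ai_seg("chr5", 10, 90)])
        assert [(e.start, e.end) for e in events] == [(10, 90)]
        assert events[0].event_class == "cnLOH"

    def test_partition_is_disjoint_cover_of_hull(self):
        cov = pd.DataFrame(
            [
                {"chrom": "chr5", "start": 0, "end": 70, "n_bins": 7, "mean_log2": 0.5},
                {"chrom": "chr5", "start": 70, "end": 200, "n_bins": 13, "mean_log2": 0.0},
            ]
        )
        events = union_segments(cov, [ai_seg("chr5", 30, 120), ai_seg("chr5", 150, 260)])
        intervals = sorted((e.start, e.end) for e in events)
        assert intervals[0][0] == 0 and intervals[-1][1] == 260
        for (s1, e1), (s2, e2) in zip(intervals[:-1], intervals[1:]):
            assert e1 == s2  # contiguous, non-overlapping


class TestArmLevelCalls:
    def _segment_events(self, chrom, start, end, mean_log2, ai=False):
        cov = pd.DataFrame(
            [{"chrom": chrom, "start": start, "end": end, "n_bins": 50,
              "mean_log2": mean_log2}]
        )
        ais = [ai_seg(chrom, start, end)] if ai else []
        return union_segments(cov, ais)

    def test_whole_arm_deletion_called_at_arm_level(self):
        row = ARMS.query("chrom == 'chr17' and arm == 'q'").iloc[0]
        events = self._segment_events("chr17", int(row.start), int(row.end), -1.0)
        calls = arm_level_calls(events)
        assert any(
            c.chrom == "chr17" and c.arm == "q" and c.event_class == "deletion"
            for c in calls
        )

    def test_small_fraction_of_arm_not_called(self):
        row = ARMS.query("chrom == 'chr17' and arm == 'q'").iloc[0]
        lo = int(row.start)
        events = self._segment_events("chr17", lo, lo + int(0.1 * (row.end - lo)), -1.0)
        # pad the rest of the arm as neutral so the analyzable extent is the arm
        cov = pd.DataFrame(
            [
                {"chrom": "chr17", "start": lo, "end": lo + int(0.1 * (row.end - lo)),
                 "n_bins": 5, "mean_log2": -1.0},
                {"chrom": "chr17", "start": lo + int(0.1 * (row.end - lo)),
                 "end": int(row.end), "n_bins": 45, "mean_log2": 0.0},
            ]
        )
        events = union_segments(cov, [])
        assert arm_level_calls(events) == []


class TestEndToEnd:
    def test_swapping_tumor_and_normal_flips_gain_and_loss(self):
        plant = TrueSegment("chr1", 130_000_000, 240_000_000, "deletion")
        rng = np.random.default_rng(9)
        track = simulate_tracks([plant], 600, 100.0, rng, purity=1.0,
                                arm_table=CHR1)
        tumor = track[["chrom", "pos"]].assign(tumor_depth=track["tumor_depth"])
        normal = track[["chrom", "pos"]].assign(tumor_depth=track["normal_depth"])
        fwd, _ = call_cnv(tumor, normal, [], arm_table=CHR1)
        rev, _ = call_cnv(normal, tumor, [], arm_table=CHR1)

        def classes_on_plant(events):
            return {
                e.event_class
                for e in events
                if e.chrom == plant.chrom
                and min(e.end, plant.end) - max(e.start, plant.start)
                > 0.5 * (plant.end - plant.start)
            }

        assert classes_on_plant(fwd) == {"deletion"}
        assert classes_on_plant(rev) == {"amplification"}

    def test_planted_deletion_with_purity_one_scores_minus_one(self):
        # genome-wide track: the median baseline must come from the
        # unaltered majority of the genome
        plant = TrueSegment("chr1", 130_000_000, 240_000_000, "deletion")
        rng = np.random.default_rng(10)
        track = simulate_tracks([plant], 4000, 100.0, rng, purity=1.0,
                                arm_table=ARMS)
        normal = track[["chrom", "pos"]].assign(tumor_depth=track["normal_depth"])
        bins = normalize_coverage(track, normal, bin_size=10)
        on = bins[
            (bins.chrom == plant.chrom)
            & (bins.start >= plant.start)
            & (bins.end <= plant.end)
        ]
        assert on["log2_ratio"].mean() == pytest.approx(-1.0, abs=0.15)
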