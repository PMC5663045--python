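"""Synthetic cohort generator: determinism, planted-truth structure, and
the read-count / track models."""

import json

import numpy as np
import pytest

from gliomapairs.resources import load_arm_table
from gliomapairs.simulate import (
    CohortConfig,
    GroundTruth,
    TrueSegment,
    noise_free_config,
    simulate_cohort,
    simulate_read_support,
    simulate_tracks,
)
from gliomapairs.variants import CALLERS
from tests.conftest import THREE_GROUPS, small_config


def _vcf_keys(path):
    keys = set()
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            continue
        chrom, pos, _, ref, alt = line.split("\t")[:5]
        keys.add((chrom, int(pos), ref, alt))
    return keys


class TestSimulateCohort:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = small_config()
        _, _ = simulate_cohort(cfg, tmp_path / "a")
        _, _ = simulate_cohort(small_config(), tmp_path / "b")
        man_a = json.loads((tmp_path / "a" / "manifest.json").read_text())
        man_b = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert man_a["files"] == man_b["files"]  # sha256 per file
        assert man_a["config_hash"] == man_b["config_hash"]

    def test_different_seed_changes_outputs(self, tmp_path):
        _, _ = simulate_cohort(small_config(seed=11), tmp_path / "a")
        _, _ = simulate_cohort(small_config(seed=12), tmp_path / "b")
        man_a = json.loads((tmp_path / "a" / "manifest.json").read_text())
        man_b = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert man_a["files"] != man_b["files"]

    def test_noise_free_variants_shared_between_pair_members(self, tmp_path):
        cfg = noise_free_config(
            n_pairs=2,
            group_spec={"H3/IDH1 mutant": 0.5, "H3/IDH1 wildtype": 0.5},
            n_shared_passengers=3,
            n_primary_private=0,
            n_recurrence_private=0,
            hypermutator_pairs={},
            n_germline_snps=0,
            germline_pairs=(),
            n_baf_sites=100,
            n_probes=600,
            seed=3,
        )
        paths, truth = simulate_cohort(cfg, tmp_path)
        for pair_id, (primary, recurrence) in truth.pair_samples.items():
            for caller in CALLERS:
                p_keys = _vcf_keys(tmp_path / "vcf" / f"{primary}_{caller}.vcf")
                r_keys = _vcf_keys(tmp_path / "vcf" / f"{recurrence}_{caller}.vcf")
                assert p_keys == r_keys and p_keys

    def test_hypermutator_pair_has_multiplied_variant_count(self, tmp_path):
        cfg = small_config(hypermutator_pairs={1: 10}, caller_fp_rate=0.0)
        paths, truth = simulate_cohort(cfg, tmp_path)
        n_hyper = len(truth.somatic_keys("P02-R"))
        n_normal = len(truth.somatic_keys("P01-R"))
        assert n_hyper >= 5 * n_normal
        keys = _vcf_keys(tmp_path / "vcf" / "P02-R_freebayes.vcf")
        assert len(keys) >= 5 * n_normal * cfg.caller_sensitivity["freebayes"] * 0.8

    def test_ground_truth_round_trips_through_json(self, small_run):
        run_dir, paths, truth = small_run
        loaded = GroundTruth.from_json(paths["ground_truth"].read_text())
        assert loaded.group == truth.group
        assert loaded.somatic_keys("P01-P") == truth.somatic_keys("P01-P")
        assert loaded.segments == truth.segments

    def test_driver_co_occurrence_rule(self, small_run):
        """Every H3/IDH1 driver travels with a TP53 or ACVR1 partner."""
        _, _, truth = small_run
        for pair_id, group in truth.group.items():
            if group != "H3/IDH1 mutant":
                continue
            primary, _ = truth.pair_samples[pair_id]
            genes = {v.gene for v in truth.variants[primary] if v.origin == "driver"}
            assert genes & {"H3F3A", "HIST1H3B", "IDH1"}
            assert genes & {"TP53", "ACVR1"}

    def test_planted_segments_do_not_overlap_within_sample(self, small_run):
        _, _, truth = small_run
        for sample, segs in truth.segments.items():
            for i, a in enumerate(segs):
                assert not any(a.overlaps(b) for b in segs[i + 1:])

    def test_group_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(group_spec={"H3/IDH1 mutant": 0.5, "H3/IDH1 wildtype": 0.3})

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_shared_passengers", -1),
            ("caller_fp_rate", -0.5),
            ("tumor_purity", 0.0),
            ("mean_depth", -10),
            ("caller_sensitivity", {"freebayes": 1.2, "samtools": 1.0, "gatk": 1.0}),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            small_config(**{field: value})


class TestReadSupport:
    def test_zero_clonal_fraction_yields_zero_alt(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ref, alt = simulate_read_support(0.0, 0.8, 100, rng)
            assert alt == 0 and ref == 100

    def test_empirical_maf_matches_binomial_mean(self):
        # clonal, purity 0.6: expected MAF = 0.6/2 = 0.30
        rng = np.random.default_rng(1)
        _, alt = simulate_read_support(1.0, 0.6, 10_000, rng)
        assert abs(alt / 10_000 - 0.30) < 0.01

    def test_deterministic_mode_returns_expectation(self):
        rng = np.random.default_rng(2)
        ref, alt = simulate_read_support(1.0, 1.0, 100, rng, deterministic=True)
        assert (ref, alt) == (50, 50)

    @pytest.mark.parametrize(
        "cf,purity,depth", [(-0.1, 0.8, 100), (0.5, 0.0, 100), (0.5, 0.8, 0)]
    )
    def test_out_of_range_arguments_raise(self, cf, purity, depth):
        with pytest.raises(ValueError):
            simulate_read_support(cf, purity, depth, np.random.default_rng(0))


class TestTracks:
    arms = load_arm_table()
    chr1 = arms[arms.chrom == "chr1"].reset_index(drop=True)

    def _on_segment(self, track, seg):
        return track[
            (track.chrom == seg.chrom)
            & (track.pos > seg.start)
            & (track.pos <= seg.end)
        ]

    def test_null_genome_folded_deviation_small(self):
        rng = np.random.default_rng(5)
        track = simulate_tracks([], 400, 100.0, rng, arm_table=self.chr1)
        baf = track.alt_reads / (track.ref_reads + track.alt_reads)
        assert np.abs(baf - 0.5).mean() < 0.1

    def test_cnloh_shifts_baf_but_not_coverage(self):
        seg = TrueSegment("chr1", 130_000_000, 240_000_000, "cnLOH")
        rng = np.random.default_rng(6)
        track = simulate_tracks([seg], 400, 100.0, rng, arm_table=self.chr1)
        on = self._on_segment(track, seg)
        log2 = np.log2(on.tumor_depth / on.normal_depth)
        baf = on.alt_reads / (on.ref_reads + on.alt_reads)
        assert abs(log2.mean()) < 0.1
        assert np.abs(baf - 0.5).mean() > 0.2

    def test_deletion_drops_coverage(self):
        seg = TrueSegment("chr1", 130_000_000, 240_000_000, "deletion")
        rng = np.random.default_rng(7)
        track = simulate_tracks(
            [seg], 400, 100.0, rng, purity=1.0, arm_table=self.chr1
        )
        on = self._on_segment(track, seg)
        log2 = np.log2(on.tumor_depth / on.normal_depth)
        assert log2.mean() < -0.5

    def test_overlapping_planted_segments_rejected(self):
        segs = [
            TrueSegment("chr1", 0, 100_000_000, "deletion"),
            TrueSegment("chr1", 50_000_000, 150_000_000, "cnLOH"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_tracks(segs, 100, 80.0, np.random.default_rng(0),
                            arm_table=self.chr1)
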