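"""Recovery and calibration experiments against planted ground truth.

These experiments quantify, on synthetic cohorts, the properties the
pipeline is designed to have: exact recovery of shared/private partitions
and molecular groups under noise-free conditions, calibrated false-positive
behavior of the allelic-imbalance detector under the null, sensitivity /
precision of AI segment recovery, per-class F1 of the joint CNV caller,
arm-level cnLOH recall on a genome-wide copy-neutral plant, and methylation
pair co-clustering. They are shared between the test suite and the
acceptance script.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gliomapairs.allelic_imbalance import (
    detect_ai,
    normal_folded_baseline,
    select_het_sites,
)
from gliomapairs.cnv import CNLOH, call_cnv
from gliomapairs.pipeline import PipelineConfig, run_pipeline
from gliomapairs.simulate import (
    CNLOH as SEG_CNLOH,
    CohortConfig,
    TrueSegment,
    noise_free_config,
    simulate_cohort,
    simulate_tracks,
)
from gliomapairs.temporal import paired_t_test


def _single_chrom_arms(chrom: str = "chr1") -> pd.DataFrame:
    from gliomapairs.resources import load_arm_table

    arms = load_arm_table()
    return arms[arms["chrom"] == chrom].reset_index(drop=True)


def _subset_arms(chroms: Sequence[str]) -> pd.DataFrame:
    from gliomapairs.resources import load_arm_table

    arms = load_arm_table()
    return arms[arms["chrom"].isin(chroms)].reset_index(drop=True)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


# ---------------------------------------------------------------------------
# allelic imbalance


def ai_null_fp_rate(
    n_sims: int = 1000,
    seed: int = 0,
    n_sites: int = 200,
    depth: float = 100.0,
    window: int = 25,
    alpha: float = 0.05,
) -> float:
    """Fraction of balanced-genome simulations yielding any AI segment.

    With Benjamini-Hochberg control at ``alpha`` across the sample's
    windows, the expected fraction under the global null is about alpha.
    """
    arms = _single_chrom_arms()
    rng = np.random.default_rng(seed)
    n_fp = 0
    for _ in range(n_sims):
        track = simulate_tracks(
            [], n_sites=n_sites, mean_depth=depth, rng=rng, arm_table=arms
        )
        sites = select_het_sites(track)
        baseline = normal_folded_baseline(track)
        if detect_ai(sites, window=window, alpha=alpha, arm_table=arms,
                     baseline=baseline):
            n_fp += 1
    return n_fp / n_sims


def ai_recovery(
    n_sims: int = 100,
    seed: int = 0,
    depth: float = 80.0,
    n_sites: int = 400,
    segment_sites: int = 40,
    window: int = 25,
    alpha: float = 0.05,
    min_overlap_fraction: float = 0.5,
) -> dict[str, float]:
    """Sensitivity and precision of planted single-copy AI segment recovery.

    Each simulation plants one copy-neutral-LOH segment spanning
    ``segment_sites`` heterozygous sites on chr1q at mean depth ``depth``.
    A plant counts as recovered when a detected segment covers at least
    ``min_overlap_fraction`` of it; a detected segment counts as correct
    when it overlaps the plant at all.
    """
    arms = _single_chrom_arms()
    rng = np.random.default_rng(seed)
    chrom_len = int(arms["end"].max())
    q_start = int(arms[arms["arm"] == "q"]["start"].iloc[0])
    spacing = chrom_len / n_sites
    n_recovered = 0
    n_detected = 0
    n_correct = 0
    for _ in range(n_sims):
        seg_len = int(segment_sites * spacing)
        start = int(rng.integers(q_start, chrom_len - seg_len))
        plant = TrueSegment("chr1", start, start + seg_len, SEG_CNLOH)
        track = simulate_tracks(
            [plant], n_sites=n_sites, mean_depth=depth, rng=rng, arm_table=arms
        )
        sites = select_het_sites(track)
        detected = detect_ai(
            sites, window=window, alpha=alpha, arm_table=arms,
            baseline=normal_folded_baseline(track),
        )
        n_detected += len(detected)
        covered = sum(
            _overlap(s.start, s.end, plant.start, plant.end) for s in detected
        )
        if covered >= min_overlap_fraction * (plant.end - plant.start):
            n_recovered += 1
        n_correct += sum(
            _overlap(s.start, s.end, plant.start, plant.end) > 0 for s in detected
        )
    return {
        "sensitivity": n_recovered / n_sims,
        "precision": n_correct / n_detected if n_detected else float("nan"),
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# CNV


def cnv_recovery(
    n_sims: int = 100,
    seed: int = 0,
    depth: float = 80.0,
    sites_per_chrom: int = 1200,
    purity: float = 0.8,
    bin_size: int = 10,
    min_overlap_fraction: float = 0.5,
) -> dict[str, float]:
    """Per-class F1 of the joint caller on planted amp/del/cnLOH segments.

    Each simulation plants one amplification, one deletion and one cnLOH
    segment on separate chromosomes (chr1-chr3), each spanning >= 50
    coverage bins. F1 per class pools true/false positives and negatives
    across simulations.
    """
    chroms = ["chr1", "chr2", "chr3"]
    arms = _subset_arms(chroms)
    rng = np.random.default_rng(seed)
    classes = ["amplification", "deletion", "cnLOH"]
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    n_sites_total = sites_per_chrom * len(chroms)
    for _ in range(n_sims):
        plants = []
        for chrom, cls in zip(chroms, classes):
            sub = arms[arms["chrom"] == chrom]
            chrom_len = int(sub["end"].max())
            frac = rng.uniform(0.45, 0.6)
            length = int(chrom_len * frac)
            start = int(rng.integers(0, chrom_len - length))
            plants.append(TrueSegment(chrom, start, start + length, cls))
        track = simulate_tracks(
            plants, n_sites=n_sites_total, mean_depth=depth, rng=rng,
            purity=purity, arm_table=arms,
        )
        normal = track[["chrom", "pos"]].assign(tumor_depth=track["normal_depth"])
        sites = select_het_sites(track)
        ai_segs = detect_ai(
            sites, arm_table=arms, baseline=normal_folded_baseline(track)
        )
        seg_events, _ = call_cnv(
            track, normal, ai_segs, bin_size=bin_size, arm_table=arms
        )
        min_event_len = 0.25 * min(p.end - p.start for p in plants)
        for plant in plants:
            covered = sum(
                _overlap(e.start, e.end, plant.start, plant.end)
                for e in seg_events
                if e.chrom == plant.chrom and e.event_class == plant.event_class
            )
            if covered >= min_overlap_fraction * (plant.end - plant.start):
                tp[plant.event_class] += 1
            else:
                fn[plant.event_class] += 1
        # events below a quarter of the plant size reflect breakpoint
        # imprecision at union-cell edges, not false discoveries
        for e in seg_events:
            if e.event_class not in classes or e.length < min_event_len:
                continue
            hits_plant = any(
                e.chrom == p.chrom
                and p.event_class == e.event_class
                and _overlap(e.start, e.end, p.start, p.end) > 0
                for p in plants
            )
            if not hits_plant:
                fp[e.event_class] += 1
    out = {}
    for c in classes:
        prec = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else float("nan")
        rec = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else float("nan")
        out[f"f1_{c}"] = (
            2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        )
    out["n_sims"] = n_sims
    return out


def whole_genome_cnloh_arm_recall(
    seed: int = 0,
    depth: float = 80.0,
    n_sites: int = 6000,
    bin_size: int = 10,
) -> dict[str, float]:
    """Arm-level cnLOH recall on a genome-wide copy-neutral-LOH plant
    (the radiotherapy-associated copy-number-neutral-genome phenotype):
    fraction of analyzable arms called cnLOH."""
    from gliomapairs.resources import load_arm_table

    arms = load_arm_table()
    rng = np.random.default_rng(seed)
    plants = [
        TrueSegment(r.chrom, int(r.start), int(r.end), SEG_CNLOH)
        for r in arms.itertuples()
    ]
    track = simulate_tracks(
        plants, n_sites=n_sites, mean_depth=depth, rng=rng, arm_table=arms
    )
    normal = track[["chrom", "pos"]].assign(tumor_depth=track["normal_depth"])
    sites = select_het_sites(track)
    ai_segs = detect_ai(
        sites, arm_table=arms, baseline=normal_folded_baseline(track)
    )
    seg_events, arm_events = call_cnv(
        track, normal, ai_segs, bin_size=bin_size, arm_table=arms
    )
    analyzable = {
        (e.chrom, e.arm) for e in seg_events
    }
    called = {
        (e.chrom, e.arm) for e in arm_events if e.event_class == CNLOH
    }
    return {
        "fraction_arms_cnloh": len(called & analyzable) / len(analyzable),
        "n_arms": len(analyzable),
    }


# ---------------------------------------------------------------------------
# end-to-end noise-free recovery and methylation co-clustering


def small_noise_free_config(seed: int = 0, **overrides) -> CohortConfig:
    """Desk-scale noise-free cohort covering all three molecular groups."""
    defaults = dict(
        n_pairs=4,
        group_spec={
            "H3/IDH1 mutant": 0.5,
            "H3/IDH1 wildtype": 0.25,
            "NF1 germline": 0.25,
        },
        n_shared_passengers=4,
        n_primary_private=2,
        n_recurrence_private=3,
        hypermutator_pairs={},
        n_germline_snps=6,
        germline_pairs=(0, 3),
        n_baf_sites=600,
        n_probes=1200,
        seed=seed,
    )
    defaults.update(overrides)
    return noise_free_config(**defaults)


def noise_free_recovery(seed: int = 0, **config_overrides) -> dict[str, float]:
    """Run the full pipeline on a noise-free cohort and compare partitions
    and group assignments with the planted truth.

    Returns the fraction of pairs whose shared/private partition matches
    ground truth exactly and the group-assignment accuracy.
    """
    config = small_noise_free_config(seed=seed, **config_overrides)
    with tempfile.TemporaryDirectory() as tmp:
        _, truth = simulate_cohort(config, tmp)
        results = run_pipeline(tmp, PipelineConfig(seed=config.seed))
    n_exact = 0
    n_group = 0
    for pair_id, part in results["partitions"].items():
        expected = truth.expected_partition(pair_id)
        if (
            part.shared == expected.shared
            and part.primary_only == expected.primary_only
            and part.recurrence_only == expected.recurrence_only
        ):
            n_exact += 1
        if results["assigned_groups"][pair_id] == truth.group[pair_id]:
            n_group += 1
    n = len(results["partitions"])
    return {
        "partition_exact_fraction": n_exact / n,
        "group_accuracy": n_group / n,
        "n_pairs": n,
    }


def coclustering_fraction(seed: int = 0, n_pairs: int = 8) -> dict[str, float]:
    """Pair co-clustering fraction at k=4 on a planted 4-subgroup cohort."""
    config = CohortConfig(
        n_pairs=n_pairs,
        group_spec={
            "H3/IDH1 mutant": 0.75,
            "H3/IDH1 wildtype": 0.125,
            "NF1 germline": 0.125,
        },
        n_baf_sites=200,
        n_probes=2000,
        hypermutator_pairs={},
        germline_pairs=(n_pairs - 1,),
        seed=seed,
    )
    from gliomapairs.methylation import (
        BetaMatrix,
        cluster_samples,
        filter_probes,
        pair_co_clustering,
        select_top_variable,
    )
    from gliomapairs.simulate import _simulate_beta, assign_groups

    # generate only the methylation layer (the other layers are irrelevant)
    rng = np.random.default_rng(config.seed)
    groups = assign_groups(config)
    meth_map = {}
    pair_samples = {}
    from gliomapairs.simulate import _H3_IDH1_TEMPLATES, WT

    t_idx = 0
    for i, g in enumerate(groups):
        pair_id = f"P{i + 1:02d}"
        pair_samples[pair_id] = (f"{pair_id}-P", f"{pair_id}-R")
        if g == "H3/IDH1 mutant":
            meth_map[pair_id] = _H3_IDH1_TEMPLATES[t_idx % len(_H3_IDH1_TEMPLATES)][1]
            t_idx += 1
        else:
            meth_map[pair_id] = WT
    values, annotation = _simulate_beta(config, meth_map, pair_samples, rng)
    m = filter_probes(BetaMatrix(values=values, annotation=annotation))
    m = select_top_variable(m, n_probes=min(1000, len(m.probe_ids)))
    result = cluster_samples(m, k=4)
    _, fraction = pair_co_clustering(result, pair_samples)
    return {"co_clustering_fraction": fraction, "n_pairs": len(pair_samples)}


# ---------------------------------------------------------------------------
# paired t-test agreement


def brute_force_paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Independent elementwise implementation of the paired t-test used as
    an oracle: explicit loops for mean and variance, p from the regularized
    incomplete beta form of the t CDF."""
    n = len(x)
    d = [float(a) - float(b) for a, b in zip(x, y)]
    mean = sum(d) / n
    ss = sum((v - mean) ** 2 for v in d)
    sd = math.sqrt(ss / (n - 1))
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    # two-sided p via the incomplete beta function: P(|T| > t)
    x_beta = df / (df + t * t)
    p = stats.beta.cdf(x_beta, df / 2.0, 0.5)
    return t, p


def ttest_agreement(n_trials: int = 1000, seed: int = 0, n: int = 8) -> dict[str, float]:
    """Max |t| and |p| discrepancies between the pipeline's paired t-test
    and the brute-force oracle over random inputs."""
    rng = np.random.default_rng(seed)
    max_dt = 0.0
    max_dp = 0.0
    for _ in range(n_trials):
        x = rng.normal(0, 5, size=n)
        y = x + rng.normal(1, 3, size=n)
        res = paired_t_test(x, y)
        t_ref, p_ref = brute_force_paired_t(x, y)
        max_dt = max(max_dt, abs(res.t - t_ref))
        max_dp = max(max_dp, abs(res.p - p_ref))
    return {"max_t_diff": max_dt, "max_p_diff": max_dp, "n_trials": n_trials}
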