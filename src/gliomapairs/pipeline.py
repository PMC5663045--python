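"""End-to-end orchestration over a cohort run directory.

A run directory (as produced by :func:`gliomapairs.simulate.simulate_cohort`)
contains per-caller VCFs, per-pair normal read counts, per-sample
coverage/BAF tracks, an annotation table, methylation matrices and a
clinical table. ``run_pipeline`` executes every analysis stage and writes
its result tables under ``<run_dir>/results``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from gliomapairs import io as gio
from gliomapairs.allelic_imbalance import (
    AIComparison,
    compare_ai_regions,
    detect_ai,
    normal_folded_baseline,
    segments_to_frame,
    select_het_sites,
)
from gliomapairs.cnv import call_cnv, events_to_frame
from gliomapairs.cohort import (
    burden_table,
    compare_burdens,
    read_clinical_table,
    summarize_clinical,
)
from gliomapairs.methylation import (
    BetaMatrix,
    cluster_samples,
    filter_probes,
    pair_co_clustering,
    select_top_variable,
)
from gliomapairs.temporal import assign_group, conservation_matrix, partition_pair
from gliomapairs.resources import load_pathway_map
from gliomapairs.variants import (
    CALLERS,
    FILTERED,
    FilterPolicy,
    build_consensus,
    annotate_variants,
    consensus_to_frame,
    read_caller_vcfs,
    run_filter_cascade,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Per-stage parameters of a full run."""

    policy: FilterPolicy = field(default_factory=FilterPolicy)
    ai_window: int = 25
    ai_alpha: float = 0.05
    ai_min_depth: int = 10
    min_median_depth: float = 20.0  # pairs below this are excluded from AI/CNV
    cnv_bin_size: int = 10
    cnv_penalty: float = 3.0
    cnv_gain_threshold: float = 0.3
    cnv_loss_threshold: float = -0.3
    cnv_arm_fraction: float = 0.7
    n_top_probes: int = 3000
    k_clusters: int = 4
    correlation_method: str = "pearson"
    seed: int = 0


def _caller_vcf_paths(vcf_dir: Path, sample_id: str) -> dict[str, Path]:
    return {c: vcf_dir / f"{sample_id}_{c}.vcf" for c in CALLERS}


def filter_sample(
    run_dir: Path,
    sample_id: str,
    pair_id: str,
    policy: FilterPolicy,
    annotation: pd.DataFrame,
) -> list:
    """Run the filter cascade for one tumor sample of a run directory."""
    calls = read_caller_vcfs(_caller_vcf_paths(run_dir / "vcf", sample_id), sample_id)
    normal_path = run_dir / "normal_counts" / f"{pair_id}.tsv"
    normal_lookup = gio.read_normal_counts(normal_path) if normal_path.exists() else None
    return run_filter_cascade(
        calls, policy, annotation=annotation, normal_alt_lookup=normal_lookup
    )


def germline_consensus(
    run_dir: Path, pair_id: str, policy: FilterPolicy, annotation: pd.DataFrame
) -> list:
    """Consensus germline variants from the pair's normal-sample VCFs."""
    normal_id = f"{pair_id}-N"
    paths = _caller_vcf_paths(run_dir / "vcf", normal_id)
    if not paths[CALLERS[0]].exists():
        return []
    calls = read_caller_vcfs(paths, normal_id)
    variants = build_consensus(calls, policy)
    variants = annotate_variants(variants, annotation)
    return [v for v in variants if v.status != FILTERED]


def run_pipeline(
    run_dir: str | Path, config: PipelineConfig | None = None
) -> dict[str, Any]:
    """Execute all stages on a run directory; returns in-memory results and
    writes tables under ``<run_dir>/results``."""
    run_dir = Path(run_dir)
    config = config or PipelineConfig()
    results_dir = run_dir / "results"
    results_dir.mkdir(exist_ok=True)

    pairs = read_clinical_table(run_dir / "clinical.tsv")
    annotation = gio.read_annotation(run_dir / "annotation.tsv")

    partitions = {}
    assigned_groups = {}
    kept_variants: dict[str, list] = {}
    gene_of: dict[tuple, str] = {}
    consensus_frames = []
    for pair in pairs:
        pair_variants = {}
        for sample_id in (pair.primary_sample_id, pair.recurrence_sample_id):
            variants = filter_sample(
                run_dir, sample_id, pair.patient_id, config.policy, annotation
            )
            pair_variants[sample_id] = [v for v in variants if v.status != FILTERED]
            kept_variants[sample_id] = pair_variants[sample_id]
            consensus_frames.append(consensus_to_frame(variants))
            for v in pair_variants[sample_id]:
                if v.gene:
                    gene_of[v.key] = v.gene
        partitions[pair.patient_id] = partition_pair(
            pair_variants[pair.primary_sample_id],
            pair_variants[pair.recurrence_sample_id],
        )
        germ = germline_consensus(run_dir, pair.patient_id, config.policy, annotation)
        assigned_groups[pair.patient_id] = assign_group(
            pair_variants[pair.primary_sample_id]
            + pair_variants[pair.recurrence_sample_id],
            germ,
        )
        pair.molecular_group = assigned_groups[pair.patient_id]
    pd.concat(consensus_frames, ignore_index=True).to_csv(
        results_dir / "consensus_variants.tsv", sep="\t", index=False
    )
    matrix = conservation_matrix(partitions, gene_of, load_pathway_map())
    matrix.to_csv(results_dir / "conservation_matrix.tsv", sep="\t")

    # allelic imbalance + CNV
    ai_segments: dict[str, list] = {}
    ai_comparisons: dict[str, AIComparison] = {}
    cnv_frames = []
    excluded_pairs = []
    for pair in pairs:
        tracks = {}
        median_depths = {}
        for sample_id in (pair.primary_sample_id, pair.recurrence_sample_id):
            track = gio.read_track(run_dir / "tracks" / f"{sample_id}.tsv")
            tracks[sample_id] = track
            median_depths[sample_id] = float(
                np.median(track["ref_reads"] + track["alt_reads"])
            )
        if min(median_depths.values()) < config.min_median_depth:
            log.warning(
                "pair %s excluded from AI/CNV: median depth %.1f below %.1f",
                pair.patient_id, min(median_depths.values()), config.min_median_depth,
            )
            excluded_pairs.append(pair.patient_id)
            continue
        for sample_id, track in tracks.items():
            sites = select_het_sites(track, min_depth=config.ai_min_depth)
            baseline = normal_folded_baseline(track, min_depth=config.ai_min_depth)
            ai_segments[sample_id] = detect_ai(
                sites,
                window=config.ai_window,
                alpha=config.ai_alpha,
                baseline=baseline,
            )
        ai_comparisons[pair.patient_id] = compare_ai_regions(
            ai_segments[pair.primary_sample_id],
            ai_segments[pair.recurrence_sample_id],
        )
        if pair.germline_available:
            for sample_id, track in tracks.items():
                normal_track = track[["chrom", "pos"]].assign(
                    tumor_depth=track["normal_depth"]
                )
                seg_events, arm_events = call_cnv(
                    track,
                    normal_track,
                    ai_segments[sample_id],
                    bin_size=config.cnv_bin_size,
                    penalty=config.cnv_penalty,
                    gain_threshold=config.cnv_gain_threshold,
                    loss_threshold=config.cnv_loss_threshold,
                    min_fraction=config.cnv_arm_fraction,
                )
                frame = events_to_frame(seg_events + arm_events)
                frame.insert(0, "sample_id", sample_id)
                cnv_frames.append(frame)
    ai_rows = []
    for sample_id, segs in ai_segments.items():
        if not segs:
            continue
        frame = segments_to_frame(segs)
        frame.insert(0, "sample_id", sample_id)
        ai_rows.append(frame)
    if ai_rows:
        pd.concat(ai_rows, ignore_index=True).to_csv(
            results_dir / "ai_segments.tsv", sep="\t", index=False
        )
    if cnv_frames:
        pd.concat(cnv_frames, ignore_index=True).to_csv(
            results_dir / "cnv_events.tsv", sep="\t", index=False
        )

    # methylation
    beta = pd.read_csv(run_dir / "methylation" / "beta.tsv", sep="\t", index_col=0)
    probe_ann = pd.read_csv(
        run_dir / "methylation" / "probe_annotation.tsv", sep="\t", index_col=0
    )
    m = filter_probes(BetaMatrix(values=beta, annotation=probe_ann))
    n_top = min(config.n_top_probes, len(m.probe_ids))
    m = select_top_variable(m, n_probes=n_top)
    clustering = cluster_samples(
        m, k=config.k_clusters, method=config.correlation_method
    )
    pair_map = {
        p.patient_id: (p.primary_sample_id, p.recurrence_sample_id) for p in pairs
    }
    co_clustered, co_fraction = pair_co_clustering(clustering, pair_map)
    (results_dir / "dendrogram.nwk").write_text(clustering.to_newick() + "\n")
    pd.DataFrame(
        {"sample_id": clustering.sample_ids,
         "cluster": [clustering.labels[s] for s in clustering.sample_ids]}
    ).to_csv(results_dir / "methylation_clusters.tsv", sep="\t", index=False)

    # cohort summaries
    summary = summarize_clinical(pairs)
    burdens = burden_table(partitions, ai_comparisons)
    burdens.to_csv(results_dir / "burden_table.tsv", sep="\t")
    try:
        tests = compare_burdens(burdens)
        test_payload = {
            name: {"t": r.t, "df": r.df, "p": r.p} for name, r in tests.items()
        }
    except ValueError as exc:  # zero-variance differences
        tests = {}
        test_payload = {"error": str(exc)}
    summary_payload = {
        "clinical": summary.to_dict(),
        "assigned_groups": assigned_groups,
        "paired_tests": test_payload,
        "pair_co_clustering": co_clustered,
        "co_clustering_fraction": co_fraction,
        "ai_excluded_pairs": excluded_pairs,
    }
    (results_dir / "cohort_summary.json").write_text(
        json.dumps(summary_payload, indent=2, sort_keys=True) + "\n"
    )
    gio.write_manifest(
        run_dir,
        config,
        config.seed,
        sorted(results_dir.glob("*")),
        extra={"stage": "pipeline"},
    )

    return {
        "pairs": pairs,
        "partitions": partitions,
        "assigned_groups": assigned_groups,
        "kept_variants": kept_variants,
        "conservation_matrix": matrix,
        "ai_segments": ai_segments,
        "ai_comparisons": ai_comparisons,
        "clustering": clustering,
        "co_clustered": co_clustered,
        "co_clustering_fraction": co_fraction,
        "summary": summary,
        "burden_table": burdens,
        "paired_tests": tests,
        "excluded_pairs": excluded_pairs,
    }
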