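"""Multi-caller consensus and the somatic filter cascade.

Per-caller VCFs for one tumor sample are merged into consensus variants
(kept when >= 2 of 3 callers agree and the representative caller shows
>= 10% read support), then passed through a mutant-allele-frequency tier
(5% floor for the genes-of-interest panel, >15% elsewhere), a matched-normal
somatic rule (zero alt reads in normal), and — when no normal exists —
population-frequency filters with a COSMIC / functional-impact rescue.

Each rule reads only its own fields and appends machine-readable codes to
``filter_reasons``; the final status is a pure function of the accumulated
evidence, so the cascade is order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: the three variant callers whose outputs are merged
CALLERS = ("freebayes", "samtools", "gatk")

#: relaxed-MAF panel: recurrently mutated pHGG genes where subclonal calls matter
GENES_OF_INTEREST = frozenset({"H3F3A", "TP53", "ATRX", "ZMYND11", "LZTR1"})

SOMATIC = "somatic"
PUTATIVE_SOMATIC = "putative_somatic"
REVIEW_FLAGGED = "review_flagged"
FILTERED = "filtered"

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantCall:
    """One caller's observation of one variant in one sample."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller: str
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}]"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterPolicy:
    """Thresholds of the filter cascade (defaults follow the study design)."""

    min_callers: int = 2
    min_read_support_fraction: float = 0.10
    goi_maf_min: float = 0.05  # inclusive floor for genes of interest
    other_maf_min: float = 0.15  # exclusive floor elsewhere
    genes_of_interest: frozenset[str] = GENES_OF_INTEREST
    pop_af_max_1000g_evs: float = 0.0005
    pop_af_max_exac: float = 0.00005
    normal_review_threshold: int = 2
    # The 10% read-support rule is waived for genes-of-interest variants so the
    # 5% MAF tier is reachable; set False to apply it uniformly.
    waive_read_support_for_goi: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.goi_maf_min <= self.other_maf_min < 1:
            raise ValueError(
                "require 0 < goi_maf_min <= other_maf_min < 1, got "
                f"{self.goi_maf_min}, {self.other_maf_min}"
            )


@dataclass
class ConsensusVariant:
    """Merged, annotated variant with somatic status and audit trail."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    callers_supporting: frozenset[str]
    depth: int
    alt_reads: int
    gene: str | None = None
    protein_change: str | None = None
    effect: str = "other"
    normal_alt_reads: int | None = None
    pop_af_1000g: float | None = None
    pop_af_evs: float | None = None
    pop_af_exac: float | None = None
    in_cosmic: bool = False
    functional_impact: str = "unknown"
    status: str = PUTATIVE_SOMATIC
    filter_reasons: list[str] = field(default_factory=list)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def maf(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0


def read_caller_vcfs(
    paths: Mapping[str, str | Path], sample_id: str
) -> list[VariantCall]:
    """Parse one VCF per caller into flat VariantCall records.

    Multi-allelic records are split (one call per ALT, with that allele's AD).
    Records lacking AD or DP are skipped with a warning. No indel
    normalization is attempted: variant keys are exact (chrom,pos,ref,alt)
    string matches.
    """
    calls: list[VariantCall] = []
    for caller, path in paths.items():
        vcf = VCF(str(path))
        n_skipped = 0
        for rec in vcf:
            try:
                ad = rec.format("AD")
                dp = rec.format("DP")
            except Exception:
                ad = dp = None
            if ad is None or dp is None:
                n_skipped += 1
                continue
            ad_row = [int(x) for x in ad[0]]
            depth = int(dp[0][0]) if dp[0][0] >= 0 else sum(ad_row)
            for i, alt in enumerate(rec.ALT):
                alt_reads = ad_row[i + 1] if i + 1 < len(ad_row) else 0
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        caller=caller,
                        depth=max(depth, alt_reads),
                        alt_reads=alt_reads,
                    )
                )
        if n_skipped:
            log.warning(
                "%s/%s: skipped %d records lacking AD/DP", sample_id, caller, n_skipped
            )
        vcf.close()
    return calls


def _resolve_status(v: ConsensusVariant, classification: str) -> str:
    return FILTERED if v.filter_reasons else classification


def build_consensus(
    calls: Sequence[VariantCall],
    policy: FilterPolicy | None = None,
    gene_lookup: Mapping[VariantKey, str] | None = None,
) -> list[ConsensusVariant]:
    """Merge per-caller calls for one sample into consensus variants.

    A variant is kept when supported by >= ``min_callers`` callers and the
    representative caller (the one with maximum depth — best-covered
    evidence) shows read support >= ``min_read_support_fraction``. Failed
    rules are recorded in ``filter_reasons`` rather than dropping the record.
    """
    policy = policy or FilterPolicy()
    if calls:
        samples = {c.sample_id for c in calls}
        if len(samples) > 1:
            raise ValueError(f"calls span multiple samples: {sorted(samples)}")
    by_key: dict[VariantKey, list[VariantCall]] = {}
    for call in calls:
        by_key.setdefault(call.key, []).append(call)

    out: list[ConsensusVariant] = []
    for key in sorted(by_key):
        group = by_key[key]
        # deterministic representative: max depth, caller name breaks ties
        rep = max(group, key=lambda c: (c.depth, c.caller))
        v = ConsensusVariant(
            sample_id=group[0].sample_id,
            chrom=key[0],
            pos=key[1],
            ref=key[2],
            alt=key[3],
            callers_supporting=frozenset(c.caller for c in group),
            depth=rep.depth,
            alt_reads=rep.alt_reads,
        )
        if gene_lookup is not None:
            v.gene = gene_lookup.get(key)
        if len(v.callers_supporting) < policy.min_callers:
            v.filter_reasons.append("insufficient_callers")
        is_goi = v.gene is not None and v.gene in policy.genes_of_interest
        waived = policy.waive_read_support_for_goi and is_goi
        if not waived and v.maf < policy.min_read_support_fraction:
            v.filter_reasons.append("low_read_support")
        v.status = _resolve_status(v, PUTATIVE_SOMATIC)
        out.append(v)
    return out


def annotate_variants(
    variants: Iterable[ConsensusVariant], annotation: pd.DataFrame
) -> list[ConsensusVariant]:
    """Join annotation columns (gene, effect, impact, COSMIC, population AFs)
    onto consensus variants by exact (chrom, pos, ref, alt) key."""
    idx = annotation.set_index(["chrom", "pos", "ref", "alt"])
    out = []
    for v in variants:
        if v.key in idx.index:
            row = idx.loc[v.key]
            v = replace(
                v,
                gene=str(row["gene"]),
                protein_change=(
                    str(row["protein_change"])
                    if pd.notna(row.get("protein_change"))
                    else None
                ),
                effect=str(row["effect"]),
                pop_af_1000g=float(row["pop_af_1000g"]),
                pop_af_evs=float(row["pop_af_evs"]),
                pop_af_exac=float(row["pop_af_exac"]),
                in_cosmic=bool(row["in_cosmic"]),
                functional_impact=str(row["functional_impact"]),
                filter_reasons=list(v.filter_reasons),
            )
        out.append(v)
    return out


def apply_maf_filter(v: ConsensusVariant, policy: FilterPolicy | None = None) -> ConsensusVariant:
    """Two-tier MAF rule: genes of interest pass at >= 5% (inclusive),
    everything else needs MAF > 15% (exclusive)."""
    policy = policy or FilterPolicy()
    v = replace(v, filter_reasons=list(v.filter_reasons))
    is_goi = v.gene is not None and v.gene in policy.genes_of_interest
    kept = (is_goi and v.maf >= policy.goi_maf_min) or v.maf > policy.other_maf_min
    if not kept:
        v.filter_reasons.append("maf_below_threshold")
    v.status = _resolve_status(
        v, v.status if v.status in (SOMATIC, REVIEW_FLAGGED) else PUTATIVE_SOMATIC
    )
    return v


def classify_somatic_with_normal(
    v: ConsensusVariant,
    normal_alt_reads: int,
    policy: FilterPolicy | None = None,
) -> ConsensusVariant:
    """Matched-normal somatic rule.

    Zero alt reads in the normal -> somatic; fewer than the review threshold
    (default 2) -> review_flagged (the study resolved these by manual
    inspection of alignments, which a pipeline cannot reproduce); at or above
    the threshold -> filtered as present_in_normal.
    """
    policy = policy or FilterPolicy()
    if normal_alt_reads < 0:
        raise ValueError(f"normal_alt_reads must be >= 0, got {normal_alt_reads}")
    v = replace(v, normal_alt_reads=normal_alt_reads,
                filter_reasons=list(v.filter_reasons))
    if normal_alt_reads == 0:
        classification = SOMATIC
    elif normal_alt_reads < policy.normal_review_threshold:
        classification = REVIEW_FLAGGED
    else:
        v.filter_reasons.append("present_in_normal")
        classification = FILTERED
    v.status = _resolve_status(v, classification)
    return v


def classify_somatic_without_normal(
    v: ConsensusVariant, policy: FilterPolicy | None = None
) -> ConsensusVariant:
    """Putative-somatic rule when no matched normal exists.

    Known polymorphisms are removed on population allele frequency
    (1000 Genomes / EVS >= 5e-4, ExAC >= 5e-5; absent treated as 0, i.e.
    novel); survivors are reported only when in COSMIC or of high/medium
    functional impact.
    """
    policy = policy or FilterPolicy()
    v = replace(v, filter_reasons=list(v.filter_reasons))
    af_1000g = v.pop_af_1000g or 0.0
    af_evs = v.pop_af_evs or 0.0
    af_exac = v.pop_af_exac or 0.0
    if (
        af_1000g >= policy.pop_af_max_1000g_evs
        or af_evs >= policy.pop_af_max_1000g_evs
        or af_exac >= policy.pop_af_max_exac
    ):
        v.filter_reasons.append("population_polymorphism")
    if not (v.in_cosmic or v.functional_impact in ("high", "medium")):
        v.filter_reasons.append("no_somatic_evidence")
    v.status = _resolve_status(v, PUTATIVE_SOMATIC)
    return v


def run_filter_cascade(
    calls: Sequence[VariantCall],
    policy: FilterPolicy | None = None,
    annotation: pd.DataFrame | None = None,
    normal_alt_lookup: Mapping[VariantKey, int] | None = None,
) -> list[ConsensusVariant]:
    """Full per-sample cascade: consensus -> annotation -> MAF tier ->
    somatic classification (matched-normal when ``normal_alt_lookup`` is
    given, population/COSMIC rescue otherwise)."""
    policy = policy or FilterPolicy()
    gene_lookup = None
    if annotation is not None:
        gene_lookup = {
            (r.chrom, r.pos, r.ref, r.alt): r.gene
            for r in annotation.itertuples()
        }
    variants = build_consensus(calls, policy, gene_lookup=gene_lookup)
    if annotation is not None:
        variants = annotate_variants(variants, annotation)
    out = []
    for v in variants:
        v = apply_maf_filter(v, policy)
        if normal_alt_lookup is not None:
            v = classify_somatic_with_normal(
                v, normal_alt_lookup.get(v.key, 0), policy
            )
        else:
            v = classify_somatic_without_normal(v, policy)
        out.append(v)
    return out


def consensus_to_frame(variants: Iterable[ConsensusVariant]) -> pd.DataFrame:
    """Tabular view of consensus variants (one row per variant)."""
    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "callers_supporting": ",".join(sorted(v.callers_supporting)),
                "depth": v.depth,
                "alt_reads": v.alt_reads,
                "maf": v.maf,
                "gene": v.gene,
                "protein_change": v.protein_change,
                "effect": v.effect,
                "normal_alt_reads": v.normal_alt_reads,
                "in_cosmic": v.in_cosmic,
                "functional_impact": v.functional_impact,
                "status": v.status,
                "filter_reasons": ";".join(v.filter_reasons),
            }
        )
    return pd.DataFrame(rows)
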