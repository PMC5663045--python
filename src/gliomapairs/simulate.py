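"""Synthetic paired-tumor cohort generator with known ground truth.

Emulates the study design this package analyzes: a cohort of primary /
recurrence pediatric high-grade glioma pairs stratified into three molecular
groups (H3/IDH1 mutant with obligate TP53 or ACVR1 partners, H3/IDH1
wildtype, NF1 germline), with conserved clonal drivers, shared and private
subclonal passengers, an optional hypermutator pair, planted
amplification / deletion / copy-neutral-LOH segments, and methylation
subgroup structure (K27M, G34, IDH, WT).

The read-count model is intentionally minimal: a heterozygous variant at
clonal fraction f in a tumor of purity p on a diploid background yields
alt reads ~ Binomial(depth, p*f/2), which is exactly the quantity the MAF
filters act on. Caller behavior is modelled as per-caller detection
sensitivity plus uniform false positives at low MAF (< 0.15), exercising
the consensus and MAF rules. Germline variants sit at BAF 0.5 in tumor and
normal, exercising the zero-alt-in-normal rule and the population filters.

With ``deterministic_reads=True`` (and sensitivity 1, false-positive rate 0)
read counts are rounded expectations, so every downstream stage recovers the
planted truth exactly — the basis of the end-to-end recovery tests.

Everything is driven by one ``numpy`` Generator seeded from the config:
identical configs and seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gliomapairs import io as gio
from gliomapairs.resources import load_arm_table, load_gene_table
from gliomapairs.temporal import (
    H3_IDH1_MUTANT,
    H3_IDH1_WILDTYPE,
    NF1_GERMLINE,
    TemporalPartition,
)
from gliomapairs.variants import CALLERS

_BASES = ("A", "C", "G", "T")

DELETION, AMPLIFICATION, CNLOH = "deletion", "amplification", "cnLOH"

#: methylation subgroups (the canonical four)
K27M, G34, IDH, WT = "K27M", "G34R/V", "IDH1", "WT"

# Driver templates per molecular group; each entry is a list of
# (gene, protein_change, effect). H3/IDH1 templates honor the co-occurrence
# rule: every oncohistone/IDH1 driver travels with a TP53 partner except
# HIST1H3B K27M, whose obligate partner is ACVR1.
_H3_IDH1_TEMPLATES = [
    ([("H3F3A", "K27M", "missense"), ("TP53", "R273H", "missense")], K27M),
    ([("H3F3A", "K27M", "missense"), ("TP53", "R175H", "missense")], K27M),
    ([("H3F3A", "K27M", "missense"), ("TP53", "R248Q", "missense")], K27M),
    ([("HIST1H3B", "K27M", "missense"), ("ACVR1", "R258G", "missense")], K27M),
    ([("H3F3A", "G34V", "missense"), ("TP53", "R273C", "missense")], G34),
    ([("IDH1", "R132H", "missense"), ("TP53", "R158L", "missense")], IDH),
    ([("IDH1", "R132S", "missense"), ("TP53", "Y220C", "missense")], IDH),
]
_WILDTYPE_TEMPLATES = [
    [("TP53", "R282W", "missense"), ("ATRX", "E1307K", "missense"),
     ("EP300", "D1399N", "missense"), ("CDKN2A", "R80X", "stopgain")],
    [("ZMYND11", "Q586fs", "frameshift"), ("TP53", "G245S", "missense"),
     ("ATRX", "L1562P", "missense")],
    [("BRAF", "V600E", "missense"), ("TP53", "R273H", "missense")],
    [("ATRX", "R1426X", "stopgain"), ("TP53", "R213X", "stopgain")],
]
_NF1_SOMATIC = [("PPM1D", "L513X", "stopgain"), ("ATRX", "R907Q", "missense")]
_NF1_GERMLINE_DRIVER = ("NF1", "Q1399fs", "frameshift")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated cohort: 16 pairs split 7/7/2 across the
    molecular groups, 69x mean coverage, one hypermutator pair with a 10x
    mutation-count multiplier, and matched normals for 9 of 16 patients.
    """

    n_pairs: int = 16
    group_spec: dict[str, float] = field(
        default_factory=lambda: {
            H3_IDH1_MUTANT: 7 / 16,
            H3_IDH1_WILDTYPE: 7 / 16,
            NF1_GERMLINE: 2 / 16,
        }
    )
    n_shared_passengers: int = 8
    n_primary_private: int = 3
    n_recurrence_private: int = 5
    hypermutator_pairs: dict[int, int] = field(default_factory=lambda: {10: 10})
    caller_sensitivity: dict[str, float] = field(
        default_factory=lambda: {c: 0.95 for c in CALLERS}
    )
    caller_fp_rate: float = 2.0
    mean_depth: float = 69.0
    tumor_purity: float = 0.8
    seed: int = 0
    deterministic_reads: bool = False
    n_germline_snps: int = 20
    germline_pairs: tuple[int, ...] | None = None  # default: Table-1-like pattern
    # planted copy-number / allelic-imbalance structure
    n_shared_segments: int = 2
    n_primary_private_segments: int = 1
    n_recurrence_private_segments: int = 1
    segment_classes: tuple[str, ...] = (DELETION, CNLOH, AMPLIFICATION)
    whole_genome_cnloh_pairs: tuple[int, ...] = ()
    nf1_17q_loh: bool = True
    baf_shift: float = 0.3  # single-copy events: BAF centers 0.2 / 0.8
    amp_baf_shift: float = 0.17  # one-extra-copy events: ~0.33 / 0.67
    n_baf_sites: int = 4000
    # methylation
    n_probes: int = 8000
    informative_fraction: float = 0.2
    subgroup_shift: float = 0.3
    pair_noise_sd: float = 0.02
    sample_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        total = sum(self.group_spec.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"group fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.group_spec.values()):
            raise ValueError("group fractions must be non-negative")
        for name in ("n_shared_passengers", "n_primary_private",
                     "n_recurrence_private", "n_germline_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for caller, s in self.caller_sensitivity.items():
            if not 0 <= s <= 1:
                raise ValueError(f"sensitivity for {caller} outside [0,1]: {s}")
        if self.caller_fp_rate < 0:
            raise ValueError("caller_fp_rate must be non-negative")
        if not 0 < self.tumor_purity <= 1:
            raise ValueError(f"tumor_purity must be in (0,1], got {self.tumor_purity}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def default_germline_pairs(self) -> tuple[int, ...]:
        if self.germline_pairs is not None:
            return self.germline_pairs
        # 9-of-16 pattern of the emulated cohort, scaled to n_pairs; NF1
        # pairs always have a germline sample (their grouping requires it).
        base = (0, 1, 2, 7, 8, 9, 10, 14, 15)
        groups = assign_groups(self)
        out = {i for i in base if i < self.n_pairs}
        out |= {i for i, g in enumerate(groups) if g == NF1_GERMLINE}
        return tuple(sorted(out))


@dataclass(frozen=True)
class TrueVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    protein_change: str | None
    effect: str
    clonal_fraction: float
    origin: str  # driver | passenger | germline_driver | germline_snp
    shared: bool

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_germline(self) -> bool:
        return self.origin.startswith("germline")


@dataclass(frozen=True)
class TrueSegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    event_class: str

    def overlaps(self, other: "TrueSegment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GroundTruth:
    """Planted truth for one simulated cohort."""

    variants: dict[str, list[TrueVariant]]  # per sample (tumors)
    germline: dict[str, list[TrueVariant]]  # per pair
    segments: dict[str, list[TrueSegment]]  # per sample
    group: dict[str, str]  # per pair
    methylation_cluster: dict[str, str]  # per pair
    pair_samples: dict[str, tuple[str, str]]  # pair -> (primary, recurrence)

    def somatic_keys(self, sample_id: str) -> frozenset:
        return frozenset(
            v.key for v in self.variants[sample_id] if not v.is_germline
        )

    def expected_partition(self, pair_id: str) -> TemporalPartition:
        primary, recurrence = self.pair_samples[pair_id]
        p, r = self.somatic_keys(primary), self.somatic_keys(recurrence)
        return TemporalPartition(shared=p & r, primary_only=p - r, recurrence_only=r - p)

    def to_json(self) -> str:
        payload = {
            "variants": {
                s: [dataclasses.asdict(v) for v in vs]
                for s, vs in self.variants.items()
            },
            "germline": {
                p: [dataclasses.asdict(v) for v in vs]
                for p, vs in self.germline.items()
            },
            "segments": {
                s: [dataclasses.asdict(seg) for seg in segs]
                for s, segs in self.segments.items()
            },
            "group": self.group,
            "methylation_cluster": self.methylation_cluster,
            "pair_samples": {p: list(v) for p, v in self.pair_samples.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            variants={
                s: [TrueVariant(**v) for v in vs] for s, vs in raw["variants"].items()
            },
            germline={
                p: [TrueVariant(**v) for v in vs] for p, vs in raw["germline"].items()
            },
            segments={
                s: [TrueSegment(**seg) for seg in segs]
                for s, segs in raw["segments"].items()
            },
            group=raw["group"],
            methylation_cluster=raw["methylation_cluster"],
            pair_samples={p: tuple(v) for p, v in raw["pair_samples"].items()},
        )


def assign_groups(config: CohortConfig) -> list[str]:
    """Deterministic largest-remainder allocation of pairs to groups, in the
    order the groups are listed in the config."""
    groups = list(config.group_spec)
    raw = [config.group_spec[g] * config.n_pairs for g in groups]
    counts = [int(math.floor(r)) for r in raw]
    remainder = config.n_pairs - sum(counts)
    order = sorted(range(len(groups)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    out: list[str] = []
    for g, c in zip(groups, counts):
        out.extend([g] * c)
    return out


def simulate_read_support(
    clonal_fraction: float,
    purity: float,
    depth: int,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> tuple[int, int]:
    """(ref_reads, alt_reads) for a heterozygous variant on a diploid
    background: alt ~ Binomial(depth, purity * clonal_fraction / 2)."""
    if not 0 <= clonal_fraction <= 1:
        raise ValueError(f"clonal_fraction outside [0,1]: {clonal_fraction}")
    if not 0 < purity <= 1:
        raise ValueError(f"purity outside (0,1]: {purity}")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    p = purity * clonal_fraction / 2.0
    alt = int(round(depth * p)) if deterministic else int(rng.binomial(depth, p))
    return depth - alt, alt


def _coverage_multiplier(event_class: str, purity: float) -> float:
    if event_class == DELETION:
        return (2.0 - purity) / 2.0
    if event_class == AMPLIFICATION:
        return (2.0 + purity) / 2.0
    return 1.0


def simulate_tracks(
    segments: Sequence[TrueSegment],
    n_sites: int,
    mean_depth: float,
    rng: np.random.Generator,
    purity: float = 0.8,
    baf_shift: float = 0.3,
    amp_baf_shift: float = 0.17,
    arm_table: pd.DataFrame | None = None,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Per-site coverage/BAF track for one tumor sample.

    Heterozygous-site positions are laid out evenly per chromosome
    (proportional to length), so every sample of a cohort shares positions.
    Off-segment sites draw BAF around 0.5; on-segment sites draw around the
    shifted centers (0.5 +/- baf_shift for single-copy events and cnLOH,
    0.5 +/- amp_baf_shift for amplification), with the coverage multiplier
    applied to tumor depth for amp/del and unity for cnLOH.
    """
    arm_table = load_arm_table() if arm_table is None else arm_table
    for i, a in enumerate(segments):
        for b in segments[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"planted segments overlap: {a} / {b}")
    lengths = arm_table.groupby("chrom", sort=False)["end"].max()
    total = lengths.sum()
    chroms_out, pos_out = [], []
    for chrom, length in lengths.items():
        k = max(int(round(n_sites * length / total)), 1)
        positions = np.linspace(1, length, k).round().astype(int)
        chroms_out.extend([chrom] * k)
        pos_out.extend(positions.tolist())
    chroms = np.array(chroms_out)
    positions = np.array(pos_out)

    mult = np.ones(len(positions))
    shift = np.zeros(len(positions))
    for seg in segments:
        on = (chroms == seg.chrom) & (positions > seg.start) & (positions <= seg.end)
        mult[on] = _coverage_multiplier(seg.event_class, purity)
        shift[on] = amp_baf_shift if seg.event_class == AMPLIFICATION else baf_shift

    if deterministic:
        tumor_depth = np.maximum(np.round(mean_depth * mult), 1).astype(int)
        normal_depth = np.full(len(positions), int(round(mean_depth)))
    else:
        tumor_depth = np.maximum(rng.poisson(mean_depth * mult), 1)
        normal_depth = np.maximum(rng.poisson(mean_depth, len(positions)), 1)
    sign = rng.choice([-1.0, 1.0], size=len(positions))
    centers = 0.5 + sign * shift
    if deterministic:
        alt = np.round(tumor_depth * centers).astype(int)
        normal_alt = np.round(normal_depth * 0.5).astype(int)
    else:
        alt = rng.binomial(tumor_depth, centers)
        normal_alt = rng.binomial(normal_depth, 0.5)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref_reads": tumor_depth - alt,
            "alt_reads": alt,
            "tumor_depth": tumor_depth,
            "normal_depth": normal_depth,
            "normal_ref_reads": normal_depth - normal_alt,
            "normal_alt_reads": normal_alt,
        }
    )


class _PositionFactory:
    """Unique genomic positions: inside a named gene's locus for drivers,
    uniform over the autosomes for passengers and false positives."""

    def __init__(self, rng: np.random.Generator, arm_table: pd.DataFrame):
        self.rng = rng
        self.genes = load_gene_table().set_index("gene")
        lengths = arm_table.groupby("chrom", sort=False)["end"].max()
        self.chroms = list(lengths.index)
        self.lengths = lengths.to_numpy(dtype=float)
        self.weights = self.lengths / self.lengths.sum()
        self.used: set[tuple[str, int]] = set()

    def in_gene(self, gene: str) -> tuple[str, int]:
        row = self.genes.loc[gene]
        while True:
            pos = int(self.rng.integers(row["start"], row["end"]))
            if (row["chrom"], pos) not in self.used:
                self.used.add((row["chrom"], pos))
                return str(row["chrom"]), pos

    def anywhere(self) -> tuple[str, int]:
        while True:
            ci = int(self.rng.choice(len(self.chroms), p=self.weights))
            pos = int(self.rng.integers(1, int(self.lengths[ci])))
            if (self.chroms[ci], pos) not in self.used:
                self.used.add((self.chroms[ci], pos))
                return self.chroms[ci], pos

    def alleles(self) -> tuple[str, str]:
        ref, alt = self.rng.choice(4, size=2, replace=False)
        return _BASES[ref], _BASES[alt]


def _plant_variants(
    config: CohortConfig,
    groups: list[str],
    rng: np.random.Generator,
    factory: _PositionFactory,
) -> tuple[dict, dict, dict, dict, list[dict]]:
    """Plant true variants for every pair; returns per-sample variants,
    per-pair germline lists, group and methylation maps, and annotation rows."""
    variants: dict[str, list[TrueVariant]] = {}
    germline: dict[str, list[TrueVariant]] = {}
    group_map: dict[str, str] = {}
    meth_map: dict[str, str] = {}
    ann_rows: list[dict] = []
    gene_counter = 0
    template_idx = {H3_IDH1_MUTANT: 0, H3_IDH1_WILDTYPE: 0}

    def make(gene, pchange, effect, cf, origin, shared, named_gene=True):
        chrom, pos = factory.in_gene(gene) if named_gene else factory.anywhere()
        ref, alt = factory.alleles()
        return TrueVariant(chrom, pos, ref, alt, gene, pchange, effect,
                           cf, origin, shared)

    def annotate(v: TrueVariant, impact: str, cosmic: bool,
                 af_1000g=0.0, af_evs=0.0, af_exac=0.0):
        ann_rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "protein_change": v.protein_change or "",
                "effect": v.effect, "functional_impact": impact,
                "in_cosmic": cosmic, "pop_af_1000g": af_1000g,
                "pop_af_evs": af_evs, "pop_af_exac": af_exac,
            }
        )

    for i, group in enumerate(groups):
        pair_id = f"P{i + 1:02d}"
        primary, recurrence = f"{pair_id}-P", f"{pair_id}-R"
        mult = config.hypermutator_pairs.get(i, 1)
        group_map[pair_id] = group
        shared_vars: list[TrueVariant] = []
        germ: list[TrueVariant] = []

        if group == H3_IDH1_MUTANT:
            template, subgroup = _H3_IDH1_TEMPLATES[
                template_idx[group] % len(_H3_IDH1_TEMPLATES)
            ]
            template_idx[group] += 1
            meth_map[pair_id] = subgroup
            for gene, pchange, effect in template:
                v = make(gene, pchange, effect, 1.0, "driver", True)
                shared_vars.append(v)
                annotate(v, "high", True)
        elif group == H3_IDH1_WILDTYPE:
            template = _WILDTYPE_TEMPLATES[
                template_idx[group] % len(_WILDTYPE_TEMPLATES)
            ]
            template_idx[group] += 1
            meth_map[pair_id] = WT
            for gene, pchange, effect in template:
                v = make(gene, pchange, effect, 1.0, "driver", True)
                shared_vars.append(v)
                annotate(v, "high", True)
        else:  # NF1 germline
            meth_map[pair_id] = WT
            gv = make(*_NF1_GERMLINE_DRIVER, 1.0, "germline_driver", True)
            germ.append(gv)
            annotate(gv, "high", False)
            for gene, pchange, effect in _NF1_SOMATIC:
                v = make(gene, pchange, effect, 1.0, "driver", True)
                shared_vars.append(v)
                annotate(v, "high", True)

        def passenger(shared: bool) -> TrueVariant:
            nonlocal gene_counter
            gene_counter += 1
            effect = str(rng.choice(["missense", "frameshift", "stopgain", "splice"]))
            lo, hi = (0.6, 1.0) if shared else (0.45, 0.9)
            v = make(f"GENE{gene_counter:05d}", None, effect,
                     float(rng.uniform(lo, hi)), "passenger", shared,
                     named_gene=False)
            annotate(v, "medium", False)
            return v

        for _ in range(config.n_shared_passengers * mult):
            shared_vars.append(passenger(True))
        primary_private = [passenger(False) for _ in range(config.n_primary_private * mult)]
        recurrence_private = [passenger(False) for _ in range(config.n_recurrence_private * mult)]

        for _ in range(config.n_germline_snps):
            chrom, pos = factory.anywhere()
            ref, alt = factory.alleles()
            gv = TrueVariant(chrom, pos, ref, alt, "SNP", None, "missense",
                             1.0, "germline_snp", True)
            germ.append(gv)
            annotate(gv, "low", False, af_1000g=0.01, af_evs=0.01, af_exac=0.005)

        variants[primary] = shared_vars + primary_private + list(germ)
        variants[recurrence] = shared_vars + recurrence_private + list(germ)
        germline[pair_id] = germ
    return variants, germline, group_map, meth_map, ann_rows


def _plant_segments(
    config: CohortConfig,
    groups: list[str],
    rng: np.random.Generator,
    arm_table: pd.DataFrame,
) -> dict[str, list[TrueSegment]]:
    """Plant non-overlapping CNV/AI segments (one arm each, distinct arms
    within a pair) for every tumor sample."""
    arms = arm_table.reset_index(drop=True)
    segments: dict[str, list[TrueSegment]] = {}

    def random_segment(arm_row, event_class) -> TrueSegment:
        span = arm_row.end - arm_row.start
        frac = rng.uniform(0.3, 0.6)
        length = int(span * frac)
        start = int(arm_row.start + rng.integers(0, span - length))
        return TrueSegment(arm_row.chrom, start, start + length, event_class)

    for i, group in enumerate(groups):
        pair_id = f"P{i + 1:02d}"
        primary, recurrence = f"{pair_id}-P", f"{pair_id}-R"
        n_total = (
            config.n_shared_segments
            + config.n_primary_private_segments
            + config.n_recurrence_private_segments
        )
        arm_idx = rng.choice(len(arms), size=min(n_total, len(arms)), replace=False)
        classes = [
            config.segment_classes[k % len(config.segment_classes)]
            for k in range(n_total)
        ]
        segs = [
            random_segment(arms.iloc[int(a)], cls)
            for a, cls in zip(arm_idx, classes)
        ]
        shared = segs[: config.n_shared_segments]
        p_priv = segs[config.n_shared_segments : config.n_shared_segments + config.n_primary_private_segments]
        r_priv = segs[config.n_shared_segments + config.n_primary_private_segments :]
        segments[primary] = shared + p_priv
        segments[recurrence] = list(shared) + r_priv

        if group == NF1_GERMLINE and config.nf1_17q_loh:
            row = arms[(arms.chrom == "chr17") & (arms.arm == "q")].iloc[0]
            seg17q = TrueSegment("chr17", int(row.start), int(row.end), CNLOH)
            segments[recurrence] = [
                s for s in segments[recurrence] if not s.overlaps(seg17q)
            ] + [seg17q]
        if i in config.whole_genome_cnloh_pairs:
            segments[recurrence] = [
                TrueSegment(r.chrom, int(r.start), int(r.end), CNLOH)
                for r in arms.itertuples()
            ]
    return segments


def _simulate_beta(
    config: CohortConfig,
    meth_map: Mapping[str, str],
    pair_samples: Mapping[str, tuple[str, str]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta matrix (probes x samples) with subgroup structure and
    pair-correlated noise, plus probe annotation."""
    n = config.n_probes
    probe_ids = [f"cg{j:08d}" for j in range(n)]
    chrom_pool = [f"chr{c}" for c in range(1, 23)]
    chroms = rng.choice(chrom_pool, size=n).astype(object)
    sex = rng.random(n)
    chroms[sex < 0.04] = "chrX"
    chroms[(sex >= 0.04) & (sex < 0.05)] = "chrY"
    is_snp = rng.random(n) < 0.05
    is_cross = rng.random(n) < 0.05
    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "is_snp_probe": is_snp,
            "is_cross_reactive": is_cross,
        }
    ).set_index("probe_id")

    clean = ~(is_snp | is_cross | np.isin(chroms, ["chrX", "chrY"]))
    clean_idx = np.flatnonzero(clean)
    n_info = int(len(clean_idx) * config.informative_fraction)
    info_idx = rng.choice(clean_idx, size=n_info, replace=False)
    subgroups = (K27M, G34, IDH, WT)
    probe_subgroup = {
        int(j): subgroups[k % 4] for k, j in enumerate(np.sort(info_idx))
    }

    base = rng.beta(0.4, 0.4, size=n)
    base = np.clip(base, 0.02, 0.7)  # headroom for the subgroup shift

    columns: dict[str, np.ndarray] = {}
    for pair_id, (primary, recurrence) in pair_samples.items():
        subgroup = meth_map[pair_id]
        mean = base.copy()
        for j, s in probe_subgroup.items():
            if s == subgroup:
                mean[j] = mean[j] + config.subgroup_shift
        pair_effect = rng.normal(0.0, config.pair_noise_sd, size=n)
        for sample in (primary, recurrence):
            noise = rng.normal(0.0, config.sample_noise_sd, size=n)
            columns[sample] = np.clip(mean + pair_effect + noise, 0.0, 1.0)
    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    return values, annotation


def _simulate_clinical(
    config: CohortConfig,
    groups: list[str],
    meth_map: Mapping[str, str],
    germline_pairs: set[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    treatment_pool = [
        "RT+ TMZ, TMZ",
        "RT + TMZ, TMZ + bevacizumab",
        "RT, bevacizumab + irinotecan",
        "Surgery",
        "RT, VP16",
    ]
    for i, group in enumerate(groups):
        pair_id = f"P{i + 1:02d}"
        midline = meth_map[pair_id] == K27M
        rows.append(
            {
                "patient_id": pair_id,
                "primary_sample_id": f"{pair_id}-P",
                "recurrence_sample_id": f"{pair_id}-R",
                "molecular_group": group,
                "age_years": int(rng.integers(4, 30)),
                "sex": str(rng.choice(["M", "F"])),
                "primary_dx": "GBM",
                "recurrence_dx": "GBM",
                "ttp_months": round(float(rng.uniform(4, 45)), 1),
                "interval_months": round(float(rng.uniform(4, 66)), 1),
                "location": "midline" if midline else "hemisphere",
                "sublocation": "Pons" if midline else "",
                "surgery1": str(rng.choice(["GTR", "STR", "Biopsy"])),
                "surgery2": "NA (autopsy)",
                "germline_available": "Yes" if i in germline_pairs else "No",
                "treatments": str(rng.choice(treatment_pool)),
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a full cohort under ``out_dir``.

    Emits per-caller VCFs for each tumor and each available normal,
    per-pair normal read-count tables, per-sample coverage/BAF tracks, a
    cohort annotation table, the beta matrix with probe annotation, a
    clinical table, the ground truth, and a manifest. Identical configs and
    seeds produce byte-identical files.

    Returns (paths, ground_truth) where ``paths`` maps logical names to the
    emitted locations.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    arm_table = load_arm_table()
    factory = _PositionFactory(rng, arm_table)
    groups = assign_groups(config)
    germline_pairs = set(config.default_germline_pairs())

    variants, germline, group_map, meth_map, ann_rows = _plant_variants(
        config, groups, rng, factory
    )
    segments = _plant_segments(config, groups, rng, arm_table)
    pair_samples = {
        f"P{i + 1:02d}": (f"P{i + 1:02d}-P", f"P{i + 1:02d}-R")
        for i in range(config.n_pairs)
    }
    truth = GroundTruth(
        variants=variants,
        germline=germline,
        segments=segments,
        group=group_map,
        methylation_cluster=meth_map,
        pair_samples=pair_samples,
    )

    vcf_dir = out_dir / "vcf"
    track_dir = out_dir / "tracks"
    normal_dir = out_dir / "normal_counts"
    meth_dir = out_dir / "methylation"
    for d in (vcf_dir, track_dir, normal_dir, meth_dir):
        d.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    paths: dict[str, Path] = {}

    mean_depth_i = max(int(round(config.mean_depth)), 1)

    def observe(v: TrueVariant) -> tuple[int, int]:
        depth = (
            mean_depth_i
            if config.deterministic_reads
            else max(int(rng.poisson(config.mean_depth)), 8)
        )
        if v.is_germline:
            alt = (
                int(round(depth * 0.5))
                if config.deterministic_reads
                else int(rng.binomial(depth, 0.5))
            )
            return depth, alt
        _, alt = simulate_read_support(
            v.clonal_fraction, config.tumor_purity, depth, rng,
            deterministic=config.deterministic_reads,
        )
        return depth, alt

    fp_counter = 0
    for i in range(config.n_pairs):
        pair_id = f"P{i + 1:02d}"
        for sample in pair_samples[pair_id]:
            for caller in CALLERS:
                records = []
                for v in variants[sample]:
                    if rng.random() >= config.caller_sensitivity[caller]:
                        continue
                    depth, alt = observe(v)
                    records.append((v.chrom, v.pos, v.ref, v.alt, depth, alt))
                n_fp = (
                    0
                    if config.caller_fp_rate == 0
                    else int(rng.poisson(config.caller_fp_rate))
                )
                for _ in range(n_fp):
                    fp_counter += 1
                    chrom, pos = factory.anywhere()
                    ref, alt_allele = factory.alleles()
                    depth = max(int(rng.poisson(config.mean_depth)), 8)
                    maf = float(rng.uniform(0.01, 0.12))
                    alt = max(int(rng.binomial(depth, maf)), 1)
                    records.append((chrom, pos, ref, alt_allele, depth, alt))
                    ann_rows.append(
                        {
                            "chrom": chrom, "pos": pos, "ref": ref,
                            "alt": alt_allele, "gene": f"FP{fp_counter:05d}",
                            "protein_change": "", "effect": "missense",
                            "functional_impact": "low", "in_cosmic": False,
                            "pop_af_1000g": 0.0, "pop_af_evs": 0.0,
                            "pop_af_exac": 0.0,
                        }
                    )
                path = vcf_dir / f"{sample}_{caller}.vcf"
                gio.write_vcf(path, sample, records)
                files.append(path)

        if i in germline_pairs:
            normal_id = f"{pair_id}-N"
            germ = germline[pair_id]
            for caller in CALLERS:
                records = []
                for v in germ:
                    if rng.random() >= config.caller_sensitivity[caller]:
                        continue
                    depth = (
                        mean_depth_i
                        if config.deterministic_reads
                        else max(int(rng.poisson(config.mean_depth)), 8)
                    )
                    alt = (
                        int(round(depth * 0.5))
                        if config.deterministic_reads
                        else int(rng.binomial(depth, 0.5))
                    )
                    records.append((v.chrom, v.pos, v.ref, v.alt, depth, alt))
                path = vcf_dir / f"{normal_id}_{caller}.vcf"
                gio.write_vcf(path, normal_id, records)
                files.append(path)

            # normal read counts at every tumor-variant site of the pair
            germ_keys = {v.key for v in germ}
            union_keys = sorted(
                {v.key for s in pair_samples[pair_id] for v in variants[s]}
            )
            rows = []
            for chrom, pos, ref, alt_allele in union_keys:
                depth = (
                    mean_depth_i
                    if config.deterministic_reads
                    else max(int(rng.poisson(config.mean_depth)), 8)
                )
                if (chrom, pos, ref, alt_allele) in germ_keys:
                    n_alt = (
                        int(round(depth * 0.5))
                        if config.deterministic_reads
                        else int(rng.binomial(depth, 0.5))
                    )
                else:
                    n_alt = 0
                rows.append(
                    {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt_allele,
                     "normal_depth": depth, "normal_alt_reads": n_alt}
                )
            path = normal_dir / f"{pair_id}.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            files.append(path)

        for sample in pair_samples[pair_id]:
            track = simulate_tracks(
                segments[sample],
                n_sites=config.n_baf_sites,
                mean_depth=config.mean_depth,
                rng=rng,
                purity=config.tumor_purity,
                baf_shift=config.baf_shift,
                amp_baf_shift=config.amp_baf_shift,
                arm_table=arm_table,
                deterministic=config.deterministic_reads,
            )
            path = track_dir / f"{sample}.tsv"
            gio.write_track(path, track)
            files.append(path)

    ann = pd.DataFrame(ann_rows).drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    ann = ann.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
    paths["annotation"] = out_dir / "annotation.tsv"
    gio.write_annotation(paths["annotation"], ann)

    beta, probe_ann = _simulate_beta(config, meth_map, pair_samples, rng)
    paths["beta"] = meth_dir / "beta.tsv"
    beta.round(6).to_csv(paths["beta"], sep="\t")
    paths["probe_annotation"] = meth_dir / "probe_annotation.tsv"
    probe_ann.to_csv(paths["probe_annotation"], sep="\t")

    clinical = _simulate_clinical(config, groups, meth_map, germline_pairs, rng)
    paths["clinical"] = out_dir / "clinical.tsv"
    clinical.to_csv(paths["clinical"], sep="\t", index=False)

    paths["ground_truth"] = out_dir / "ground_truth.json"
    paths["ground_truth"].write_text(truth.to_json() + "\n")

    files.extend(paths.values())
    paths["manifest"] = gio.write_manifest(out_dir, config, config.seed, files)
    paths["vcf_dir"] = vcf_dir
    paths["track_dir"] = track_dir
    paths["normal_counts_dir"] = normal_dir
    return paths, truth


def noise_free_config(**overrides) -> CohortConfig:
    """Convenience: conditions under which every stage recovers the planted
    truth exactly (perfect caller sensitivity, no false positives,
    expectation-valued read counts)."""
    defaults = dict(
        caller_sensitivity={c: 1.0 for c in CALLERS},
        caller_fp_rate=0.0,
        deterministic_reads=True,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)
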