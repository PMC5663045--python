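"""Temporal comparison of tumor pairs: shared vs private variants,
molecular grouping, and the gene-by-pair conservation matrix.

Each patient contributes a primary and a recurrence sample. Variants are
compared at the exact-key level (chrom, pos, ref, alt): a variant present in
both members is *shared* (an early, clonally stable event), otherwise it is
private to one timepoint. Pairs are stratified into three disjoint molecular
groups — H3/IDH1 mutant (oncohistone or IDH1 hotspot), NF1 germline
(truncating germline NF1), and the residual H3/IDH1 wildtype — with
H3/IDH1 taking precedence when evidence conflicts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gliomapairs.variants import ConsensusVariant, FILTERED, VariantKey

log = logging.getLogger(__name__)

H3_IDH1_MUTANT = "H3/IDH1 mutant"
H3_IDH1_WILDTYPE = "H3/IDH1 wildtype"
NF1_GERMLINE = "NF1 germline"

MOLECULAR_GROUPS = (H3_IDH1_MUTANT, H3_IDH1_WILDTYPE, NF1_GERMLINE)

#: (gene, protein-change pattern) pairs defining the H3/IDH1 mutant group
_H3_IDH1_DRIVERS: tuple[tuple[str, re.Pattern], ...] = (
    ("H3F3A", re.compile(r"^K27M$")),
    ("H3F3A", re.compile(r"^G34[VR]$")),
    ("HIST1H3B", re.compile(r"^K27M$")),
    ("IDH1", re.compile(r"^R132")),
)

_TRUNCATING_EFFECTS = frozenset({"frameshift", "stopgain"})


@dataclass(frozen=True)
class TemporalPartition:
    """Disjoint split of a pair's variant keys by timepoint membership."""

    shared: frozenset[VariantKey]
    primary_only: frozenset[VariantKey]
    recurrence_only: frozenset[VariantKey]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_primary_only(self) -> int:
        return len(self.primary_only)

    @property
    def n_recurrence_only(self) -> int:
        return len(self.recurrence_only)


def _keys(variants: Iterable) -> frozenset:
    out = set()
    for v in variants:
        if isinstance(v, ConsensusVariant):
            if v.status == FILTERED:
                continue
            out.add(v.key)
        else:
            out.add(v)
    return frozenset(out)


def partition_pair(primary_variants: Iterable, recurrence_variants: Iterable) -> TemporalPartition:
    """Set algebra on variant keys: shared / primary-only / recurrence-only.

    Accepts ConsensusVariant objects (filtered ones are ignored) or bare
    hashable keys.
    """
    p = _keys(primary_variants)
    r = _keys(recurrence_variants)
    return TemporalPartition(
        shared=p & r, primary_only=p - r, recurrence_only=r - p
    )


def _matches_driver(gene: str | None, protein_change: str | None) -> bool:
    if gene is None or protein_change is None:
        return False
    return any(
        gene == g and pat.search(protein_change) for g, pat in _H3_IDH1_DRIVERS
    )


def assign_group(
    pair_variants: Iterable[ConsensusVariant],
    germline_variants: Iterable[ConsensusVariant] = (),
) -> str:
    """Assign one of the three molecular groups to a tumor pair.

    H3/IDH1 mutant when an oncohistone (H3F3A K27M/G34V/G34R, HIST1H3B K27M)
    or IDH1 R132 hotspot is present in either tumor; else NF1 germline when
    the germline carries a truncating NF1 variant; else H3/IDH1 wildtype.
    H3/IDH1 evidence takes precedence on conflict (logged).
    """
    tumor = [v for v in pair_variants if v.status != FILTERED]
    has_h3_idh1 = any(_matches_driver(v.gene, v.protein_change) for v in tumor)
    has_nf1 = any(
        v.gene == "NF1" and v.effect in _TRUNCATING_EFFECTS
        for v in germline_variants
    )
    if has_h3_idh1:
        if has_nf1:
            log.warning(
                "both H3/IDH1 driver and germline NF1 present; "
                "H3/IDH1 precedence applied"
            )
        return H3_IDH1_MUTANT
    if has_nf1:
        return NF1_GERMLINE
    return H3_IDH1_WILDTYPE


SHARED = "shared"
PRIMARY_ONLY = "primary_only"
RECURRENCE_ONLY = "recurrence_only"
ABSENT = "absent"

#: per-(gene, pair) precedence when variants fall in several categories
_STATUS_PRECEDENCE = (SHARED, PRIMARY_ONLY, RECURRENCE_ONLY)


def conservation_matrix(
    partitions: Mapping[str, TemporalPartition],
    gene_of: Mapping[VariantKey, str],
    pathway_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Gene x pair conservation status table with pathway rollups.

    Per (gene, pair) the status is shared / primary_only / recurrence_only /
    absent; when a gene carries variants in several categories the first of
    (shared, primary_only, recurrence_only) wins. Pathway rows (prefixed
    ``pathway:``) roll genes up as any-gene-altered under the same
    precedence.
    """
    genes = sorted(set(gene_of.values()))
    pairs = list(partitions)
    table = pd.DataFrame(ABSENT, index=genes, columns=pairs)
    for pair_id, part in partitions.items():
        per_gene: dict[str, set[str]] = {}
        for status, keys in (
            (SHARED, part.shared),
            (PRIMARY_ONLY, part.primary_only),
            (RECURRENCE_ONLY, part.recurrence_only),
        ):
            for key in keys:
                gene = gene_of.get(key)
                if gene is not None:
                    per_gene.setdefault(gene, set()).add(status)
        for gene, statuses in per_gene.items():
            for status in _STATUS_PRECEDENCE:
                if status in statuses:
                    table.loc[gene, pair_id] = status
                    break
    if pathway_map:
        pathways = sorted({pathway_map.get(g, "other") for g in genes})
        roll = pd.DataFrame(ABSENT, index=[f"pathway:{p}" for p in pathways], columns=pairs)
        for pathway in pathways:
            members = [g for g in genes if pathway_map.get(g, "other") == pathway]
            for pair_id in pairs:
                statuses = {table.loc[g, pair_id] for g in members} - {ABSENT}
                for status in _STATUS_PRECEDENCE:
                    if status in statuses:
                        roll.loc[f"pathway:{pathway}", pair_id] = status
                        break
        table = pd.concat([table, roll])
    return table


class PairedTestResult(NamedTuple):
    t: float
    df: int
    p: float


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on per-pair counts.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample standard deviation (n-1
    denominator), df = n-1, p two-sided from the t distribution. Differences
    with zero variance make the statistic undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0 or not math.isfinite(sd):
        raise ValueError("zero-variance differences: t statistic undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p))
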