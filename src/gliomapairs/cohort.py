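"""Cohort-level clinical and burden summaries.

Reads the clinical table (one row per primary/recurrence pair: age, sex,
diagnoses, time to progression, neuro-anatomical location, surgeries,
germline availability, free-text treatment history), computes the standard
descriptive statistics (medians with the even-n average-of-middle-two
convention, treatment and location counts, molecular-group counts), builds
the per-pair mutation / allelic-imbalance burden table, and runs the paired
t-tests comparing primary vs recurrence burdens.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gliomapairs.allelic_imbalance import AIComparison
from gliomapairs.temporal import (
    MOLECULAR_GROUPS,
    PairedTestResult,
    TemporalPartition,
    paired_t_test,
)

log = logging.getLogger(__name__)

LOCATIONS = ("midline", "hemisphere")

#: canonical treatment vocabulary; free-text tokens are matched
#: case-insensitively after splitting on commas and plus signs
TREATMENT_VOCABULARY = {
    "rt": "RT",
    "radiation": "RT",
    "tmz": "TMZ",
    "temozolomide": "TMZ",
}


def tokenize_treatments(raw: str) -> list[str]:
    """Split a free-text treatment history into canonical tokens.

    Combination strings ("RT+ TMZ", "lapatinib + bevacizumab") are split on
    '+' and ','; tokens in the controlled vocabulary are canonicalized (RT,
    TMZ), everything else is kept lowercased.
    """
    tokens = []
    for piece in re.split(r"[+,]", raw or ""):
        piece = piece.strip()
        if not piece:
            continue
        tokens.append(TREATMENT_VOCABULARY.get(piece.lower(), piece.lower()))
    return tokens


@dataclass
class TumorPair:
    """Patient-level container: one primary and one recurrence sample plus
    clinical fields."""

    patient_id: str
    primary_sample_id: str = ""
    recurrence_sample_id: str = ""
    molecular_group: str | None = None
    age_years: float = float("nan")
    sex: str = ""
    primary_dx: str = ""
    recurrence_dx: str = ""
    time_to_progression_months: float = float("nan")
    interval_months: float = float("nan")
    location: str = ""
    sublocation: str = ""
    germline_available: bool = False
    treatments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ttp = self.time_to_progression_months
        if not np.isnan(ttp) and ttp <= 0:
            raise ValueError(
                f"{self.patient_id}: time to progression must be > 0, got {ttp}"
            )
        if self.location and self.location not in LOCATIONS:
            raise ValueError(
                f"{self.patient_id}: unknown location {self.location!r}, "
                f"expected one of {LOCATIONS}"
            )


def read_clinical_table(path: str | Path) -> list[TumorPair]:
    """Parse a clinical cohort TSV into typed TumorPair records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty:
        raise ValueError(f"clinical table {path} is empty")
    required = {"patient_id", "age_years", "ttp_months", "location", "treatments"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    pairs = []
    for i, row in df.iterrows():
        try:
            pairs.append(
                TumorPair(
                    patient_id=row["patient_id"],
                    primary_sample_id=row.get("primary_sample_id", f"{row['patient_id']}-P"),
                    recurrence_sample_id=row.get("recurrence_sample_id", f"{row['patient_id']}-R"),
                    molecular_group=row.get("molecular_group") or None,
                    age_years=float(row["age_years"]) if row["age_years"] else float("nan"),
                    sex=row.get("sex", ""),
                    primary_dx=row.get("primary_dx", ""),
                    recurrence_dx=row.get("recurrence_dx", ""),
                    time_to_progression_months=float(row["ttp_months"]) if row["ttp_months"] else float("nan"),
                    interval_months=float(row["interval_months"]) if row.get("interval_months") else float("nan"),
                    location=row["location"],
                    sublocation=row.get("sublocation", ""),
                    germline_available=row.get("germline_available", "").strip().lower() in ("yes", "true", "1"),
                    treatments=tokenize_treatments(row["treatments"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i + 1} ({row.get('patient_id', '?')}): {exc}") from exc
    return pairs


@dataclass
class CohortSummary:
    n_pairs: int
    median_age_years: float
    median_age_years_rounded: int
    age_range: tuple[float, float]
    median_ttp_months: float
    median_ttp_months_rounded: int
    ttp_range: tuple[float, float]
    ttp_range_rounded: tuple[int, int]
    n_radiation: int
    n_tmz: int
    n_midline: int
    n_hemispheric: int
    group_counts: dict[str, int]
    n_age: int = 0
    n_ttp: int = 0

    def to_dict(self) -> dict:
        d = {
            "n_pairs": self.n_pairs,
            "median_age_years": self.median_age_years,
            "median_age_years_rounded": self.median_age_years_rounded,
            "age_range": list(self.age_range),
            "median_ttp_months": self.median_ttp_months,
            "median_ttp_months_rounded": self.median_ttp_months_rounded,
            "ttp_range": list(self.ttp_range),
            "ttp_range_rounded": list(self.ttp_range_rounded),
            "n_radiation": self.n_radiation,
            "n_tmz": self.n_tmz,
            "n_midline": self.n_midline,
            "n_hemispheric": self.n_hemispheric,
            "group_counts": dict(self.group_counts),
            "n_age": self.n_age,
            "n_ttp": self.n_ttp,
        }
        return d


def _median(values: Sequence[float]) -> float:
    """Median with the even-n average-of-middle-two convention."""
    return float(np.median(np.asarray(values, dtype=float)))


def summarize_clinical(pairs: Sequence[TumorPair]) -> CohortSummary:
    """Descriptive cohort summary: medians (raw to one decimal and rounded
    to the nearest integer, as clinical reports print them), ranges,
    treatment and location counts, and molecular-group counts.

    Pairs missing a field are excluded from that statistic with a warning;
    the contributing n is reported.
    """
    ages = [p.age_years for p in pairs if not np.isnan(p.age_years)]
    ttps = [
        p.time_to_progression_months
        for p in pairs
        if not np.isnan(p.time_to_progression_months)
    ]
    for name, vals in (("age_years", ages), ("ttp_months", ttps)):
        if len(vals) < len(pairs):
            log.warning(
                "%d/%d pairs missing %s; excluded from that statistic",
                len(pairs) - len(vals), len(pairs), name,
            )
    med_age = round(_median(ages), 1)
    med_ttp = round(_median(ttps), 1)
    group_counts = {g: 0 for g in MOLECULAR_GROUPS}
    for p in pairs:
        if p.molecular_group is not None:
            group_counts[p.molecular_group] = group_counts.get(p.molecular_group, 0) + 1
    return CohortSummary(
        n_pairs=len(pairs),
        median_age_years=med_age,
        median_age_years_rounded=int(round(med_age)),
        age_range=(min(ages), max(ages)),
        median_ttp_months=med_ttp,
        median_ttp_months_rounded=int(round(med_ttp)),
        ttp_range=(min(ttps), max(ttps)),
        ttp_range_rounded=(int(round(min(ttps))), int(round(max(ttps)))),
        n_radiation=sum("RT" in p.treatments for p in pairs),
        n_tmz=sum("TMZ" in p.treatments for p in pairs),
        n_midline=sum(p.location == "midline" for p in pairs),
        n_hemispheric=sum(p.location == "hemisphere" for p in pairs),
        group_counts=group_counts,
        n_age=len(ages),
        n_ttp=len(ttps),
    )


def burden_table(
    partitions: Mapping[str, TemporalPartition],
    ai_comparisons: Mapping[str, AIComparison] | None = None,
) -> pd.DataFrame:
    """Per-pair burden counts: shared / primary-only / recurrence-only for
    SNVs (and AI regions when provided), plus per-sample totals."""
    rows = []
    for pair_id, part in partitions.items():
        row = {
            "pair_id": pair_id,
            "snv_shared": part.n_shared,
            "snv_primary_only": part.n_primary_only,
            "snv_recurrence_only": part.n_recurrence_only,
            "snv_primary_total": part.n_shared + part.n_primary_only,
            "snv_recurrence_total": part.n_shared + part.n_recurrence_only,
        }
        if ai_comparisons is not None and pair_id in ai_comparisons:
            cmp = ai_comparisons[pair_id]
            row.update(
                ai_shared=cmp.shared,
                ai_shared_primary=cmp.shared_primary,
                ai_shared_recurrence=cmp.shared_recurrence,
                ai_primary_only=cmp.primary_only,
                ai_recurrence_only=cmp.recurrence_only,
                ai_primary_total=cmp.shared_primary + cmp.primary_only,
                ai_recurrence_total=cmp.shared_recurrence + cmp.recurrence_only,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair_id").sort_index()


def compare_burdens(table: pd.DataFrame) -> dict[str, PairedTestResult]:
    """Paired t-tests of primary vs recurrence totals, for SNVs and (when
    present) AI regions. Zero-variance differences propagate as errors."""
    out: dict[str, PairedTestResult] = {}
    out["snv"] = paired_t_test(
        table["snv_primary_total"], table["snv_recurrence_total"]
    )
    if "ai_primary_total" in table.columns:
        sub = table.dropna(subset=["ai_primary_total", "ai_recurrence_total"])
        out["ai"] = paired_t_test(
            sub["ai_primary_total"], sub["ai_recurrence_total"]
        )
    return out
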