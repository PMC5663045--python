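"""Joint coverage + B-allele-frequency copy-number calling.

Combines two per-sample features over the same exome positions:

* a normalized coverage log2 ratio (tumor vs matched normal, each scaled by
  its genome-wide median depth), segmented by recursive binary segmentation;
* allelic-imbalance segments from the BAF detector
  (:mod:`gliomapairs.allelic_imbalance`).

The union of breakpoints from the two features partitions each chromosome
into cells; each cell inherits a coverage state (gain / loss / neutral, by
mean log2 thresholds) and an AI state (imbalanced / balanced), and the pair
maps deterministically onto an event class:

    (gain, *)            -> amplification
    (loss, *)            -> deletion
    (neutral, imbalanced) -> copy-neutral LOH
    (neutral, balanced)   -> none

Events are reported both at the union-of-segments level and rolled up to
chromosome arms (an arm call requires the class to cover >= ``min_fraction``
of the arm's analyzable bases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from gliomapairs.allelic_imbalance import AISegment
from gliomapairs.resources import load_arm_table

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"
IMBALANCED, BALANCED = "imbalanced", "balanced"
AMPLIFICATION, DELETION, CNLOH, NONE = "amplification", "deletion", "cnLOH", "none"


@dataclass(frozen=True)
class CoverageBin:
    chrom: str
    start: int  # 0-based half-open
    end: int
    tumor_depth_mean: float
    normal_depth_mean: float
    log2_ratio: float


@dataclass(frozen=True)
class CNVEvent:
    chrom: str
    arm: str
    start: int
    end: int
    coverage_state: str
    ai_state: str
    event_class: str
    level: str  # "segment" or "arm"
    mean_log2: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_coverage(
    tumor_track: pd.DataFrame,
    normal_track: pd.DataFrame,
    bin_size: int = 10,
    min_normal_depth: float = 10.0,
) -> pd.DataFrame:
    """Bin per-site depths and compute median-normalized log2 ratios.

    Both tracks must cover the same positions. Sites are grouped into bins of
    ``bin_size`` consecutive targets per chromosome; each sample's depths are
    divided by its genome-wide median before the ratio, making the ratio
    robust to library size and to focal events. Bins whose raw normal mean
    depth falls below ``min_normal_depth`` are dropped.

    Returns a DataFrame with CoverageBin columns.
    """
    t = tumor_track.reset_index(drop=True)
    n = normal_track.reset_index(drop=True)
    if len(t) != len(n) or not (
        t["chrom"].equals(n["chrom"]) and t["pos"].equals(n["pos"])
    ):
        raise ValueError("tumor and normal tracks must share positions")
    t_med = float(np.median(t["tumor_depth"]))
    n_med = float(np.median(n["tumor_depth"]))
    if t_med <= 0 or n_med <= 0:
        raise ValueError("median depth must be positive")

    rows = []
    for chrom, sub in t.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        n_bins = len(idx) // bin_size
        if n_bins == 0:
            continue
        for b in range(n_bins):
            lo = b * bin_size
            hi = (b + 1) * bin_size if b < n_bins - 1 else len(idx)
            block = idx[lo:hi]
            t_mean = float(t.loc[block, "tumor_depth"].mean())
            n_mean = float(n.loc[block, "tumor_depth"].mean())
            if n_mean < min_normal_depth:
                continue
            ratio = (t_mean / t_med) / (n_mean / n_med)
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(t.loc[block[0], "pos"]) - 1,
                    "end": int(t.loc[block[-1], "pos"]),
                    "tumor_depth_mean": t_mean,
                    "normal_depth_mean": n_mean,
                    "log2_ratio": math.log2(ratio) if ratio > 0 else float("-inf"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "tumor_depth_mean", "normal_depth_mean", "log2_ratio"],
    )


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best split index (left segment is x[:k]) and its pooled |t| statistic."""
    n = x.size
    ks = np.arange(min_bins, n - min_bins + 1)
    if ks.size == 0:
        return 0, 0.0
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    total, total2 = csum[-1], csum2[-1]
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = csum[ks - 1]
    s2 = total - s1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = csum2[ks - 1] - n1 * m1**2
    ss2 = (total2 - csum2[ks - 1]) - n2 * m2**2
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss1 + ss2) / df if df > 0 else np.full_like(n1, np.inf)
        tstat = np.abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    tstat = np.where(np.isfinite(tstat), tstat, np.where(m1 != m2, np.inf, 0.0))
    best = int(np.argmax(tstat))
    return int(ks[best]), float(tstat[best])


def segment_log2(
    values: Sequence[float],
    penalty: float = 3.0,
    min_bins: int = 3,
) -> list[tuple[int, int, float]]:
    """Recursive binary segmentation of a log2-ratio profile.

    At each step the candidate breakpoint maximizing the pooled two-sample
    t statistic between the flanks is accepted when |t| exceeds
    sqrt(2 * penalty * log n) (a BIC-style threshold scaling with segment
    length), then both flanks are segmented recursively. Segments shorter
    than ``2 * min_bins`` are never split.

    Returns (start_index, end_index, mean) tuples, end exclusive.
    """
    x = np.asarray(values, dtype=float)
    out: list[tuple[int, int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = seg.size
        if n >= 2 * min_bins:
            k, t = _best_split(seg, min_bins)
            threshold = math.sqrt(2.0 * penalty * math.log(max(n, 2)))
            if k > 0 and t > threshold:
                recurse(lo, lo + k)
                recurse(lo + k, hi)
                return
        out.append((lo, hi, float(seg.mean())))

    if x.size:
        recurse(0, x.size)
    return out


def segment_bins(
    bins: pd.DataFrame, penalty: float = 3.0, min_bins: int = 3
) -> pd.DataFrame:
    """Segment a binned log2 profile per chromosome into genomic segments."""
    rows = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        for lo, hi, mean in segment_log2(
            sub["log2_ratio"].to_numpy(), penalty=penalty, min_bins=min_bins
        ):
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(sub.loc[lo, "start"]),
                    "end": int(sub.loc[hi - 1, "end"]),
                    "n_bins": hi - lo,
                    "mean_log2": mean,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "mean_log2"])


def coverage_state(mean_log2: float, gain_threshold: float = 0.3, loss_threshold: float = -0.3) -> str:
    if mean_log2 >= gain_threshold:
        return GAIN
    if mean_log2 <= loss_threshold:
        return LOSS
    return NEUTRAL


_EVENT_MAP = {
    (GAIN, IMBALANCED): AMPLIFICATION,
    (GAIN, BALANCED): AMPLIFICATION,
    (LOSS, IMBALANCED): DELETION,
    (LOSS, BALANCED): DELETION,
    (NEUTRAL, IMBALANCED): CNLOH,
    (NEUTRAL, BALANCED): NONE,
}


def classify_event(coverage_state: str, ai_state: str) -> str:
    """Deterministic (coverage, AI) -> event-class mapping; total over the
    six state combinations."""
    try:
        return _EVENT_MAP[(coverage_state, ai_state)]
    except KeyError:
        raise ValueError(f"unknown state combination ({coverage_state}, {ai_state})")


def union_segments(
    coverage_segments: pd.DataFrame,
    ai_segments: Sequence[AISegment],
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
    arm_table: pd.DataFrame | None = None,
) -> list[CNVEvent]:
    """Partition each chromosome at the union of the two features' breakpoints.

    Every cell of the partition inherits its coverage state from the
    covering coverage segment (neutral where none covers it) and its AI
    state from overlap with an AI segment, then maps to an event class.
    Cells are split at the centromere so each event lies on one arm, and
    adjacent cells with identical states on the same arm are merged.
    """
    arm_table = load_arm_table() if arm_table is None else arm_table
    cen = {r.chrom: r.end for r in arm_table[arm_table["arm"] == "p"].itertuples()}

    cov_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for r in coverage_segments.itertuples():
        cov_by_chrom.setdefault(str(r.chrom), []).append((int(r.start), int(r.end), float(r.mean_log2)))
    ai_by_chrom: dict[str, list[AISegment]] = {}
    for s in ai_segments:
        ai_by_chrom.setdefault(s.chrom, []).append(s)

    events: list[CNVEvent] = []
    for chrom in sorted(set(cov_by_chrom) | set(ai_by_chrom)):
        covs = sorted(cov_by_chrom.get(chrom, []))
        ais = sorted(ai_by_chrom.get(chrom, []), key=lambda s: s.start)
        points = set()
        for s, e, _ in covs:
            points.update((s, e))
        for a in ais:
            points.update((a.start, a.end))
        if chrom in cen and min(points) < cen[chrom] < max(points):
            points.add(cen[chrom])
        points = sorted(points)
        cells = []
        for lo, hi in zip(points[:-1], points[1:]):
            if lo >= hi:
                continue
            mid = (lo + hi) // 2
            mean_log2 = next(
                (m for s, e, m in covs if s <= mid < e), 0.0
            )
            covered_by_cov = any(s <= mid < e for s, e, _ in covs)
            cstate = coverage_state(mean_log2, gain_threshold, loss_threshold) if covered_by_cov else NEUTRAL
            astate = IMBALANCED if any(a.start <= mid < a.end for a in ais) else BALANCED
            arm = "p" if (chrom in cen and hi <= cen[chrom]) else "q"
            cells.append([chrom, arm, lo, hi, cstate, astate, mean_log2 if covered_by_cov else float("nan")])
        # merge adjacent identical-state cells on the same arm
        merged: list[list] = []
        for cell in cells:
            if (
                merged
                and merged[-1][1] == cell[1]
                and merged[-1][3] == cell[2]
                and merged[-1][4] == cell[4]
                and merged[-1][5] == cell[5]
            ):
                prev = merged[-1]
                w1, w2 = prev[3] - prev[2], cell[3] - cell[2]
                if not (math.isnan(prev[6]) and math.isnan(cell[6])):
                    prev[6] = (
                        (0.0 if math.isnan(prev[6]) else prev[6]) * w1
                        + (0.0 if math.isnan(cell[6]) else cell[6]) * w2
                    ) / (w1 + w2)
                prev[3] = cell[3]
            else:
                merged.append(list(cell))
        for chrom_, arm, lo, hi, cstate, astate, mlog2 in merged:
            events.append(
                CNVEvent(
                    chrom=chrom_,
                    arm=arm,
                    start=lo,
                    end=hi,
                    coverage_state=cstate,
                    ai_state=astate,
                    event_class=classify_event(cstate, astate),
                    level="segment",
                    mean_log2=mlog2,
                )
            )
    return events


def arm_level_calls(
    events: Sequence[CNVEvent],
    arm_table: pd.DataFrame | None = None,
    min_fraction: float = 0.7,
) -> list[CNVEvent]:
    """Roll segment-level events up to chromosome arms.

    The analyzable extent of an arm is the total length of segment-level
    events (of any class, including none) intersecting it; an arm-level call
    of class c is emitted when class-c events cover >= ``min_fraction`` of
    that extent.
    """
    arm_table = load_arm_table() if arm_table is None else arm_table
    out: list[CNVEvent] = []
    for r in arm_table.itertuples():
        overlaps = []
        for ev in events:
            if ev.chrom != r.chrom or ev.level != "segment":
                continue
            lo, hi = max(ev.start, r.start), min(ev.end, r.end)
            if lo < hi:
                overlaps.append((ev, hi - lo))
        analyzable = sum(w for _, w in overlaps)
        if analyzable == 0:
            continue
        for cls in (AMPLIFICATION, DELETION, CNLOH):
            covered = sum(w for ev, w in overlaps if ev.event_class == cls)
            if covered / analyzable >= min_fraction:
                cstate = {AMPLIFICATION: GAIN, DELETION: LOSS, CNLOH: NEUTRAL}[cls]
                astate = IMBALANCED if cls == CNLOH else BALANCED
                out.append(
                    CNVEvent(
                        chrom=r.chrom,
                        arm=r.arm,
                        start=int(r.start),
                        end=int(r.end),
                        coverage_state=cstate,
                        ai_state=astate,
                        event_class=cls,
                        level="arm",
                    )
                )
    return out


def call_cnv(
    tumor_track: pd.DataFrame,
    normal_track: pd.DataFrame,
    ai_segments: Sequence[AISegment],
    bin_size: int = 10,
    penalty: float = 3.0,
    min_bins: int = 3,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
    min_fraction: float = 0.7,
    arm_table: pd.DataFrame | None = None,
) -> tuple[list[CNVEvent], list[CNVEvent]]:
    """Full joint caller: normalize, segment, join with AI, classify.

    Returns (segment_level_events, arm_level_events).
    """
    bins = normalize_coverage(tumor_track, normal_track, bin_size=bin_size)
    cov_segments = segment_bins(bins, penalty=penalty, min_bins=min_bins)
    seg_events = union_segments(
        cov_segments,
        ai_segments,
        gain_threshold=gain_threshold,
        loss_threshold=loss_threshold,
        arm_table=arm_table,
    )
    arm_events = arm_level_calls(seg_events, arm_table=arm_table, min_fraction=min_fraction)
    return seg_events, arm_events


def events_to_frame(events: Sequence[CNVEvent]) -> pd.DataFrame:
    rows = [
        {
            "chrom": e.chrom,
            "arm": e.arm,
            "start": e.start,
            "end": e.end,
            "coverage_state": e.coverage_state,
            "ai_state": e.ai_state,
            "event_class": e.event_class,
            "level": e.level,
            "mean_log2": e.mean_log2,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "arm", "start", "end", "coverage_state", "ai_state", "event_class", "level", "mean_log2"],
    )
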