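"""Allelic-imbalance (AI) detection from tumor B-allele frequencies.

At a heterozygous site the B-allele frequency (BAF) is the fraction of reads
carrying the non-reference allele; in a balanced diploid region it scatters
binomially around 0.5, and under allelic imbalance (single-copy loss, gain,
or copy-neutral LOH) it shifts symmetrically away from 0.5. Because tumor
data are unphased, the detector works on the *folded* deviation |BAF - 0.5|,
which is invariant under allele relabelling.

The folded deviation is strictly positive at finite depth even in balanced
regions, so windows are tested against the sample's own genome-wide baseline
rather than against zero: the one-sample Wilcoxon signed-rank statistic is
applied to (folded deviation - baseline pseudo-median) per non-overlapping
window of ``window`` sites, one-sided (greater), with Benjamini-Hochberg
correction across all windows of the sample. Adjacent significant windows
are merged and trimmed to the first/last individually deviant site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gliomapairs.resources import load_arm_table

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BAFSite:
    """One heterozygous site with tumor read counts."""

    chrom: str
    pos: int  # 1-based
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads + self.alt_reads <= 0:
            raise ValueError(f"zero depth at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def baf(self) -> float:
        return self.alt_reads / self.depth

    @property
    def folded_dev(self) -> float:
        return abs(self.baf - 0.5)


@dataclass(frozen=True)
class AISegment:
    """A maximal run of windows with significant allelic imbalance."""

    chrom: str
    arm: str
    start: int  # 0-based half-open
    end: int
    n_sites: int
    mean_folded_dev: float
    q_value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def overlaps(self, other: "AISegment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def select_het_sites(
    track: pd.DataFrame,
    min_depth: int = 10,
    het_band: tuple[float, float] = (0.3, 0.7),
) -> list[BAFSite]:
    """Select candidate heterozygous sites from a BAF track.

    With matched-normal read counts in the track (columns normal_ref_reads /
    normal_alt_reads) a site is heterozygous when the normal BAF lies within
    ``het_band``; without a normal, sites with tumor BAF in (0.05, 0.95) are
    kept to exclude homozygous sites. Sites below ``min_depth`` tumor reads
    are dropped either way.
    """
    depth = track["ref_reads"] + track["alt_reads"]
    keep = depth >= min_depth
    has_normal = {"normal_ref_reads", "normal_alt_reads"}.issubset(track.columns)
    if has_normal:
        n_depth = track["normal_ref_reads"] + track["normal_alt_reads"]
        with np.errstate(invalid="ignore", divide="ignore"):
            n_baf = track["normal_alt_reads"] / n_depth
        keep &= (n_depth > 0) & n_baf.between(het_band[0], het_band[1])
    else:
        baf = track["alt_reads"] / depth
        keep &= (baf > 0.05) & (baf < 0.95)
    sub = track.loc[keep]
    return [
        BAFSite(chrom=str(r.chrom), pos=int(r.pos), ref_reads=int(r.ref_reads),
                alt_reads=int(r.alt_reads))
        for r in sub.itertuples()
    ]


def _pseudomedian(x: np.ndarray, max_n: int = 400) -> float:
    """Hodges-Lehmann estimator (median of Walsh averages).

    The Wilcoxon signed-rank test is a test of the pseudo-median, so
    centering on the genome-wide pseudo-median calibrates the window tests
    under the null even though folded deviations are skewed. Large inputs
    are thinned deterministically to bound the pairwise computation.
    """
    x = np.sort(np.asarray(x, dtype=float))
    if x.size == 0:
        return 0.0
    if x.size > max_n:
        idx = np.linspace(0, x.size - 1, max_n).round().astype(int)
        x = x[idx]
    walsh = (x[:, None] + x[None, :]) / 2.0
    iu = np.triu_indices(x.size)
    return float(np.median(walsh[iu]))


def _window_pvalue(centered: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p for median(centered) > 0."""
    nz = centered[centered != 0.0]
    if nz.size == 0:
        return 1.0
    try:
        return float(stats.wilcoxon(nz, alternative="greater").pvalue)
    except ValueError:
        return 1.0


def normal_folded_baseline(
    track: pd.DataFrame,
    min_depth: int = 10,
    het_band: tuple[float, float] = (0.3, 0.7),
) -> float | None:
    """Null baseline from the matched normal: pseudo-median of the normal's
    folded BAF deviations over candidate heterozygous sites.

    Estimating the baseline from the tumor itself assumes most of the
    genome is balanced; a genome-wide copy-neutral-LOH tumor violates that,
    while the matched normal is balanced by construction. Returns None when
    the track carries no normal read counts.
    """
    if not {"normal_ref_reads", "normal_alt_reads"}.issubset(track.columns):
        return None
    n_depth = track["normal_ref_reads"] + track["normal_alt_reads"]
    keep = n_depth >= min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        n_baf = track["normal_alt_reads"] / n_depth
    keep &= n_baf.between(het_band[0], het_band[1]) & (n_depth > 0)
    folded = np.abs(n_baf[keep].to_numpy(dtype=float) - 0.5)
    if folded.size == 0:
        return None
    return _pseudomedian(folded)


def _site_deviant(baf: np.ndarray, depth: np.ndarray, z: float = 1.96) -> np.ndarray:
    """Per-site call: BAF inconsistent with 0.5 by a normal-approximate
    two-sided binomial test at ~5%."""
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.abs(baf - 0.5) * 2.0 * np.sqrt(depth)
    return zscore > z


def assign_arms(
    chroms: Sequence[str], positions: Sequence[int], arm_table: pd.DataFrame | None = None
) -> np.ndarray:
    """Map (chrom, 1-based pos) to chromosome arm labels ('p'/'q')."""
    arm_table = load_arm_table() if arm_table is None else arm_table
    cen = {
        r.chrom: r.end
        for r in arm_table[arm_table["arm"] == "p"].itertuples()
    }
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    out = np.empty(len(chroms), dtype=object)
    for i, (c, p) in enumerate(zip(chroms, positions)):
        boundary = cen.get(str(c))
        if boundary is None:
            out[i] = "q"  # unknown chrom: single-arm convention
        else:
            out[i] = "p" if p <= boundary else "q"
    return out


def detect_ai(
    sites: Iterable[BAFSite],
    window: int = 25,
    alpha: float = 0.05,
    arm_table: pd.DataFrame | None = None,
    baseline: float | None = None,
    min_sites: int = 10,
) -> list[AISegment]:
    """Windowed AI detection over one sample's heterozygous sites.

    Sites are grouped by chromosome arm and processed in sliding
    non-overlapping windows of ``window`` sites (a trailing remainder is
    folded into the last window; arms with fewer than ``window`` sites are
    skipped with a log message). Window p-values are BH-adjusted across the
    whole sample; runs of adjacent significant windows are merged into
    maximal segments and trimmed to the first/last individually deviant
    site.

    ``baseline`` is the null pseudo-median of folded deviations; by default
    it is estimated from the sample's own genome (valid when most of it is
    balanced). Pass :func:`normal_folded_baseline` of the matched normal
    when one exists — mandatory for genomes that may be imbalanced
    end-to-end.

    Segments supported by fewer than ``min_sites`` sites after trimming are
    discarded: a genuine event spans most of a window, while marginal
    windows trim to short runs of noise sites.
    """
    sites = sorted(sites, key=lambda s: (s.chrom, s.pos))
    if not sites:
        return []
    chroms = np.array([s.chrom for s in sites])
    positions = np.array([s.pos for s in sites])
    folded = np.array([s.folded_dev for s in sites])
    depths = np.array([s.depth for s in sites], dtype=float)
    bafs = np.array([s.baf for s in sites])
    arms = assign_arms(chroms, positions, arm_table)

    if baseline is None:
        baseline = _pseudomedian(folded)
    centered = folded - baseline

    # build windows per arm
    windows: list[tuple[str, str, int, int]] = []  # (chrom, arm, lo, hi) index slice
    pvals: list[float] = []
    for chrom in pd.unique(chroms):
        for arm in ("p", "q"):
            idx = np.flatnonzero((chroms == chrom) & (arms == arm))
            if idx.size == 0:
                continue
            if idx.size < window:
                log.info("%s%s: %d sites < window %d, no call", chrom, arm, idx.size, window)
                continue
            n_win = idx.size // window
            for w in range(n_win):
                lo = w * window
                hi = (w + 1) * window if w < n_win - 1 else idx.size
                block = idx[lo:hi]
                windows.append((chrom, arm, block[0], block[-1]))
                pvals.append(_window_pvalue(centered[block]))
    if not windows:
        return []

    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    deviant = _site_deviant(bafs, depths)
    segments: list[AISegment] = []
    i = 0
    while i < len(windows):
        if not reject[i]:
            i += 1
            continue
        chrom, arm, first, last = windows[i]
        q = qvals[i]
        j = i + 1
        while (
            j < len(windows)
            and reject[j]
            and windows[j][0] == chrom
            and windows[j][1] == arm
        ):
            last = windows[j][3]
            q = min(q, qvals[j])
            j += 1
        span = np.arange(first, last + 1)
        dev_in_span = span[deviant[span]]
        if dev_in_span.size:
            first, last = int(dev_in_span[0]), int(dev_in_span[-1])
        if last - first + 1 < min_sites:
            i = j
            continue
        segments.append(
            AISegment(
                chrom=chrom,
                arm=arm,
                start=int(positions[first]) - 1,
                end=int(positions[last]),
                n_sites=int(last - first + 1),
                mean_folded_dev=float(folded[first : last + 1].mean()),
                q_value=float(q),
            )
        )
        i = j
    return segments


@dataclass(frozen=True)
class AIComparison:
    """Per-pair region counts, counted per list regardless of region size.

    A segment is *shared* when any segment of the partner sample overlaps it
    by at least 1 bp on the same chromosome; each segment is counted once in
    its own list, so a region split across two partner regions contributes
    asymmetric shared counts.
    """

    shared_primary: int
    shared_recurrence: int
    primary_only: int
    recurrence_only: int

    @property
    def shared(self) -> int:
        """Shared count as reported per pair (primary-list convention)."""
        return self.shared_primary


def compare_ai_regions(
    primary_segments: Sequence[AISegment],
    recurrence_segments: Sequence[AISegment],
) -> AIComparison:
    """Count AI regions shared vs private between primary and recurrence."""
    def shared_count(a: Sequence[AISegment], b: Sequence[AISegment]) -> int:
        return sum(any(s.overlaps(t) for t in b) for s in a)

    sp = shared_count(primary_segments, recurrence_segments)
    sr = shared_count(recurrence_segments, primary_segments)
    return AIComparison(
        shared_primary=sp,
        shared_recurrence=sr,
        primary_only=len(primary_segments) - sp,
        recurrence_only=len(recurrence_segments) - sr,
    )


def segments_to_frame(segments: Iterable[AISegment]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.chrom,
            "arm": s.arm,
            "start": s.start,
            "end": s.end,
            "n_sites": s.n_sites,
            "mean_folded_dev": s.mean_folded_dev,
            "q_value": s.q_value,
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "arm", "start", "end", "n_sites", "mean_folded_dev", "q_value"],
    )
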