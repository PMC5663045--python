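"""450K-style methylation subgroup clustering.

Probe-level beta values (fraction methylated, in [0,1]) are filtered
(sex-chromosome, SNP-overlapping and cross-reactive probes removed), reduced
to the most variable probes by standard deviation, and clustered by
average-linkage agglomeration on correlation distance (1 - Pearson r between
sample beta vectors; a Spearman variant is available). Tumor pairs are then
scored for co-clustering: whether primary and recurrence fall in the same
flat cluster when the tree is cut at k groups (default k=4, the canonical
pHGG methylation subgroups: K27M, G34R/V, IDH1, wildtype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cut_tree, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

log = logging.getLogger(__name__)


@dataclass
class BetaMatrix:
    """Probes x samples beta values with probe annotation.

    ``values``: DataFrame indexed by probe_id, columns are sample ids.
    ``annotation``: DataFrame indexed by probe_id with columns
    chrom, is_snp_probe, is_cross_reactive.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("beta matrix contains missing values")
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.values.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack annotation (e.g. {missing[0]})")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ClusterResult:
    """Average-linkage tree plus flat labels at k clusters."""

    linkage: np.ndarray
    sample_ids: list[str]
    labels: dict[str, int]
    k: int

    def co_clustered(self, a: str, b: str) -> bool:
        return self.labels[a] == self.labels[b]

    def to_newick(self) -> str:
        """Dendrogram in newick format with branch lengths from merge heights."""
        tree = to_tree(self.linkage)

        def walk(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def filter_probes(m: BetaMatrix) -> BetaMatrix:
    """Remove probes on chrX/chrY, SNP-overlapping probes, and
    cross-reactive (multi-mapping) probes."""
    ann = m.annotation.loc[m.probe_ids]
    bad = (
        ann["chrom"].isin(["chrX", "chrY", "X", "Y"])
        | ann["is_snp_probe"].astype(bool)
        | ann["is_cross_reactive"].astype(bool)
    )
    keep = m.probe_ids[~bad.to_numpy()]
    return BetaMatrix(values=m.values.loc[keep], annotation=m.annotation)


def select_top_variable(m: BetaMatrix, n_probes: int = 3000) -> BetaMatrix:
    """Keep the ``n_probes`` probes with the largest across-sample standard
    deviation of beta (n-1 denominator); ties broken by probe_id."""
    if len(m.probe_ids) < n_probes:
        raise ValueError(
            f"only {len(m.probe_ids)} probes available, need {n_probes}"
        )
    sd = m.values.std(axis=1, ddof=1)
    # mergesort is stable; pre-sorting by probe_id gives a deterministic tie-break
    order = (
        pd.DataFrame({"sd": sd})
        .sort_index()
        .sort_values(by="sd", ascending=False, kind="mergesort")
    )
    keep = order.index[:n_probes]
    return BetaMatrix(values=m.values.loc[keep], annotation=m.annotation)


def correlation_distance(values: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise sample distance 1 - correlation (Pearson by default,
    ``method='spearman'`` rank-transforms first). Raises on zero-variance
    samples, naming the offender."""
    x = values.to_numpy(dtype=float).T  # samples x probes
    sds = x.std(axis=1)
    for sample, sd in zip(values.columns, sds):
        if sd == 0:
            raise ValueError(f"sample {sample!r} has zero variance: correlation undefined")
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    d = squareform(pdist(x, metric="correlation"))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def cluster_samples(m: BetaMatrix, k: int = 4, method: str = "pearson") -> ClusterResult:
    """Average-linkage hierarchical clustering on correlation distance,
    with flat labels from cutting the tree at k clusters."""
    if len(m.sample_ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    dist = correlation_distance(m.values, method=method)
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = average(condensed)
    flat = cut_tree(linkage, n_clusters=min(k, len(m.sample_ids))).ravel()
    samples = list(m.sample_ids)
    return ClusterResult(
        linkage=linkage,
        sample_ids=samples,
        labels={s: int(c) for s, c in zip(samples, flat)},
        k=k,
    )


def pair_co_clustering(
    result: ClusterResult, pairs: Mapping[str, tuple[str, str]]
) -> tuple[dict[str, bool], float]:
    """Per-pair co-clustering booleans and the cohort fraction.

    ``pairs`` maps pair id -> (primary_sample, recurrence_sample). Pairs with
    a member absent from the clustering (e.g. one timepoint failed QC) are
    skipped and logged; the fraction is over evaluable pairs.
    """
    out: dict[str, bool] = {}
    for pair_id, (primary, recurrence) in pairs.items():
        if primary not in result.labels or recurrence not in result.labels:
            log.info("pair %s skipped: member missing from clustering", pair_id)
            continue
        out[pair_id] = result.co_clustered(primary, recurrence)
    fraction = sum(out.values()) / len(out) if out else float("nan")
    return out, fraction
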