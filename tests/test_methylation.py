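"""Probe filtering, variable-probe selection, correlation-distance
clustering, and pair co-clustering."""

import numpy as np
import pandas as pd
import pytest

from gliomapairs.methylation import (
    BetaMatrix,
    cluster_samples,
    correlation_distance,
    filter_probes,
    pair_co_clustering,
    select_top_variable,
)


def matrix(values: dict, chroms=None, snp=None, cross=None) -> BetaMatrix:
    vals = pd.DataFrame(values)
    n = len(vals)
    vals.index = [f"cg{i:03d}" for i in range(n)]
    ann = pd.DataFrame(
        {
            "chrom": chroms or ["chr1"] * n,
            "is_snp_probe": snp or [False] * n,
            "is_cross_reactive": cross or [False] * n,
        },
        index=vals.index,
    )
    return BetaMatrix(values=vals, annotation=ann)


class TestBetaMatrix:
    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            matrix({"s1": [0.5, 1.2], "s2": [0.4, 0.3]})

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            matrix({"s1": [0.5, np.nan], "s2": [0.4, 0.3]})


class TestFilterProbes:
    def test_sex_chromosome_snp_and_cross_reactive_probes_removed(self):
        m = matrix(
            {"s1": [0.1, 0.2, 0.3, 0.4, 0.5], "s2": [0.5, 0.4, 0.3, 0.2, 0.1]},
            chroms=["chr1", "chrX", "chrY", "chr2", "chr3"],
            snp=[False, False, False, True, False],
            cross=[False, False, False, False, True],
        )
        kept = filter_probes(m)
        assert list(kept.probe_ids) == ["cg000"]

    def test_clean_autosomal_probes_retained(self):
        m = matrix({"s1": [0.1, 0.2], "s2": [0.3, 0.4]})
        assert len(filter_probes(m).probe_ids) == 2


class TestSelectTopVariable:
    def test_top_n_by_standard_deviation(self):
        # sds: cg000 > cg001 > cg002 > cg003 (constant)
        m = matrix(
            {
                "s1": [0.0, 0.1, 0.2, 0.5],
                "s2": [0.5, 0.35, 0.3, 0.5],
                "s3": [1.0, 0.6, 0.4, 0.5],
            }
        )
        kept = select_top_variable(m, n_probes=3)
        assert list(kept.probe_ids) == ["cg000", "cg001", "cg002"]

    def test_constant_probe_never_selected_over_variable(self):
        m = matrix({"s1": [0.5, 0.1], "s2": [0.5, 0.9]})
        kept = select_top_variable(m, n_probes=1)
        assert list(kept.probe_ids) == ["cg001"]

    def test_ties_broken_by_probe_id(self):
        m = matrix({"s1": [0.2, 0.2, 0.2], "s2": [0.4, 0.4, 0.4]})
        kept = select_top_variable(m, n_probes=2)
        assert list(kept.probe_ids) == ["cg000", "cg001"]

    def test_fewer_probes_than_requested_raises(self):
        m = matrix({"s1": [0.1], "s2": [0.2]})
        with pytest.raises(ValueError, match="probes"):
            select_top_variable(m, n_probes=3000)


class TestClusterSamples:
    def test_identical_samples_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.9, 30)
        m = matrix(
            {
                "a": base,
                "b": base,
                "c": np.clip(base + rng.normal(0.3, 0.1, 30), 0, 1),
            }
        )
        result = cluster_samples(m, k=2)
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert result.co_clustered("a", "b")

    def test_anticorrelated_samples_at_maximum_distance(self):
        x = np.linspace(0.1, 0.9, 20)
        m = matrix({"up": x, "down": x[::-1]})
        d = correlation_distance(m.values)
        assert d.loc["up", "down"] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_sample_error_names_sample(self):
        m = matrix({"flat": [0.5, 0.5, 0.5], "ok": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(m, k=2)

    def test_planted_four_clusters_recovered_exactly(self):
        rng = np.random.default_rng(7)
        n_probes, per_cluster = 300, 4
        centers = rng.uniform(0.2, 0.5, size=(4, n_probes))
        for c in range(4):
            informative = slice(c * 60, (c + 1) * 60)
            centers[c, informative] += 0.3
        values = {}
        truth = {}
        for c in range(4):
            for s in range(per_cluster):
                name = f"c{c}s{s}"
                values[name] = np.clip(
                    centers[c] + rng.normal(0, 0.05, n_probes), 0, 1
                )
                truth[name] = c
        m = matrix(values)
        result = cluster_samples(m, k=4)
        # label agreement up to permutation
        mapping = {}
        for sample, label in result.labels.items():
            mapping.setdefault(label, truth[sample])
            assert mapping[label] == truth[sample]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(8)
        values = {f"s{i}": rng.uniform(0, 1, 50) for i in range(6)}
        m1 = matrix(values)
        reordered = {k: values[k] for k in reversed(list(values))}
        m2 = matrix(reordered)
        r1, r2 = cluster_samples(m1, k=3), cluster_samples(m2, k=3)
        for a in values:
            for b in values:
                assert r1.co_clustered(a, b) == r2.co_clustered(a, b)

    def test_newick_output_contains_all_samples(self):
        rng = np.random.default_rng(9)
        m = matrix({f"s{i}": rng.uniform(0, 1, 20) for i in range(4)})
        newick = cluster_samples(m, k=2).to_newick()
        assert newick.endswith(";")
        for i in range(4):
            assert f"s{i}:" in newick


class TestPairCoClustering:
    def _result(self):
        rng = np.random.default_rng(10)
        base_a = rng.uniform(0.1, 0.4, 40)
        base_b = np.clip(base_a + 0.4, 0, 1)
        m = matrix(
            {
                "p1-P": np.clip(base_a + rng.normal(0, 0.02, 40), 0, 1),
                "p1-R": np.clip(base_a + rng.normal(0, 0.02, 40), 0, 1),
                "p2-P": np.clip(base_b + rng.normal(0, 0.02, 40), 0, 1),
                "p2-R": np.clip(base_a + rng.normal(0, 0.02, 40), 0, 1),
            }
        )
        return cluster_samples(m, k=2)

    def test_pairs_scored_and_fraction_computed(self):
        result = self._result()
        flags, fraction = pair_co_clustering(
            result, {"p1": ("p1-P", "p1-R"), "p2": ("p2-P", "p2-R")}
        )
        assert flags["p1"] is True
        assert flags["p2"] is False
        assert fraction == 0.5

    def test_pair_with_missing_member_skipped(self):
        result = self._result()
        flags, fraction = pair_co_clustering(
            result, {"p1": ("p1-P", "p1-R"), "p3": ("p3-P", "p3-R")}
        )
        assert set(flags) == {"p1"}
        assert fraction == 1.0
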