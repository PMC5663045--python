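"""Consensus merge and the somatic filter cascade: boundary behavior of
every rule, plus order-independence and monotonicity properties."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from gliomapairs import io as gio
from gliomapairs.variants import (
    ConsensusVariant,
    FilterPolicy,
    VariantCall,
    apply_maf_filter,
    build_consensus,
    classify_somatic_with_normal,
    classify_somatic_without_normal,
    read_caller_vcfs,
    run_filter_cascade,
)

POLICY = FilterPolicy()


def call(caller="freebayes", depth=100, alt=40, pos=1000, chrom="chr1"):
    return VariantCall(
        sample_id="S1", chrom=chrom, pos=pos, ref="A", alt="T",
        caller=caller, depth=depth, alt_reads=alt,
    )


def consensus(maf=0.4, gene=None, depth=100, **kw) -> ConsensusVariant:
    alt = int(round(maf * depth))
    defaults = dict(
        sample_id="S1", chrom="chr1", pos=1000, ref="A", alt="T",
        callers_supporting=frozenset({"freebayes", "gatk"}),
        depth=depth, alt_reads=alt, gene=gene,
    )
    defaults.update(kw)
    return ConsensusVariant(**defaults)


class TestReadCallerVcfs:
    def test_biallelic_record_maps_ad_and_dp(self, tmp_path):
        path = tmp_path / "a.vcf"
        gio.write_vcf(path, "S1", [("chr1", 1000, "A", "T", 100, 40)])
        calls = read_caller_vcfs({"freebayes": path}, "S1")
        assert len(calls) == 1
        assert calls[0].depth == 100 and calls[0].alt_reads == 40
        assert calls[0].key == ("chr1", 1000, "A", "T")

    def test_multiallelic_record_is_split(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t500\t.\tA\tC,T\t.\tPASS\t.\tGT:AD:DP\t1/2:10,60,30:100\n"
        )
        path = tmp_path / "m.vcf"
        path.write_text(text)
        calls = read_caller_vcfs({"gatk": path}, "S1")
        assert {(c.alt, c.alt_reads) for c in calls} == {("C", 60), ("T", 30)}

    def test_record_without_ad_is_skipped(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
        )
        path = tmp_path / "noad.vcf"
        path.write_text(text)
        assert read_caller_vcfs({"samtools": path}, "S1") == []

    def test_empty_vcf_yields_no_calls(self, tmp_path):
        path = tmp_path / "e.vcf"
        gio.write_vcf(path, "S1", [])
        assert read_caller_vcfs({"freebayes": path}, "S1") == []


class TestBuildConsensus:
    def test_two_of_three_callers_retained(self):
        calls = [call("freebayes"), call("samtools")]
        (v,) = build_consensus(calls, POLICY)
        assert v.status != "filtered"
        assert v.callers_supporting == {"freebayes", "samtools"}

    def test_single_caller_filtered(self):
        (v,) = build_consensus([call("gatk")], POLICY)
        assert v.status == "filtered"
        assert "insufficient_callers" in v.filter_reasons

    def test_low_read_support_filtered(self):
        calls = [call("freebayes", alt=8), call("samtools", alt=8)]
        (v,) = build_consensus(calls, POLICY)
        assert "low_read_support" in v.filter_reasons

    def test_representative_is_max_depth_caller(self):
        calls = [call("freebayes", depth=80, alt=20), call("gatk", depth=120, alt=48)]
        (v,) = build_consensus(calls, POLICY)
        assert (v.depth, v.alt_reads) == (120, 48)

    def test_mixed_samples_rejected(self):
        other = dataclasses.replace(call(), sample_id="S2")
        with pytest.raises(ValueError, match="multiple samples"):
            build_consensus([call(), other], POLICY)


class TestMafFilter:
    @pytest.mark.parametrize(
        "gene,maf,kept",
        [
            ("TP53", 0.07, True),    # gene of interest, above 5% floor
            ("TP53", 0.05, True),    # inclusive boundary
            ("TP53", 0.04, False),
            ("EGFR", 0.07, False),   # not a gene of interest
            ("EGFR", 0.15, False),   # exclusive boundary
            ("EGFR", 0.30, True),
            (None, 0.30, True),
        ],
    )
    def test_two_tier_maf_rule(self, gene, maf, kept):
        v = apply_maf_filter(consensus(maf=maf, gene=gene), POLICY)
        assert ("maf_below_threshold" not in v.filter_reasons) is kept


class TestSomaticWithNormal:
    def test_zero_alt_in_normal_is_somatic(self):
        v = classify_somatic_with_normal(consensus(), 0, POLICY)
        assert v.status == "somatic"

    def test_one_alt_read_flagged_for_review(self):
        v = classify_somatic_with_normal(consensus(), 1, POLICY)
        assert v.status == "review_flagged"

    def test_many_alt_reads_filtered_as_germline(self):
        v = classify_somatic_with_normal(consensus(), 10, POLICY)
        assert v.status == "filtered"
        assert "present_in_normal" in v.filter_reasons

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_somatic_with_normal(consensus(), -1, POLICY)


class TestSomaticWithoutNormal:
    def test_population_polymorphism_filtered(self):
        v = classify_somatic_without_normal(
            consensus(pop_af_exac=0.001), POLICY
        )
        assert v.status == "filtered"
        assert "population_polymorphism" in v.filter_reasons

    @pytest.mark.parametrize(
        "field,af,filtered",
        [
            ("pop_af_1000g", 0.0005, True),   # inclusive cutoff
            ("pop_af_1000g", 0.0004, False),
            ("pop_af_evs", 0.0005, True),
            ("pop_af_exac", 0.00005, True),
            ("pop_af_exac", 0.00004, False),
        ],
    )
    def test_population_cutoffs(self, field, af, filtered):
        v = classify_somatic_without_normal(
            consensus(in_cosmic=True, **{field: af}), POLICY
        )
        assert ("population_polymorphism" in v.filter_reasons) is filtered

    def test_cosmic_variant_rescued(self):
        v = classify_somatic_without_normal(consensus(in_cosmic=True), POLICY)
        assert v.status == "putative_somatic"

    def test_high_impact_variant_rescued(self):
        v = classify_somatic_without_normal(
            consensus(functional_impact="high"), POLICY
        )
        assert v.status == "putative_somatic"

    def test_low_impact_non_cosmic_filtered(self):
        v = classify_somatic_without_normal(
            consensus(functional_impact="low"), POLICY
        )
        assert v.status == "filtered"
        assert "no_somatic_evidence" in v.filter_reasons

    def test_absent_population_af_treated_as_novel(self):
        v = classify_somatic_without_normal(consensus(in_cosmic=True), POLICY)
        assert "population_polymorphism" not in v.filter_reasons


class TestPolicy:
    def test_maf_tier_ordering_enforced(self):
        with pytest.raises(ValueError):
            FilterPolicy(goi_maf_min=0.2, other_maf_min=0.15)


class TestCascadeProperties:
    @given(normal_alt=st.integers(min_value=1, max_value=500))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_variant_with_alt_in_normal_never_somatic(self, normal_alt):
        v = classify_somatic_with_normal(consensus(), normal_alt, POLICY)
        assert v.status != "somatic"

    @given(
        maf=st.floats(min_value=0.0, max_value=1.0),
        lo=st.floats(min_value=0.05, max_value=0.5),
        hi=st.floats(min_value=0.05, max_value=0.5),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_raising_maf_threshold_never_retains_more(self, maf, lo, hi):
        lo, hi = sorted((lo, hi))
        v_lo = apply_maf_filter(consensus(maf=maf), FilterPolicy(other_maf_min=lo))
        v_hi = apply_maf_filter(consensus(maf=maf), FilterPolicy(other_maf_min=hi))
        if v_lo.status == "filtered":
            assert v_hi.status == "filtered"

    @given(
        maf=st.floats(min_value=0.0, max_value=1.0),
        normal_alt=st.integers(min_value=0, max_value=10),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_rule_order_does_not_change_final_status(self, maf, normal_alt):
        base = consensus(maf=maf)
        a = classify_somatic_with_normal(apply_maf_filter(base, POLICY), normal_alt, POLICY)
        b = apply_maf_filter(classify_somatic_with_normal(base, normal_alt, POLICY), POLICY)
        assert a.status == b.status
        assert sorted(a.filter_reasons) == sorted(b.filter_reasons)


class TestFullCascade:
    def test_goi_read_support_waiver(self):
        """A 7% MAF TP53 variant survives the 10% read-support rule under
        the default policy but not when the waiver is off."""
        import pandas as pd

        calls = [call("freebayes", alt=7), call("samtools", alt=7)]
        ann = pd.DataFrame(
            [{
                "chrom": "chr1", "pos": 1000, "ref": "A", "alt": "T",
                "gene": "TP53", "protein_change": "R273H", "effect": "missense",
                "functional_impact": "high", "in_cosmic": True,
                "pop_af_1000g": 0.0, "pop_af_evs": 0.0, "pop_af_exac": 0.0,
            }]
        )
        (kept,) = run_filter_cascade(calls, POLICY, annotation=ann,
                                     normal_alt_lookup={})
        assert kept.status == "somatic"
        strict = FilterPolicy(waive_read_support_for_goi=False)
        (dropped,) = run_filter_cascade(calls, strict, annotation=ann,
                                        normal_alt_lookup={})
        assert "low_read_support" in dropped.filter_reasons
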