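"""Small-variant reportability filtering and CNA amplification calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exomark import (
    CopyNumberCall,
    DomainError,
    PipelineConfig,
    VariantRecord,
    apply_reportability_filter,
    call_amplifications,
    min_detectable_vaf,
)


def make_record(alt_count, depth=200, ref="A", alt="G", quality_pass=True, pos=100):
    return VariantRecord("chr1", pos, ref, alt, depth, alt_count, quality_pass=quality_pass)


class TestMinDetectableVaf:
    @pytest.mark.parametrize(
        "depth,min_alt,expected",
        [(200, 10, 0.05), (100, 10, 0.10), (1, 1, 1.0)],
    )
    def test_examples(self, depth, min_alt, expected):
        assert min_detectable_vaf(depth, min_alt) == expected

    def test_zero_depth_is_domain_error(self):
        with pytest.raises(DomainError):
            min_detectable_vaf(0, 10)

    @given(st.integers(1, 10_000), st.integers(1, 100))
    def test_rational_contract(self, depth, min_alt):
        """The result is the exact quotient m/d: multiplying back by the depth
        recovers the read floor to within one ulp."""
        vaf = min_detectable_vaf(depth, min_alt)
        assert vaf == min_alt / depth  # exactly the correctly-rounded rational
        assert vaf * depth == pytest.approx(min_alt, rel=1e-15)


class TestReportability:
    def test_snv_at_support_floor_passes(self, config):
        (r,) = apply_reportability_filter([make_record(10)], config)
        assert r.is_pass

    def test_snv_below_support_floor_is_labeled(self, config):
        (r,) = apply_reportability_filter([make_record(9)], config)
        assert "min_alt_reads" in r.filters

    def test_snv_below_lod_is_labeled(self, config):
        # 10 mutant reads at 400x is 2.5% VAF: enough reads, below the 5% LOD
        (r,) = apply_reportability_filter([make_record(10, depth=400)], config)
        assert r.filters == ["below_lod"]

    def test_indel_lod_is_ten_percent(self, config):
        ins = VariantRecord("chr1", 10, "A", "AT", 200, 15)  # 7.5% insertion
        (r,) = apply_reportability_filter([ins], config)
        assert r.filters == ["below_lod"]

    def test_long_deletion_out_of_scope(self, config):
        ref = "A" + "C" * 25
        deletion = VariantRecord("chr1", 10, ref, "A", 200, 30)  # 25 bp deleted, 15% VAF
        (r,) = apply_reportability_filter([deletion], config)
        assert r.filters == ["deletion_scope"]

    def test_deletion_just_under_scope_passes(self, config):
        ref = "A" + "C" * 19
        deletion = VariantRecord("chr1", 10, ref, "A", 200, 30)
        (r,) = apply_reportability_filter([deletion], config)
        assert r.is_pass

    def test_caller_quality_failure_is_labeled(self, config):
        (r,) = apply_reportability_filter([make_record(30, quality_pass=False)], config)
        assert "caller_quality" in r.filters

    def test_brute_force_oracle_on_randomized_records(self, config):
        """PASS set equals an independent per-record re-check of all predicates."""
        rng = np.random.default_rng(42)
        records = []
        for i in range(200):
            depth = int(rng.integers(1, 400))
            alt = int(rng.integers(0, depth + 1))
            kind = rng.choice(["SNV", "INS", "DEL"])
            if kind == "SNV":
                ref, alt_seq = "A", "G"
            elif kind == "INS":
                ref, alt_seq = "A", "A" + "T" * int(rng.integers(1, 5))
            else:
                ref, alt_seq = "A" + "T" * int(rng.integers(1, 30)), "A"
            records.append(
                VariantRecord("chr1", i + 1, ref, alt_seq, depth, alt,
                              quality_pass=bool(rng.random() > 0.1))
            )
        labeled = apply_reportability_filter(records, config)
        for r_in, r_out in zip(records, labeled):
            vaf = r_in.alt_count / r_in.total_depth
            lod = 0.05 if r_in.variant_class in ("SNV", "MNV") else 0.10
            expect_pass = (
                r_in.quality_pass
                and r_in.alt_count >= 10
                and vaf >= lod
                and not (
                    r_in.variant_class == "DEL"
                    and len(r_in.ref) - len(r_in.alt) >= 20
                )
            )
            assert r_out.is_pass == expect_pass, (r_in, r_out.filters)

    def test_idempotent_on_own_pass_output(self, config):
        rng = np.random.default_rng(7)
        records = [make_record(int(rng.integers(0, 201)), pos=i + 1) for i in range(50)]
        once = [r for r in apply_reportability_filter(records, config) if r.is_pass]
        twice = apply_reportability_filter(once, config)
        assert [r.filters for r in twice] == [[] for _ in once]

    @given(st.integers(1, 30))
    def test_raising_support_floor_shrinks_pass_set(self, floor):
        records = [make_record(k, pos=k + 1) for k in range(0, 40)]
        loose = {
            r.pos
            for r in apply_reportability_filter(records, PipelineConfig(min_alt_reads=floor))
            if r.is_pass
        }
        strict = {
            r.pos
            for r in apply_reportability_filter(
                records, PipelineConfig(min_alt_reads=floor + 5)
            )
            if r.is_pass
        }
        assert strict <= loose

    def test_empty_input_allowed(self, config):
        assert apply_reportability_filter([], config) == []

    def test_input_order_preserved(self, config):
        records = [make_record(50, pos=p) for p in (300, 100, 200)]
        assert [r.pos for r in apply_reportability_filter(records, config)] == [300, 100, 200]


class TestAmplifications:
    @pytest.mark.parametrize(
        "cn,expected", [(6.0, True), (5.9, False), (2.0, False), (9.5, True)]
    )
    def test_inclusive_cutoff(self, config, cn, expected):
        (call,) = call_amplifications([CopyNumberCall("ERBB2", cn)], config)
        assert call.amplified is expected

    def test_negative_copy_number_rejected(self):
        with pytest.raises(DomainError):
            CopyNumberCall("MET", -1.0)

    def test_order_preserved(self, config):
        calls = [CopyNumberCall(g, cn) for g, cn in [("B", 7.0), ("A", 2.0), ("C", 6.0)]]
        out = call_amplifications(calls, config)
        assert [c.gene for c in out] == ["B", "A", "C"]
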