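"""Tumor-only germline-filter cascade and TMB classification."""

import itertools

import pytest

from exomark import (
    BaselineModel,
    ConfigError,
    DomainError,
    PipelineConfig,
    VariantRecord,
    classify_tmb,
    compute_tmb,
    level1_population_filter,
    level2_vaf_filter,
    level3_baseline_filter,
)
from exomark.synthetic import simulate_panel_baseline, simulate_tumor_only_vcf


def variant(pos=1, vaf=0.2, depth=200, af_global=None, af_sas=None):
    return VariantRecord(
        "chr1", pos, "A", "G", depth, int(round(vaf * depth)),
        pop_af_global=af_global, pop_af_south_asian=af_sas,
    )


class TestLevel1:
    @pytest.mark.parametrize(
        "af,kept",
        [(0.015, False), (0.005, True), (0.010, True), (None, True)],
        ids=["polymorphic", "rare", "exactly-1pct-strict", "absent"],
    )
    def test_global_af_rule(self, config, af, kept):
        out = level1_population_filter([variant(af_global=af)], config)
        assert bool(out) is kept

    def test_south_asian_af_alone_can_remove(self, config):
        out = level1_population_filter([variant(af_global=0.001, af_sas=0.05)], config)
        assert out == []


class TestLevel2:
    @pytest.mark.parametrize(
        "vaf,kept",
        [(0.50, False), (0.95, False), (0.05, True), (0.40, False), (0.60, False),
         (0.39, True), (0.61, True), (0.90, False), (0.89, True)],
    )
    def test_germline_vaf_patterns(self, config, vaf, kept):
        out = level2_vaf_filter([variant(vaf=vaf)], config)
        assert bool(out) is kept

    def test_empty_input(self, config):
        assert level2_vaf_filter([], config) == []


class TestLevel3:
    def make_baseline(self, occurrences):
        return BaselineModel(
            n_normals=10,
            site_occurrence={("chr1", pos, "A", "G"): occ for pos, occ in occurrences},
        )

    def test_recurrent_site_removed(self, config):
        baseline = self.make_baseline([(1, 3)])
        assert level3_baseline_filter([variant(pos=1)], baseline, config) == []

    def test_singleton_site_retained(self, config):
        baseline = self.make_baseline([(1, 1)])
        assert len(level3_baseline_filter([variant(pos=1)], baseline, config)) == 1

    def test_absent_site_retained(self, config):
        baseline = self.make_baseline([(99, 5)])
        assert len(level3_baseline_filter([variant(pos=1)], baseline, config)) == 1

    def test_empty_baseline_is_configuration_error(self, config):
        empty = BaselineModel(n_normals=5)
        with pytest.raises(ConfigError):
            level3_baseline_filter([variant()], empty, config)


class TestComputeTmb:
    def test_sixty_survivors_over_thirty_mb(self, config):
        records = [variant(pos=i + 1, vaf=0.2) for i in range(60)]
        result = compute_tmb(records, config)
        assert result.tmb == pytest.approx(2.0)
        assert result.classification == "low"

    def test_six_hundred_survivors_is_exactly_high(self, config):
        records = [variant(pos=i + 1, vaf=0.2) for i in range(600)]
        result = compute_tmb(records, config)
        assert result.tmb == pytest.approx(20.0)
        assert result.classification == "high"

    def test_no_survivors(self, config):
        result = compute_tmb([], config)
        assert result.tmb == 0.0 and result.classification == "low"

    def test_counts_are_monotone_non_increasing(self, config):
        records, truth = simulate_tumor_only_vcf(50, 30, 60, seed=5)
        baseline = simulate_panel_baseline(truth, seed=5)
        result = compute_tmb(records, config, baseline)
        assert (
            result.n_input
            >= result.n_after_level1
            >= result.n_after_level2
            >= result.n_after_level3
        )

    def test_consequence_whitelist_restricts_numerator(self):
        cfg = PipelineConfig(tmb_consequence_whitelist=("missense_variant",))
        records = [variant(pos=1, vaf=0.2), variant(pos=2, vaf=0.2)]
        records[1].consequence = "synonymous_variant"
        records[0].consequence = "missense_variant"
        assert compute_tmb(records, cfg).n_input == 1

    def test_nonpositive_exome_size_rejected(self):
        with pytest.raises(ConfigError):
            compute_tmb([], PipelineConfig(exome_size_mb=0.0))
        # construction itself rejects negative footprints
        with pytest.raises(ConfigError):
            PipelineConfig(exome_size_mb=-1.0)


class TestClassifyTmb:
    @pytest.mark.parametrize("tmb,label", [(20.0, "high"), (19.99, "low"), (0.0, "low")])
    def test_inclusive_boundary(self, config, tmb, label):
        assert classify_tmb(tmb, config) == label

    def test_negative_is_domain_error(self, config):
        with pytest.raises(DomainError):
            classify_tmb(-1.0, config)


def test_levels_commute_pairwise_on_synthetic_data(config):
    """Each level filters on an independent predicate, so order cannot matter."""
    records, truth = simulate_tumor_only_vcf(40, 20, 40, seed=9)
    baseline = simulate_panel_baseline(truth, seed=9)
    filters = {
        "l1": lambda rs: level1_population_filter(rs, config),
        "l2": lambda rs: level2_vaf_filter(rs, config),
        "l3": lambda rs: level3_baseline_filter(rs, baseline, config),
    }
    for a, b in itertools.permutations(filters, 2):
        ab = filters[b](filters[a](records))
        ba = filters[a](filters[b](records))
        assert [r.key for r in ab] == [r.key for r in ba]


def test_each_level_output_is_subset_of_input(config):
    records, truth = simulate_tumor_only_vcf(30, 20, 30, seed=13)
    baseline = simulate_panel_baseline(truth, seed=13)
    keys = {r.key for r in records}
    for out in (
        level1_population_filter(records, config),
        level2_vaf_filter(records, config),
        level3_baseline_filter(records, baseline, config),
    ):
        assert {r.key for r in out} <= keys
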