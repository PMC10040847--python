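"""QC gates, coverage summaries and clinical-validation statistics."""

import numpy as np
import pandas as pd
import pytest

from exomark import (
    DomainError,
    concordance_metrics,
    coverage_summary,
    evaluate_sample_qc,
    reproducibility,
)

NOMINAL = {
    "tumor_content": 0.5,
    "tumor_area_mm2": 25.0,
    "library_nM": 14.0,
    "library_peak_bp": 310.0,
    "mean_depth": 230.0,
    "on_target_fraction": 0.92,
    "uniformity_fraction": 0.96,
}


class TestSampleQC:
    @pytest.mark.parametrize(
        "key,value,passes",
        [
            ("tumor_content", 0.10, True),
            ("tumor_content", 0.09, False),
            ("tumor_area_mm2", 5.0, True),
            ("tumor_area_mm2", 4.9, False),
            ("library_nM", 10.0, True),
            ("library_nM", 9.9, False),
            ("library_peak_bp", 300.0, True),
            ("library_peak_bp", 401.0, False),
            ("mean_depth", 200.0, True),
            ("mean_depth", 199.0, False),
            ("on_target_fraction", 0.80, False),   # strict >
            ("on_target_fraction", 0.81, True),
            ("uniformity_fraction", 0.90, False),  # strict >
            ("uniformity_fraction", 0.91, True),
        ],
    )
    def test_gate_boundaries(self, config, key, value, passes):
        from exomark.qc import METRIC_KEYS

        result = evaluate_sample_qc({key: value}, config)
        assert result.checks[METRIC_KEYS[key]] is passes

    def test_all_nominal_is_overall_pass(self, config):
        result = evaluate_sample_qc(NOMINAL, config)
        assert result.overall_pass
        assert all(v is True for v in result.checks.values())

    def test_unmeasured_checks_skipped_in_verdict(self, config):
        result = evaluate_sample_qc({"tumor_content": 0.5}, config)
        assert result.checks["tumor_content"] is True
        assert result.checks["library_peak"] is None
        assert result.overall_pass

    def test_one_failed_gate_fails_overall(self, config):
        metrics = dict(NOMINAL, tumor_content=0.05)
        assert not evaluate_sample_qc(metrics, config).overall_pass

    def test_negative_metric_rejected(self, config):
        with pytest.raises(DomainError):
            evaluate_sample_qc({"mean_depth": -5.0}, config)


def track(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "depth"])


class TestCoverage:
    def test_flat_on_target_coverage(self, config):
        df = track([("chr1", p, 200) for p in range(1, 11)])
        mean, on_target, uniformity = coverage_summary(df, [("chr1", 0, 10)], config)
        assert (mean, on_target, uniformity) == (200.0, 1.0, 1.0)

    def test_uniformity_with_a_dropout_base(self, config):
        df = track([("chr1", 1, 10), ("chr1", 2, 10), ("chr1", 3, 0), ("chr1", 4, 10)])
        mean, _, uniformity = coverage_summary(df, [("chr1", 0, 4)], config)
        assert mean == pytest.approx(7.5)
        assert uniformity == pytest.approx(0.75)  # 0.2 * 7.5 = 1.5; 3 of 4 bases

    def test_half_of_aligned_bases_off_target(self, config):
        df = track([("chr1", 1, 100), ("chr1", 1000, 100)])
        _, on_target, _ = coverage_summary(df, [("chr1", 0, 1)], config)
        assert on_target == pytest.approx(0.5)

    def test_empty_target_is_domain_error(self, config):
        with pytest.raises(DomainError):
            coverage_summary(track([("chr1", 1, 10)]), [], config)

    def test_uniformity_matches_brute_force_recount(self, config):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            depths = rng.poisson(100, size=n)
            df = track([("chr1", p + 1, int(d)) for p, d in enumerate(depths)])
            mean, _, uniformity = coverage_summary(df, [("chr1", 0, n)], config)
            assert mean == pytest.approx(depths.mean())
            brute = sum(1 for d in depths if d >= 0.2 * depths.mean()) / n
            assert uniformity == pytest.approx(brute)


class TestConcordance:
    def test_worked_confusion_table(self):
        pos = {f"p{i}" for i in range(40)}
        neg = {f"n{i}" for i in range(40)}
        observed = pos | {"n0"}  # all positives found, one false positive
        report = concordance_metrics(pos, neg, observed)
        assert (report.tp, report.fn, report.tn, report.fp) == (40, 0, 39, 1)
        assert report.sensitivity == pytest.approx(100.0)
        assert report.specificity == pytest.approx(97.5)
        assert report.accuracy == pytest.approx(98.75)

    def test_perfect_agreement(self):
        pos = {("chr1", 10, "A", "G"), ("chr2", 20, "C", "T")}
        neg = {("chr3", 5, "G", "A")}
        report = concordance_metrics(pos, neg, pos)
        assert report.sensitivity == report.specificity == report.accuracy == 100.0

    def test_counts_match_element_by_element_tally(self):
        rng = np.random.default_rng(23)
        features = [f"f{i}" for i in range(50)]
        labels = rng.random(50) < 0.5
        pos = {f for f, l in zip(features, labels) if l}
        neg = {f for f, l in zip(features, labels) if not l}
        observed = {f for f in features if rng.random() < 0.6}
        report = concordance_metrics(pos, neg, observed)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for f in features:
            if f in pos:
                tally["tp" if f in observed else "fn"] += 1
            else:
                tally["fp" if f in observed else "tn"] += 1
        assert (report.tp, report.fp, report.tn, report.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"],
        )

    def test_confusion_counts_conserve_truth_sets(self):
        pos = {f"p{i}" for i in range(17)}
        neg = {f"n{i}" for i in range(23)}
        observed = {f"p{i}" for i in range(9)} | {f"n{i}" for i in range(4)}
        report = concordance_metrics(pos, neg, observed)
        assert report.tp + report.fn == len(pos)
        assert report.tn + report.fp == len(neg)

    def test_duplicates_collapse_to_set_semantics(self):
        report = concordance_metrics(["a", "a", "b"], ["c", "c"], ["a", "a", "c"])
        assert (report.tp, report.fn, report.fp, report.tn) == (1, 1, 1, 0)

    def test_overlapping_truth_keys_rejected(self):
        with pytest.raises(DomainError):
            concordance_metrics({"x"}, {"x", "y"}, set())


class TestReproducibility:
    def test_all_features_in_all_replicates(self):
        truth = {f"v{i}" for i in range(25)}
        assert reproducibility(truth, [set(truth)] * 4) == 100.0

    def test_one_feature_missed_in_one_replicate(self):
        truth = {f"v{i}" for i in range(25)}
        reps = [set(truth), set(truth) - {"v0"}, set(truth)]
        assert reproducibility(truth, reps) == pytest.approx(96.0)

    def test_feature_absent_everywhere(self):
        assert reproducibility({"v"}, [set(), set()]) == 0.0

    def test_empty_truth_is_domain_error(self):
        with pytest.raises(DomainError):
            reproducibility(set(), [set(), set()])

    def test_single_replicate_is_domain_error(self):
        with pytest.raises(DomainError):
            reproducibility({"v"}, [{"v"}])
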