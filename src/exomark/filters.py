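"""Reportability filtering of small variants and copy-number amplification calls.

A small variant is reportable only when the caller flagged it as good
quality, at least ``min_alt_reads`` mutant reads support it, its VAF reaches
the class-specific limit of detection (5% for SNV/MNV, 10% for INS/DEL by
default), and — for deletions — fewer than ``max_deletion_bp`` bases are
deleted (long deletions are outside the validated scope of a hybrid-capture
exome assay on FFPE material). Gene amplification is called at copy number
greater than or equal to the configured cutoff (6 by default).
"""

from __future__ import annotations

from dataclasses import replace

from .config import PipelineConfig
from .errors import DomainError
from .models import CopyNumberCall, VariantRecord


def min_detectable_vaf(depth: int, min_alt_reads: int) -> float:
    """Smallest VAF whose expected mutant-read count meets the support floor.

    At the assay's 200x depth with a 10-read support floor this is 0.05 —
    the 5% SNV limit of detection. Exact rational contract:
    ``min_detectable_vaf(d, m) * d == m``.
    """
    if depth <= 0:
        raise DomainError(f"depth must be positive, got {depth}")
    if min_alt_reads < 1:
        raise DomainError(f"min_alt_reads must be >= 1, got {min_alt_reads}")
    return min_alt_reads / depth


def reportability_failures(record: VariantRecord, config: PipelineConfig) -> list[str]:
    """Names of every reportability criterion this record fails (empty = PASS)."""
    failed: list[str] = []
    if not record.quality_pass:
        failed.append("caller_quality")
    if record.alt_count < config.min_alt_reads:
        failed.append("min_alt_reads")
    lod = config.lod_snv if record.variant_class in ("SNV", "MNV") else config.lod_indel
    if record.vaf < lod:
        failed.append("below_lod")
    if record.variant_class == "DEL" and record.deletion_length >= config.max_deletion_bp:
        failed.append("deletion_scope")
    return failed


def apply_reportability_filter(
    records: list[VariantRecord], config: PipelineConfig | None = None
) -> list[VariantRecord]:
    """Label each record PASS or with every failed filter name; order preserved.

    Returns new records; inputs are not mutated. Idempotent on its own PASS
    output.
    """
    config = config or PipelineConfig()
    return [replace(r, filters=reportability_failures(r, config)) for r in records]


def call_amplifications(
    calls: list[CopyNumberCall], config: PipelineConfig | None = None
) -> list[CopyNumberCall]:
    """Label each gene-level call amplified iff copy_number >= cutoff (inclusive)."""
    config = config or PipelineConfig()
    return [
        replace(c, amplified=c.copy_number >= config.cna_amplification_cutoff)
        for c in calls
    ]
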