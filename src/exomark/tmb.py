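"""Tumor-only germline filtering and tumor mutational burden.

Without a matched normal, germline variants must be removed from a tumor
VCF before counting somatic mutations. The engine applies a sequential
three-level cascade:

level 1 (tolerant)  — drop polymorphisms whose global or South-Asian
                      population allele fraction exceeds 1%;
level 2 (stringent) — drop variants whose VAF looks germline: inside the
                      heterozygous window (0.40–0.60 by default) or at or
                      above the homozygous floor (0.90);
level 3 (baseline)  — drop variants recurrent in a panel of normals built
                      by pooling blood samples of healthy individuals
                      (present in >= 2 normals by default).

TMB is the surviving coding mutation count divided by the exome footprint
in megabases; at or above 20 mut/Mb the sample is classified TMB-high.

Each level is a pure set filter (output is a subset of the input), so the
recorded per-level counts are monotone non-increasing.
"""

from __future__ import annotations

from .config import PipelineConfig
from .errors import ConfigError, DomainError
from .models import BaselineModel, TMBResult, VariantRecord


def level1_population_filter(
    records: list[VariantRecord], config: PipelineConfig | None = None
) -> list[VariantRecord]:
    """Drop records whose population AF exceeds ``max_pop_af`` (strict >).

    Records with both population annotations absent are retained: absence of
    frequency evidence cannot mark a variant polymorphic.
    """
    config = config or PipelineConfig()
    kept = []
    for r in records:
        polymorphic = any(
            af is not None and af > config.max_pop_af
            for af in (r.pop_af_global, r.pop_af_south_asian)
        )
        if not polymorphic:
            kept.append(r)
    return kept


def level2_vaf_filter(
    records: list[VariantRecord], config: PipelineConfig | None = None
) -> list[VariantRecord]:
    """Drop records whose VAF matches a germline genotype pattern.

    Heterozygous: VAF inside [het_vaf_low, het_vaf_high] (inclusive).
    Homozygous: VAF >= hom_vaf_min. Everything else is retained.
    """
    config = config or PipelineConfig()
    kept = []
    for r in records:
        het = config.het_vaf_low <= r.vaf <= config.het_vaf_high
        hom = r.vaf >= config.hom_vaf_min
        if not (het or hom):
            kept.append(r)
    return kept


def level3_baseline_filter(
    records: list[VariantRecord],
    baseline: BaselineModel,
    config: PipelineConfig | None = None,
) -> list[VariantRecord]:
    """Drop records recurrent in the panel of normals.

    A site is germline/artifactual when it occurs in at least
    ``baseline_min_occurrence`` normals; singleton panel hits are retained
    to avoid over-filtering on a single normal's noise.
    """
    config = config or PipelineConfig()
    if baseline is None or baseline.is_empty:
        raise ConfigError("level 3 filtering requires a non-empty panel-of-normals baseline")
    return [
        r
        for r in records
        if baseline.site_occurrence.get(r.key, 0) < config.baseline_min_occurrence
    ]


def classify_tmb(tmb: float, config: PipelineConfig | None = None) -> str:
    """'high' iff tmb >= tmb_high_cutoff (inclusive, 20 mut/Mb default), else 'low'."""
    config = config or PipelineConfig()
    if tmb < 0:
        raise DomainError(f"TMB cannot be negative, got {tmb}")
    return "high" if tmb >= config.tmb_high_cutoff else "low"


def compute_tmb(
    records: list[VariantRecord],
    config: PipelineConfig | None = None,
    baseline: BaselineModel | None = None,
) -> TMBResult:
    """Run the cascade in order 1 -> 2 -> 3 and convert the survivor count to mut/Mb.

    ``records`` should be the PASS output of the reportability filter
    restricted to coding calls. When ``tmb_consequence_whitelist`` is set,
    annotated records outside the whitelist are excluded from the input
    count. When no panel baseline is available level 3 retains everything
    (its count then equals the level-2 count).
    """
    config = config or PipelineConfig()
    if config.exome_size_mb <= 0:
        raise ConfigError(f"exome_size_mb must be positive, got {config.exome_size_mb}")
    if config.tmb_consequence_whitelist is not None:
        allowed = set(config.tmb_consequence_whitelist)
        records = [r for r in records if r.consequence is None or r.consequence in allowed]
    after1 = level1_population_filter(records, config)
    after2 = level2_vaf_filter(after1, config)
    if baseline is not None and not baseline.is_empty:
        after3 = level3_baseline_filter(after2, baseline, config)
    else:
        after3 = after2
    tmb = len(after3) / config.exome_size_mb
    return TMBResult(
        n_input=len(records),
        n_after_level1=len(after1),
        n_after_level2=len(after2),
        n_after_level3=len(after3),
        tmb=tmb,
        classification=classify_tmb(tmb, config),
    )
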