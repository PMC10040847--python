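"""Domain types for the biomarker engine.

The pipeline consumes the outputs of an upstream aligner/caller: annotated
small-variant calls, gene-level copy-number calls, RNA fusion calls and
per-locus microsatellite repeat-length histograms. Each type here is a plain
validated container; all filtering logic lives in the engine modules.

Coordinates are 1-based inclusive (VCF convention); target regions loaded
from BED are half-open 0-based and converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError, DomainError

#: variant classes for small variants
VARIANT_CLASSES = ("SNV", "MNV", "INS", "DEL")

#: ordered fusion-caller confidence levels, lowest first
CONFIDENCE_LEVELS = ("low", "medium", "high")

#: fusion open-reading-frame status values
ORF_STATUSES = ("retained", "lost", "unknown")

#: identity key for a small variant site
SiteKey = tuple[str, int, str, str]


def infer_variant_class(ref: str, alt: str) -> str:
    """Classify a REF/ALT allele pair as SNV, MNV, INS or DEL."""
    if not ref or not alt:
        raise DomainError(f"empty allele in {ref!r}>{alt!r}")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass
class VariantRecord:
    """One small-variant call (one ALT allele) with read support and annotations.

    ``vaf`` is always ``alt_count / total_depth`` (0 when the site has no
    coverage); population allele fractions and gene annotations are optional
    and ``None`` when the source VCF does not carry them. ``filters`` holds
    the names of every reportability filter the record failed (empty, or
    ``["PASS"]`` semantics, means reportable).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_count: int
    variant_class: str = ""
    pop_af_global: float | None = None
    pop_af_south_asian: float | None = None
    gene: str | None = None
    consequence: str | None = None
    quality_pass: bool = True
    filters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variant_class:
            self.variant_class = infer_variant_class(self.ref, self.alt)
        if self.variant_class not in VARIANT_CLASSES:
            raise DomainError(f"unknown variant class {self.variant_class!r}")
        if self.total_depth < 0 or self.alt_count < 0:
            raise DomainError(
                f"negative read counts at {self.chrom}:{self.pos} "
                f"(DP={self.total_depth}, alt={self.alt_count})"
            )
        if self.alt_count > self.total_depth:
            raise DomainError(
                f"alt_count {self.alt_count} exceeds depth {self.total_depth} "
                f"at {self.chrom}:{self.pos}"
            )
        for af in (self.pop_af_global, self.pop_af_south_asian):
            if af is not None and not 0.0 <= af <= 1.0:
                raise DomainError(f"population AF {af} outside [0,1]")

    @property
    def vaf(self) -> float:
        """Variant allele fraction, alt reads over total reads."""
        if self.total_depth == 0:
            return 0.0
        return self.alt_count / self.total_depth

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def deletion_length(self) -> int:
        """Number of deleted bases (0 for non-deletions)."""
        return max(0, len(self.ref) - len(self.alt))

    @property
    def is_pass(self) -> bool:
        return not self.filters


@dataclass
class CopyNumberCall:
    """Gene-level copy-number call from the upstream CNA caller."""

    gene: str
    copy_number: float
    chrom: str = ""
    start: int = 0
    end: int = 0
    amplified: bool | None = None

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise DomainError(f"negative copy number {self.copy_number} for {self.gene}")
        if self.end and self.start > self.end:
            raise DomainError(f"segment start {self.start} > end {self.end} for {self.gene}")


@dataclass
class FusionCall:
    """RNA-derived gene-fusion call with junction read support."""

    gene_5p: str
    gene_3p: str
    junction_reads: int
    confidence: str = "high"
    orf_status: str = "unknown"
    chrom_5p: str = ""
    pos_5p: int = 0
    chrom_3p: str = ""
    pos_3p: int = 0
    drop_reasons: list[str] = field(default_factory=list)
    known: bool | None = None

    def __post_init__(self) -> None:
        if self.junction_reads < 0:
            raise DomainError("junction_reads must be >= 0")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise DomainError(f"unknown confidence {self.confidence!r}")
        if self.orf_status not in ORF_STATUSES:
            raise DomainError(f"unknown orf_status {self.orf_status!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_5p, self.gene_3p)


@dataclass
class MicrosatelliteProfile:
    """Repeat-length read histogram at one microsatellite locus in one sample."""

    locus_id: str
    chrom: str
    pos: int
    repeat_unit: str
    ref_repeat_count: int
    length_histogram: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.length_histogram.values()):
            raise DomainError(f"negative histogram count at locus {self.locus_id}")

    @property
    def total_reads(self) -> int:
        return sum(self.length_histogram.values())


@dataclass
class BaselineModel:
    """Panel-of-normals baseline built from blood samples of healthy individuals.

    ``site_occurrence`` maps small-variant site keys to the number of normals
    carrying the variant (used by the level-3 germline filter);
    ``msi_baseline`` maps locus ids to the (mean, sd) of the non-reference
    repeat-length read fraction across normals.
    """

    n_normals: int
    site_occurrence: dict[SiteKey, int] = field(default_factory=dict)
    msi_baseline: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_normals < 1:
            raise ConfigError("baseline panel must contain at least one normal")
        bad = [k for k, v in self.site_occurrence.items() if not 1 <= v <= self.n_normals]
        if bad:
            raise ConfigError(f"site occurrences outside [1, n_normals] at {bad[:3]}")
        if any(sd < 0 for _, sd in self.msi_baseline.values()):
            raise ConfigError("negative sd in MSI baseline")

    @property
    def is_empty(self) -> bool:
        return not self.site_occurrence and not self.msi_baseline


@dataclass
class TMBResult:
    """Tumor mutational burden after the three-level germline-filter cascade."""

    n_input: int
    n_after_level1: int
    n_after_level2: int
    n_after_level3: int
    tmb: float
    classification: str  # "high" | "low"

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_level1": self.n_after_level1,
            "n_after_level2": self.n_after_level2,
            "n_after_level3": self.n_after_level3,
            "tmb_mut_per_mb": round(self.tmb, 4),
            "classification": self.classification,
        }


@dataclass
class MSIResult:
    """Microsatellite instability score: percent unstable loci among evaluated."""

    n_evaluated: int
    n_unstable: int
    score: float | None
    classification: str  # "MSI-High" | "MSS" | "Not-Assessable"

    def as_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_unstable": self.n_unstable,
            "score_percent": None if self.score is None else round(self.score, 4),
            "classification": self.classification,
        }


@dataclass
class ConcordanceReport:
    """Confusion counts and validation statistics against an orthogonal truth set."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        """100 * tp / (tp + fn); NaN when there are no truth positives."""
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else math.nan

    @property
    def accuracy(self) -> float:
        denom = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / denom if denom else math.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity_percent": round(self.sensitivity, 4),
            "specificity_percent": round(self.specificity, 4),
            "accuracy_percent": round(self.accuracy, 4),
        }


@dataclass
class SampleQCResult:
    """Per-check specimen/library/sequencing QC booleans.

    A check whose input metric was not measured is ``None`` and does not
    count against the overall verdict.
    """

    checks: dict[str, bool | None]

    #: canonical check names, in report order
    CHECK_NAMES = (
        "tumor_content",
        "tumor_area",
        "library_concentration",
        "library_peak",
        "mean_depth",
        "on_target",
        "uniformity",
    )

    @property
    def overall_pass(self) -> bool:
        applicable = [v for v in self.checks.values() if v is not None]
        return all(applicable) if applicable else True

    def as_dict(self) -> dict:
        return {**self.checks, "overall_pass": self.overall_pass}
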