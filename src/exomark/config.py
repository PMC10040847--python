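"""Pipeline configuration: every threshold used by the engine, with the
validated assay defaults.

The defaults encode the thresholds under which the assay was validated:
a variant needs at least 10 good-quality mutant reads, the limit of
detection is 5% VAF for SNVs and 10% for INDELs, deletions of 20 bp or more
are out of assay scope, gene amplification is called at copy number >= 6,
fusions need high caller confidence and >= 5 junction-spanning reads,
polymorphisms above 1% population frequency are treated as germline,
TMB-high is >= 20 mutations/Mb and MSI-High is >= 15% unstable loci.
Everything is overridable from a YAML or JSON file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # --- small-variant reportability ---
    min_alt_reads: int = 10          # minimum good-quality mutant reads
    lod_snv: float = 0.05            # SNV/MNV limit of detection (VAF)
    lod_indel: float = 0.10          # INS/DEL limit of detection (VAF)
    max_deletion_bp: int = 20        # deletions of >= this many bases are out of scope

    # --- copy number ---
    cna_amplification_cutoff: float = 6.0   # amplified iff copy number >= cutoff

    # --- fusions ---
    min_fusion_junction_reads: int = 5
    fusion_required_confidence: str = "high"
    fusion_drop_unknown_orf: bool = False   # strict mode: drop ORF-unknown too

    # --- tumor-only germline filtering / TMB ---
    max_pop_af: float = 0.01         # level 1: polymorphic above 1% of the population
    het_vaf_low: float = 0.40        # level 2: heterozygous-germline VAF window
    het_vaf_high: float = 0.60
    hom_vaf_min: float = 0.90        # level 2: homozygous-germline VAF floor
    baseline_min_occurrence: int = 2  # level 3: normals carrying a site to call it germline
    tmb_high_cutoff: float = 20.0    # mut/Mb, inclusive
    exome_size_mb: float = 30.0      # coding footprint used as TMB denominator
    tmb_consequence_whitelist: tuple[str, ...] | None = None  # None = count all coding calls

    # --- MSI ---
    msi_high_cutoff: float = 15.0    # percent unstable loci, inclusive
    msi_min_locus_coverage: int = 20  # reads required to evaluate a locus
    msi_shift_sd_multiplier: float = 3.0
    msi_sd_floor: float = 0.01       # floor on baseline sd before the k*sd test

    # --- specimen / library / sequencing QC ---
    min_tumor_content: float = 0.10
    min_tumor_area_mm2: float = 5.0
    min_library_nM: float = 10.0
    library_peak_bp: float = 300.0
    library_peak_tolerance_bp: float = 100.0
    min_mean_depth: float = 200.0
    min_on_target_fraction: float = 0.80   # strict: must exceed
    min_uniformity_fraction: float = 0.90  # strict: must exceed
    uniformity_depth_fraction: float = 0.2  # base counts as uniform at >= this * mean depth

    # --- VCF dialect (tag names are caller-dependent) ---
    vcf_depth_tag: str = "DP"
    vcf_ad_tag: str = "AD"
    vcf_global_af_tag: str = "GLOBAL_AF"
    vcf_sas_af_tag: str = "SAS_AF"
    vcf_gene_tag: str = "GENE"
    vcf_consequence_tag: str = "CONSEQ"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ConfigError listing every violated invariant."""
        problems: list[str] = []
        fractions = {
            "lod_snv": self.lod_snv,
            "lod_indel": self.lod_indel,
            "max_pop_af": self.max_pop_af,
            "het_vaf_low": self.het_vaf_low,
            "het_vaf_high": self.het_vaf_high,
            "hom_vaf_min": self.hom_vaf_min,
            "min_tumor_content": self.min_tumor_content,
            "min_on_target_fraction": self.min_on_target_fraction,
            "min_uniformity_fraction": self.min_uniformity_fraction,
            "uniformity_depth_fraction": self.uniformity_depth_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                problems.append(f"{name}={value} outside [0,1]")
        counts = {
            "min_alt_reads": self.min_alt_reads,
            "max_deletion_bp": self.max_deletion_bp,
            "min_fusion_junction_reads": self.min_fusion_junction_reads,
            "baseline_min_occurrence": self.baseline_min_occurrence,
            "msi_min_locus_coverage": self.msi_min_locus_coverage,
        }
        for name, value in counts.items():
            if value < 0:
                problems.append(f"{name}={value} is negative")
        if self.lod_snv > self.lod_indel:
            problems.append(
                f"lod_snv={self.lod_snv} > lod_indel={self.lod_indel} "
                "(SNV LOD must not exceed INDEL LOD)"
            )
        if self.het_vaf_low > self.het_vaf_high:
            problems.append("het_vaf_low > het_vaf_high")
        for name in (
            "cna_amplification_cutoff",
            "tmb_high_cutoff",
            "exome_size_mb",
            "msi_high_cutoff",
            "msi_shift_sd_multiplier",
            "msi_sd_floor",
            "min_tumor_area_mm2",
            "min_library_nM",
            "library_peak_bp",
            "library_peak_tolerance_bp",
            "min_mean_depth",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} is negative")
        if self.fusion_required_confidence not in ("low", "medium", "high"):
            problems.append(
                f"fusion_required_confidence={self.fusion_required_confidence!r} "
                "not one of low/medium/high"
            )
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["tmb_consequence_whitelist"] is not None:
            d["tmb_consequence_whitelist"] = list(d["tmb_consequence_whitelist"])
        return d


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file, or defaults when absent.

    Keys in the file must be a subset of the config fields; unknown keys and
    invariant violations raise :class:`ConfigError` naming the offenders.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    if data.get("tmb_consequence_whitelist") is not None:
        data["tmb_consequence_whitelist"] = tuple(data["tmb_consequence_whitelist"])
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the active configuration to JSON (for report auditability)."""
    Path(path).write_text(json.dumps(config.as_dict(), indent=2, sort_keys=True) + "\n")
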