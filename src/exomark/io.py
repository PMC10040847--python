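"""Readers and writers for the standard formats the pipeline touches.

Small variants travel as VCF 4.2 (read and written through pysam); gene
copy-number calls, fusion calls, microsatellite histograms, depth tracks and
feature sets are tab-separated tables; target regions are BED (half-open,
0-based, converted to Python ranges on read).

Depth and alt-read counts come from the standard per-sample FORMAT fields
(default ``DP``/``AD``); population allele fractions and gene annotations
come from INFO tags (default ``GLOBAL_AF``, ``SAS_AF``, ``GENE``,
``CONSEQ``). All tag names are configurable because the upstream caller's
VCF dialect varies.
"""

from __future__ import annotations

import contextlib
from pathlib import Path

import pandas as pd
import pysam

from .config import PipelineConfig
from .errors import ConfigError, ParseError
from .models import (
    BaselineModel,
    CopyNumberCall,
    FusionCall,
    MicrosatelliteProfile,
    SiteKey,
    VariantRecord,
)

#: FILTER names this pipeline itself assigns (everything else in a FILTER
#: column is attributed to the upstream caller)
PIPELINE_FILTER_NAMES = ("caller_quality", "min_alt_reads", "below_lod", "deletion_scope")

_FILTER_DESCRIPTIONS = {
    "caller_quality": "Failed upstream caller quality",
    "min_alt_reads": "Fewer mutant reads than the reportability floor",
    "below_lod": "VAF below the class-specific limit of detection",
    "deletion_scope": "Deletion length outside the validated assay scope",
}

FUSION_COLUMNS = [
    "gene_5p", "gene_3p", "chrom_5p", "pos_5p", "chrom_3p", "pos_3p",
    "junction_reads", "confidence", "orf_status",
]

MSI_COLUMNS = ["locus_id", "chrom", "pos", "repeat_unit", "ref_repeat_count", "length", "read_count"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, config: PipelineConfig | None = None) -> list[VariantRecord]:
    """Read a VCF 4.2 file into one VariantRecord per ALT allele.

    Multi-allelic records are split; per-allele alt counts come from the AD
    field, total depth from DP (falling back to the sum of AD). A record is
    ``quality_pass`` unless its FILTER column carries a name this pipeline
    does not itself assign; pipeline-assigned names round-trip into
    ``filters``.
    """
    config = config or PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"malformed VCF {path}: {exc}") from exc
    with contextlib.closing(vcf):
        sample_names = list(vcf.header.samples)
        line_no = len(str(vcf.header).rstrip("\n").split("\n"))
        for rec in vcf:
            line_no += 1
            try:
                records.extend(_split_record(rec, sample_names, config))
            except (ParseError, ConfigError):
                raise
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(f"malformed VCF record at {path} line {line_no}: {exc}") from exc
    return records


def _split_record(rec, sample_names: list[str], config: PipelineConfig) -> list[VariantRecord]:
    alts = rec.alts or ()
    if not alts:
        return []
    dp, ads = _read_support(rec, sample_names, config)
    af_global = _per_allele_info(rec, config.vcf_global_af_tag, len(alts))
    af_sas = _per_allele_info(rec, config.vcf_sas_af_tag, len(alts))
    gene = _scalar_info(rec, config.vcf_gene_tag)
    conseq = _scalar_info(rec, config.vcf_consequence_tag)
    filter_names = list(rec.filter.keys())
    pipeline_filters = [f for f in filter_names if f in PIPELINE_FILTER_NAMES]
    foreign = [f for f in filter_names if f not in PIPELINE_FILTER_NAMES and f != "PASS"]
    quality_pass = not foreign and "caller_quality" not in pipeline_filters
    out = []
    for i, alt in enumerate(alts):
        out.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=str(alt),
                total_depth=dp,
                alt_count=ads[i],
                pop_af_global=af_global[i],
                pop_af_south_asian=af_sas[i],
                gene=gene,
                consequence=conseq,
                quality_pass=quality_pass,
                filters=list(pipeline_filters),
            )
        )
    return out


def _read_support(rec, sample_names: list[str], config: PipelineConfig) -> tuple[int, list[int]]:
    """Return (total depth, per-ALT alt counts) from FORMAT or INFO fields."""
    ad = dp = None
    if sample_names:
        sample = rec.samples[sample_names[0]]
        ad = sample.get(config.vcf_ad_tag)
        dp = sample.get(config.vcf_depth_tag)
    if ad is None and config.vcf_ad_tag in rec.info:
        ad = rec.info[config.vcf_ad_tag]
    if dp is None and config.vcf_depth_tag in rec.info:
        dp = rec.info[config.vcf_depth_tag]
    if ad is None or all(a is None for a in ad):
        raise ConfigError(
            f"no allele-depth tag {config.vcf_ad_tag!r} at {rec.chrom}:{rec.pos}; "
            "set vcf_ad_tag to the caller's field name"
        )
    ad = [int(a) for a in ad]
    n_alts = len(rec.alts or ())
    if len(ad) != n_alts + 1:
        raise ParseError(
            f"{config.vcf_ad_tag} has {len(ad)} entries for {n_alts} ALT alleles "
            f"at {rec.chrom}:{rec.pos}"
        )
    total = int(dp) if dp is not None else sum(ad)
    return total, ad[1:]


def _per_allele_info(rec, tag: str, n_alts: int) -> list[float | None]:
    if tag not in rec.info:
        return [None] * n_alts
    value = rec.info[tag]
    if not isinstance(value, tuple):
        value = (value,)
    values = [None if v is None else float(v) for v in value]
    if len(values) == 1 and n_alts > 1:
        values = values * n_alts
    if len(values) != n_alts:
        raise ParseError(f"INFO tag {tag} has {len(values)} values for {n_alts} ALT alleles")
    return values


def _scalar_info(rec, tag: str) -> str | None:
    if tag not in rec.info:
        return None
    value = rec.info[tag]
    if isinstance(value, tuple):
        value = value[0]
    return None if value is None else str(value)


def build_vcf_header(
    contigs: list[str], config: PipelineConfig | None = None, sample: str = "TUMOR"
) -> pysam.VariantHeader:
    config = config or PipelineConfig()
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.add_meta(
        "INFO",
        items=[("ID", config.vcf_global_af_tag), ("Number", "A"), ("Type", "Float"),
               ("Description", "Global population allele fraction")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", config.vcf_sas_af_tag), ("Number", "A"), ("Type", "Float"),
               ("Description", "South-Asian population allele fraction")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", config.vcf_gene_tag), ("Number", "1"), ("Type", "String"),
               ("Description", "Gene symbol")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", config.vcf_consequence_tag), ("Number", "1"), ("Type", "String"),
               ("Description", "Coding consequence")],
    )
    for name in PIPELINE_FILTER_NAMES:
        header.filters.add(name, None, None, _FILTER_DESCRIPTIONS[name])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(config.vcf_depth_tag, 1, "Integer", "Total read depth")
    header.formats.add(config.vcf_ad_tag, "R", "Integer", "Allelic depths (ref, alt...)")
    header.add_sample(sample)
    return header


def write_filtered_vcf(
    records: list[VariantRecord],
    path: str | Path,
    config: PipelineConfig | None = None,
    sample: str = "TUMOR",
) -> None:
    """Write records to VCF 4.2 with FILTER reflecting the applied filters.

    Reading the file back with :func:`read_vcf` reproduces every field
    (population AFs to float precision).
    """
    config = config or PipelineConfig()
    contigs = list(dict.fromkeys(r.chrom for r in records))
    header = build_vcf_header(contigs or ["chr1"], config, sample)
    path = Path(path)
    try:
        out = pysam.VariantFile(str(path), "w", header=header)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    with contextlib.closing(out):
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            if r.pop_af_global is not None:
                rec.info[config.vcf_global_af_tag] = (r.pop_af_global,)
            if r.pop_af_south_asian is not None:
                rec.info[config.vcf_sas_af_tag] = (r.pop_af_south_asian,)
            if r.gene is not None:
                rec.info[config.vcf_gene_tag] = r.gene
            if r.consequence is not None:
                rec.info[config.vcf_consequence_tag] = r.consequence
            labels = list(r.filters)
            if not r.quality_pass and "caller_quality" not in labels:
                labels.append("caller_quality")
            if labels:
                for name in labels:
                    rec.filter.add(name)
            else:
                rec.filter.add("PASS")
            s = rec.samples[sample]
            s["GT"] = (0, 1)
            s[config.vcf_depth_tag] = r.total_depth
            s[config.vcf_ad_tag] = (r.total_depth - r.alt_count, r.alt_count)
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path} lacks required columns: {', '.join(missing)}")
    return df


def read_cnv_table(path: str | Path) -> list[CopyNumberCall]:
    """Read gene-level copy-number calls (columns: gene, copy_number[, chrom, start, end])."""
    df = _read_tsv(path, ["gene", "copy_number"])
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CopyNumberCall(
                gene=str(row.gene),
                copy_number=float(row.copy_number),
                chrom=str(getattr(row, "chrom", "")),
                start=int(getattr(row, "start", 0)),
                end=int(getattr(row, "end", 0)),
            )
        )
    return calls


def write_cnv_table(calls: list[CopyNumberCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "copy_number": [c.copy_number for c in calls],
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fusion_table(path: str | Path) -> list[FusionCall]:
    df = _read_tsv(path, ["gene_5p", "gene_3p", "junction_reads", "confidence", "orf_status"])
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            FusionCall(
                gene_5p=str(row.gene_5p),
                gene_3p=str(row.gene_3p),
                junction_reads=int(row.junction_reads),
                confidence=str(row.confidence),
                orf_status=str(row.orf_status),
                chrom_5p=str(getattr(row, "chrom_5p", "")),
                pos_5p=int(getattr(row, "pos_5p", 0)),
                chrom_3p=str(getattr(row, "chrom_3p", "")),
                pos_3p=int(getattr(row, "pos_3p", 0)),
            )
        )
    return calls


def write_fusion_table(calls: list[FusionCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_5p": c.gene_5p, "gene_3p": c.gene_3p,
                "chrom_5p": c.chrom_5p, "pos_5p": c.pos_5p,
                "chrom_3p": c.chrom_3p, "pos_3p": c.pos_3p,
                "junction_reads": c.junction_reads,
                "confidence": c.confidence, "orf_status": c.orf_status,
            }
            for c in calls
        ],
        columns=FUSION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_msi_profiles(path: str | Path) -> list[MicrosatelliteProfile]:
    """Read one sample's microsatellite histograms (one row per observed length)."""
    df = _read_tsv(path, MSI_COLUMNS)
    profiles = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        first = grp.iloc[0]
        profiles.append(
            MicrosatelliteProfile(
                locus_id=str(locus_id),
                chrom=str(first["chrom"]),
                pos=int(first["pos"]),
                repeat_unit=str(first["repeat_unit"]),
                ref_repeat_count=int(first["ref_repeat_count"]),
                length_histogram={
                    int(l): int(c) for l, c in zip(grp["length"], grp["read_count"])
                },
            )
        )
    return profiles


def write_msi_profiles(profiles: list[MicrosatelliteProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for length in sorted(p.length_histogram):
            rows.append(
                {
                    "locus_id": p.locus_id, "chrom": p.chrom, "pos": p.pos,
                    "repeat_unit": p.repeat_unit, "ref_repeat_count": p.ref_repeat_count,
                    "length": length, "read_count": p.length_histogram[length],
                }
            )
    pd.DataFrame(rows, columns=MSI_COLUMNS).to_csv(path, sep="\t", index=False)


def read_msi_baseline_dir(directory: str | Path) -> list[list[MicrosatelliteProfile]]:
    """Read one histogram TSV per normal from a directory (sorted by filename)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise ParseError(f"no .tsv normal profiles found in {directory}")
    return [read_msi_profiles(p) for p in paths]


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Read a per-base depth track (columns: chrom, pos, depth; pos 1-based)."""
    df = _read_tsv(path, ["chrom", "pos", "depth"])
    if (df["depth"] < 0).any():
        raise ParseError(f"negative depth values in {path}")
    return df


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read target regions from BED (0-based half-open intervals)."""
    regions = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path} line {i}: BED needs chrom, start, end")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path} line {i}: non-integer BED coordinates") from exc
        if start > end:
            raise ParseError(f"{path} line {i}: start > end")
        regions.append((parts[0], start, end))
    return regions


def write_bed(regions: list[tuple[str, int, int]], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in regions)
    )


# ---------------------------------------------------------------------------
# Panel-of-normals site baseline
# ---------------------------------------------------------------------------

def read_baseline_sites(path: str | Path) -> BaselineModel:
    """Read a panel-of-normals site table.

    Format: a ``#n_normals=<N>`` comment line followed by a TSV with columns
    chrom, pos, ref, alt, occurrence.
    """
    path = Path(path)
    n_normals = None
    for line in path.read_text().splitlines():
        if line.startswith("#n_normals="):
            n_normals = int(line.split("=", 1)[1])
            break
    if n_normals is None:
        raise ParseError(f"{path} lacks the '#n_normals=<N>' header line")
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt", "occurrence"])
    occ: dict[SiteKey, int] = {}
    for row in df.itertuples(index=False):
        occ[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = int(row.occurrence)
    return BaselineModel(n_normals=n_normals, site_occurrence=occ)


def write_baseline_sites(baseline: BaselineModel, path: str | Path) -> None:
    lines = [f"#n_normals={baseline.n_normals}", "chrom\tpos\tref\talt\toccurrence"]
    for (chrom, pos, ref, alt), occ in sorted(baseline.site_occurrence.items()):
        lines.append(f"{chrom}\t{pos}\t{ref}\t{alt}\t{occ}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Known fusion pairs and labeled feature sets
# ---------------------------------------------------------------------------

def read_known_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Read a curated ordered (gene_5p, gene_3p) pair list from TSV."""
    df = _read_tsv(path, ["gene_5p", "gene_3p"])
    return {(str(a), str(b)) for a, b in zip(df["gene_5p"], df["gene_3p"])}


def read_feature_set(path: str | Path) -> set[tuple]:
    """Read a labeled feature set for concordance (variant keys or fusion pairs)."""
    df = _read_tsv(path, [])
    cols = list(df.columns)
    if {"chrom", "pos", "ref", "alt"}.issubset(cols):
        return {
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples(index=False)
        }
    if {"gene_5p", "gene_3p"}.issubset(cols):
        return {(str(r.gene_5p), str(r.gene_3p)) for r in df.itertuples(index=False)}
    raise ParseError(
        f"{path}: feature set needs chrom/pos/ref/alt or gene_5p/gene_3p columns"
    )
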