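"""End-to-end pipeline run and the consolidated biomarker report.

The report is a machine-readable aggregation of every stage's output: a QC
block, the PASS variant list with filter provenance, amplified copy-number
calls, retained fusions, the TMB cascade counts and the MSI score. Every
threshold in force is echoed into the report header so a reviewer can audit
exactly which configuration produced each verdict. Inputs that were not
provided yield explicit ``"not_assessed"`` blocks rather than silently
vanishing.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .config import PipelineConfig
from .errors import ExomarkError
from .filters import apply_reportability_filter, call_amplifications
from .fusions import annotate_known_fusions, prioritize_fusions
from .msi import build_msi_baseline, compute_msi_score
from .qc import coverage_summary, evaluate_sample_qc
from .tmb import compute_tmb

NOT_ASSESSED = {"status": "not_assessed"}


@contextmanager
def _stage(name: str):
    """Re-raise any stage failure with the stage name attached."""
    try:
        yield
    except ExomarkError as exc:
        raise type(exc)(f"stage '{name}': {exc}") from exc


def _variant_row(record) -> dict:
    return {
        "chrom": record.chrom,
        "pos": record.pos,
        "ref": record.ref,
        "alt": record.alt,
        "variant_class": record.variant_class,
        "total_depth": record.total_depth,
        "alt_count": record.alt_count,
        "vaf": round(record.vaf, 6),
        "gene": record.gene,
        "consequence": record.consequence,
        "filters": sorted(record.filters),
    }


def run_pipeline(
    vcf_path: str | Path,
    config: PipelineConfig | None = None,
    cnv_path: str | Path | None = None,
    fusion_path: str | Path | None = None,
    known_pairs_path: str | Path | None = None,
    msi_sample_path: str | Path | None = None,
    msi_baseline_dir: str | Path | None = None,
    baseline_sites_path: str | Path | None = None,
    depth_track_path: str | Path | None = None,
    target_bed_path: str | Path | None = None,
    metadata: dict | str | Path | None = None,
) -> dict:
    """Run every applicable stage on one sample and return the biomarker report.

    Only the VCF is mandatory. The return value is a plain JSON-serializable
    dict; :func:`write_report` persists it deterministically.
    """
    if vcf_path is None:
        raise ValueError("a small-variant VCF is required")
    config = config or PipelineConfig()
    report: dict = {"config": config.as_dict()}

    # --- QC ---
    if isinstance(metadata, (str, Path)):
        metadata = yaml.safe_load(Path(metadata).read_text()) or {}
    metrics = dict(metadata or {})
    if depth_track_path is not None and target_bed_path is not None:
        with _stage("coverage"):
            depth_df = io.read_depth_track(depth_track_path)
            regions = io.read_bed(target_bed_path)
            mean_depth, on_target, uniformity = coverage_summary(depth_df, regions, config)
        metrics.update(
            mean_depth=mean_depth,
            on_target_fraction=on_target,
            uniformity_fraction=uniformity,
        )
        report["coverage"] = {
            "mean_depth": round(mean_depth, 4),
            "on_target_fraction": round(on_target, 6),
            "uniformity_fraction": round(uniformity, 6),
        }
    else:
        report["coverage"] = dict(NOT_ASSESSED)
    if metrics:
        with _stage("sample_qc"):
            report["qc"] = evaluate_sample_qc(metrics, config).as_dict()
    else:
        report["qc"] = dict(NOT_ASSESSED)

    # --- small variants ---
    with _stage("variant_filter"):
        records = io.read_vcf(vcf_path, config)
        labeled = apply_reportability_filter(records, config)
    passing = [r for r in labeled if r.is_pass]
    reason_counts: dict[str, int] = {}
    for r in labeled:
        for f in r.filters:
            reason_counts[f] = reason_counts.get(f, 0) + 1
    report["variants"] = {
        "n_input": len(labeled),
        "n_pass": len(passing),
        "filter_counts": dict(sorted(reason_counts.items())),
        "pass_variants": [_variant_row(r) for r in passing],
    }

    # --- TMB ---
    with _stage("tmb"):
        baseline = (
            io.read_baseline_sites(baseline_sites_path)
            if baseline_sites_path is not None
            else None
        )
        tmb_result = compute_tmb(passing, config, baseline)
    report["tmb"] = tmb_result.as_dict()

    # --- CNA ---
    if cnv_path is not None:
        with _stage("copy_number"):
            cnv_calls = call_amplifications(io.read_cnv_table(cnv_path), config)
        report["copy_number"] = {
            "n_input": len(cnv_calls),
            "amplified": [
                {"gene": c.gene, "copy_number": c.copy_number}
                for c in cnv_calls
                if c.amplified
            ],
        }
    else:
        report["copy_number"] = dict(NOT_ASSESSED)

    # --- fusions ---
    if fusion_path is not None:
        with _stage("fusions"):
            calls = io.read_fusion_table(fusion_path)
            retained, dropped = prioritize_fusions(calls, config)
            if known_pairs_path is not None:
                known = io.read_known_pairs(known_pairs_path)
                retained = annotate_known_fusions(retained, known)
        report["fusions"] = {
            "n_input": len(calls),
            "n_retained": len(retained),
            "retained": [
                {
                    "gene_5p": c.gene_5p,
                    "gene_3p": c.gene_3p,
                    "junction_reads": c.junction_reads,
                    "confidence": c.confidence,
                    "orf_status": c.orf_status,
                    "known": c.known,
                }
                for c in retained
            ],
            "dropped": [
                {"gene_5p": c.gene_5p, "gene_3p": c.gene_3p,
                 "reasons": list(c.drop_reasons)}
                for c in dropped
            ],
        }
    else:
        report["fusions"] = dict(NOT_ASSESSED)

    # --- MSI ---
    if msi_sample_path is not None and msi_baseline_dir is not None:
        with _stage("msi"):
            sample_profiles = io.read_msi_profiles(msi_sample_path)
            normal_profiles = io.read_msi_baseline_dir(msi_baseline_dir)
            msi_baseline = build_msi_baseline(normal_profiles)
            msi_result = compute_msi_score(sample_profiles, msi_baseline, config)
        report["msi"] = msi_result.as_dict()
    else:
        report["msi"] = dict(NOT_ASSESSED)

    report["_labeled_records"] = labeled  # internal, stripped before writing
    return report


def write_report(report: dict, out_dir: str | Path, config: PipelineConfig | None = None) -> None:
    """Persist a report deterministically: JSON summary, PASS-variant TSV,
    and the fully labeled VCF."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labeled = report.pop("_labeled_records", None)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    rows = report.get("variants", {}).get("pass_variants", [])
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "variant_class", "total_depth",
            "alt_count", "vaf", "gene", "consequence", "filters",
        ],
    )
    if len(df):
        df["filters"] = df["filters"].map(lambda fs: ";".join(fs) if fs else "PASS")
    df.to_csv(out_dir / "pass_variants.tsv", sep="\t", index=False)
    if labeled is not None:
        io.write_filtered_vcf(labeled, out_dir / "filtered.vcf", config)
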