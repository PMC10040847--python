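"""Sample/sequencing QC gates and clinical-validation statistics.

Specimen and library gates mirror wet-lab acceptance rules: tumor surface
area >= 5 mm^2, tumor content >= 10%, library concentration >= 10 nM with a
fragment peak near 300 bp, and sequencing-level gates of mean depth >= 200x,
on-target fraction above 80% and uniformity above 90% (uniformity = fraction
of target bases covered at >= 0.2x the mean target depth, the common
industry definition).

Validation statistics (sensitivity, specificity, accuracy, reproducibility)
compare observed call sets with an orthogonal truth set. Specificity needs
an explicit negative universe — sites that were assayed and are known
wild-type — because "true negatives" are undefined without it.
"""

from __future__ import annotations

from collections.abc import Collection, Hashable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .errors import DomainError
from .models import ConcordanceReport, SampleQCResult

#: metric keys accepted by evaluate_sample_qc, mapped to check names
METRIC_KEYS = {
    "tumor_content": "tumor_content",
    "tumor_area_mm2": "tumor_area",
    "library_nM": "library_concentration",
    "library_peak_bp": "library_peak",
    "mean_depth": "mean_depth",
    "on_target_fraction": "on_target",
    "uniformity_fraction": "uniformity",
}


def evaluate_sample_qc(
    metrics: Mapping[str, float | None], config: PipelineConfig | None = None
) -> SampleQCResult:
    """Check measured specimen/library/sequencing metrics against the gates.

    Metrics that are absent or ``None`` are reported as not-measured
    (``None``) and skipped in the overall verdict. Negative values raise
    :class:`DomainError`. Boundary conventions follow the validated assay:
    >= for specimen and library gates and mean depth, strict > for on-target
    and uniformity fractions.
    """
    config = config or PipelineConfig()
    m = {k: metrics.get(k) for k in METRIC_KEYS}
    for key, value in m.items():
        if value is not None and value < 0:
            raise DomainError(f"QC metric {key} cannot be negative, got {value}")

    def gate(value, predicate):
        return None if value is None else bool(predicate(value))

    checks = {
        "tumor_content": gate(m["tumor_content"], lambda v: v >= config.min_tumor_content),
        "tumor_area": gate(m["tumor_area_mm2"], lambda v: v >= config.min_tumor_area_mm2),
        "library_concentration": gate(m["library_nM"], lambda v: v >= config.min_library_nM),
        "library_peak": gate(
            m["library_peak_bp"],
            lambda v: abs(v - config.library_peak_bp) <= config.library_peak_tolerance_bp,
        ),
        "mean_depth": gate(m["mean_depth"], lambda v: v >= config.min_mean_depth),
        "on_target": gate(
            m["on_target_fraction"], lambda v: v > config.min_on_target_fraction
        ),
        "uniformity": gate(
            m["uniformity_fraction"], lambda v: v > config.min_uniformity_fraction
        ),
    }
    return SampleQCResult(checks=checks)


def coverage_summary(
    depth_track: pd.DataFrame,
    target_regions: list[tuple[str, int, int]],
    config: PipelineConfig | None = None,
) -> tuple[float, float, float]:
    """Summarise a per-base depth track over a target BED.

    Returns (mean target depth, on-target fraction of aligned bases,
    uniformity). Target bases absent from the track count as depth 0; the
    on-target fraction is depth-weighted (aligned bases on target over all
    aligned bases).
    """
    config = config or PipelineConfig()
    target_positions: set[tuple[str, int]] = set()
    for chrom, start, end in target_regions:
        # BED half-open 0-based -> 1-based positions start+1 .. end
        target_positions.update((chrom, p) for p in range(start + 1, end + 1))
    if not target_positions:
        raise DomainError("target region is empty")
    depth_map: dict[tuple[str, int], float] = {}
    for chrom, pos, depth in zip(
        depth_track["chrom"], depth_track["pos"], depth_track["depth"]
    ):
        key = (str(chrom), int(pos))
        depth_map[key] = depth_map.get(key, 0.0) + float(depth)
    total_aligned = sum(depth_map.values())
    on_target_depth = sum(d for k, d in depth_map.items() if k in target_positions)
    target_depths = [depth_map.get(k, 0.0) for k in target_positions]
    mean_depth = sum(target_depths) / len(target_depths)
    on_target_fraction = on_target_depth / total_aligned if total_aligned > 0 else 0.0
    floor = config.uniformity_depth_fraction * mean_depth
    uniform = sum(1 for d in target_depths if d >= floor)
    uniformity = uniform / len(target_depths)
    return mean_depth, on_target_fraction, uniformity


def concordance_metrics(
    truth_positives: Collection[Hashable],
    truth_negatives: Collection[Hashable],
    observed: Collection[Hashable],
) -> ConcordanceReport:
    """Confusion counts and statistics over an explicit assayed universe.

    Features are compared as sets (duplicates collapse); observed features
    outside the truth universe are ignored — they were not assayed against
    the orthogonal method, so no truth state exists for them.
    """
    pos, neg, obs = set(truth_positives), set(truth_negatives), set(observed)
    overlap = pos & neg
    if overlap:
        raise DomainError(
            f"{len(overlap)} features are both truth-positive and truth-negative, "
            f"e.g. {sorted(overlap, key=repr)[:3]}"
        )
    tp = len(pos & obs)
    fn = len(pos - obs)
    fp = len(neg & obs)
    tn = len(neg - obs)
    return ConcordanceReport(tp=tp, fp=fp, tn=tn, fn=fn)


def reproducibility(
    truth_features: Collection[Hashable],
    replicate_call_sets: Sequence[Collection[Hashable]],
) -> float:
    """Percentage of truth features detected in every replicate."""
    truth = set(truth_features)
    if not truth:
        raise DomainError("reproducibility is undefined for an empty truth set")
    if len(replicate_call_sets) < 2:
        raise DomainError("reproducibility needs >= 2 replicates")
    replicates = [set(r) for r in replicate_call_sets]
    in_all = {f for f in truth if all(f in rep for rep in replicates)}
    return 100.0 * len(in_all) / len(truth)
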