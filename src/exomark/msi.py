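"""Microsatellite-instability scoring against a panel-of-normals baseline.

Mismatch-repair deficiency lets replication slippage accumulate at
microsatellites, shifting sequencing reads away from the reference repeat
length. For each locus we summarise a sample by its *shift fraction* — the
fraction of reads whose repeat length differs from the reference count —
and compare it with the distribution of shift fractions observed across a
panel of healthy blood normals (which share the PCR stutter process). A
locus with enough coverage is unstable when its shift fraction exceeds the
baseline mean by more than k standard deviations (k = 3 by default, with
the sd floored at 0.01 so a degenerate panel cannot flag ordinary stutter).

The sample-level MSI score is the percentage of evaluated loci that are
unstable; at or above 15% the sample is MSI-High, otherwise MSS.
"""

from __future__ import annotations

import statistics

from .config import PipelineConfig
from .errors import ConfigError, DomainError
from .models import BaselineModel, MicrosatelliteProfile, MSIResult

UNSTABLE, STABLE, NOT_EVALUATED = "unstable", "stable", "not_evaluated"


def shift_fraction(profile: MicrosatelliteProfile) -> float:
    """Fraction of reads with repeat length different from the reference count."""
    total = profile.total_reads
    if total == 0:
        raise DomainError(f"locus {profile.locus_id}: empty histogram")
    shifted = sum(
        count
        for length, count in profile.length_histogram.items()
        if length != profile.ref_repeat_count
    )
    return shifted / total


def build_msi_baseline(
    normal_profiles: list[list[MicrosatelliteProfile]],
) -> BaselineModel:
    """Summarise per-locus shift fractions across a panel of >= 2 normals.

    Only loci profiled in every normal enter the baseline; mean and
    *population* standard deviation are stored per locus.
    """
    if len(normal_profiles) < 2:
        raise ConfigError(
            f"MSI baseline needs >= 2 normals (got {len(normal_profiles)}); "
            "sd is undefined otherwise"
        )
    per_normal = [{p.locus_id: p for p in profiles} for profiles in normal_profiles]
    shared = set(per_normal[0])
    for d in per_normal[1:]:
        shared &= set(d)
    msi_baseline = {}
    for locus_id in sorted(shared):
        fractions = [shift_fraction(d[locus_id]) for d in per_normal]
        msi_baseline[locus_id] = (
            statistics.fmean(fractions),
            statistics.pstdev(fractions),
        )
    return BaselineModel(n_normals=len(normal_profiles), msi_baseline=msi_baseline)


def score_locus(
    profile: MicrosatelliteProfile,
    baseline_entry: tuple[float, float],
    config: PipelineConfig | None = None,
) -> str:
    """Score one locus: 'unstable', 'stable', or 'not_evaluated' (low coverage)."""
    config = config or PipelineConfig()
    if baseline_entry is None:
        raise LookupError(f"no baseline entry for locus {profile.locus_id}")
    if profile.total_reads < config.msi_min_locus_coverage:
        return NOT_EVALUATED
    mean, sd = baseline_entry
    threshold = mean + config.msi_shift_sd_multiplier * max(sd, config.msi_sd_floor)
    return UNSTABLE if shift_fraction(profile) > threshold else STABLE


def compute_msi_score(
    sample_profiles: list[MicrosatelliteProfile],
    baseline: BaselineModel,
    config: PipelineConfig | None = None,
) -> MSIResult:
    """Score every locus with a baseline entry and summarise as percent unstable.

    Loci absent from the baseline or under the coverage floor are skipped.
    With zero evaluable loci the result is 'Not-Assessable' rather than an
    error — a thin FFPE sample must still produce a report.
    """
    config = config or PipelineConfig()
    n_evaluated = n_unstable = 0
    for profile in sample_profiles:
        entry = baseline.msi_baseline.get(profile.locus_id)
        if entry is None:
            continue
        status = score_locus(profile, entry, config)
        if status == NOT_EVALUATED:
            continue
        n_evaluated += 1
        if status == UNSTABLE:
            n_unstable += 1
    if n_evaluated == 0:
        return MSIResult(0, 0, None, "Not-Assessable")
    score = 100.0 * n_unstable / n_evaluated
    classification = "MSI-High" if score >= config.msi_high_cutoff else "MSS"
    return MSIResult(n_evaluated, n_unstable, score, classification)
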