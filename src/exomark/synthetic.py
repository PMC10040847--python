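"""Seeded generators for every input the pipeline consumes, with truth labels.

The generators emulate the statistical structure of a tumor-only exome run
at the assay's operating point (about 200x mean depth):

* germline variants segregate at population frequency, with heterozygous
  calls at ~50% VAF and homozygous calls at ~100%;
* somatic variants have expected VAF ``purity * clonal_fraction / 2`` with
  no population-frequency annotation;
* observed alt counts are binomial draws at Poisson-distributed depth
  (variants are simulated at the pileup level, not the read level — no
  sequencing-error or FFPE-artifact model);
* microsatellite loci draw a non-reference repeat-length read fraction
  around a stable (stutter-only) or unstable shift level, and panel normals
  are always stable;
* fusion tables mix reportable calls with low-support and lost-ORF decoys.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .io import write_filtered_vcf
from .models import BaselineModel, FusionCall, MicrosatelliteProfile, VariantRecord

_BASES = np.array(list("ACGT"))


def _draw_positions(rng: np.random.Generator, n: int, region_bases: int) -> np.ndarray:
    """n distinct 1-based positions in [1, region_bases]."""
    if n > region_bases:
        raise DomainError(f"cannot place {n} variants in {region_bases} bases")
    positions: set[int] = set()
    while len(positions) < n:
        draw = rng.integers(1, region_bases + 1, size=n - len(positions))
        positions.update(int(p) for p in draw)
    return np.array(sorted(positions))


def _draw_alleles(rng: np.random.Generator, indel_fraction: float) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    u = rng.random()
    if u < indel_fraction / 2:  # insertion
        ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        return ref, ref + ins
    if u < indel_fraction:  # short deletion
        tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        return ref + tail, ref
    alt = str(rng.choice(_BASES[_BASES != ref]))
    return ref, alt


def simulate_tumor_only_vcf(
    n_common_germline: int = 200,
    n_rare_germline: int = 100,
    n_somatic: int = 300,
    purity: float = 0.5,
    mean_depth: float = 200.0,
    region_size_mb: float = 30.0,
    seed: int = 0,
    indel_fraction: float = 0.1,
    chrom: str = "chr1",
    out_vcf: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Simulate an annotated tumor-only small-variant call set with truth labels.

    Common germline variants carry population AF ~ Uniform(0.02, 0.5) (all
    above the 1% polymorphism rule); rare germline carry AF < 0.001 and a
    heterozygous VAF; somatic variants carry no population annotation and
    expected VAF ``purity * Uniform(0.2, 1.0) / 2``. Returns the records and
    a truth table labeling each site germline/somatic; optionally writes a
    VCF and a truth TSV.
    """
    if not 0.0 < purity <= 1.0:
        raise DomainError(f"purity must be in (0, 1], got {purity}")
    if mean_depth < 1:
        raise DomainError(f"mean_depth must be >= 1, got {mean_depth}")
    for name, n in (
        ("n_common_germline", n_common_germline),
        ("n_rare_germline", n_rare_germline),
        ("n_somatic", n_somatic),
    ):
        if n < 0:
            raise DomainError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    n_total = n_common_germline + n_rare_germline + n_somatic
    region_bases = int(region_size_mb * 1e6)
    positions = _draw_positions(rng, n_total, region_bases)
    origins = np.array(
        ["common_germline"] * n_common_germline
        + ["rare_germline"] * n_rare_germline
        + ["somatic"] * n_somatic
    )
    rng.shuffle(origins)

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    for i, (pos, origin) in enumerate(zip(positions, origins)):
        ref, alt = _draw_alleles(rng, indel_fraction)
        if origin == "common_germline":
            af = float(rng.uniform(0.02, 0.5))
            hom = rng.random() < af / (2.0 - af)  # P(hom | carrier) under HWE
            expected_vaf = 1.0 if hom else 0.5
            af_global = af
            af_sas = float(min(1.0, af * rng.uniform(0.5, 1.5)))
        elif origin == "rare_germline":
            af = float(rng.uniform(1e-5, 1e-3))
            expected_vaf = 0.5
            af_global = af
            af_sas = float(min(1.0, af * rng.uniform(0.5, 1.5)))
        else:  # somatic
            clonal = float(rng.uniform(0.2, 1.0))
            expected_vaf = purity * clonal / 2.0
            af_global = af_sas = None
        depth = max(1, int(rng.poisson(mean_depth)))
        alt_count = int(rng.binomial(depth, min(1.0, expected_vaf)))
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                total_depth=depth,
                alt_count=alt_count,
                pop_af_global=af_global,
                pop_af_south_asian=af_sas,
                gene=f"GENE{i % 500:04d}",
                consequence="missense_variant",
                quality_pass=True,
            )
        )
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "origin": origin,
                "expected_vaf": expected_vaf,
                "pop_af_global": af_global,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "origin", "expected_vaf", "pop_af_global"],
    )
    if out_vcf is not None:
        write_filtered_vcf(records, out_vcf)
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return records, truth


def simulate_panel_baseline(
    truth: pd.DataFrame, n_normals: int = 10, seed: int = 0
) -> BaselineModel:
    """Simulate panel-of-normals site occurrences consistent with a truth table.

    Each germline site is carried by ``Binomial(n_normals, carrier_freq)``
    normals (carrier frequency from the site's population AF under
    Hardy-Weinberg, floored at one carrier — the sample itself proves the
    allele exists); somatic sites never enter the panel.
    """
    if n_normals < 2:
        raise ConfigError("panel baseline needs >= 2 normals")
    rng = np.random.default_rng(seed)
    occurrence = {}
    for row in truth.itertuples(index=False):
        if row.origin == "somatic":
            continue
        af = row.pop_af_global if row.pop_af_global is not None else 0.0
        carrier_freq = 2 * af * (1 - af) + af * af
        occ = int(rng.binomial(n_normals, min(1.0, carrier_freq)))
        occurrence[(row.chrom, int(row.pos), row.ref, row.alt)] = max(1, occ)
    return BaselineModel(n_normals=n_normals, site_occurrence=occurrence)


def simulate_msi_profiles(
    n_loci: int = 30,
    fraction_unstable: float = 0.0,
    reads_per_locus: float = 100.0,
    stable_shift: float = 0.05,
    unstable_shift: float = 0.35,
    n_normals: int = 5,
    seed: int = 0,
) -> tuple[list[MicrosatelliteProfile], list[list[MicrosatelliteProfile]], pd.DataFrame]:
    """Simulate a tumor sample's microsatellite histograms plus a stable normal panel.

    Stable loci (and all normal-panel loci) draw their non-reference-length
    read fraction ``Binomial(reads, stable_shift)``; unstable loci use
    ``unstable_shift``. Shifted reads land on repeat lengths ref-1/ref-2/ref+1
    with probabilities 0.5/0.3/0.2 (deletion slippage dominates). Returns
    (sample profiles, per-normal profile lists, truth table).
    """
    if not 0.0 <= fraction_unstable <= 1.0:
        raise DomainError(f"fraction_unstable must be in [0,1], got {fraction_unstable}")
    if reads_per_locus < 1:
        raise DomainError("reads_per_locus must be >= 1")
    if unstable_shift <= stable_shift:
        raise ConfigError(
            f"unstable_shift ({unstable_shift}) must exceed stable_shift ({stable_shift})"
        )
    rng = np.random.default_rng(seed)
    n_unstable = int(round(n_loci * fraction_unstable))
    unstable_flags = np.zeros(n_loci, dtype=bool)
    unstable_flags[:n_unstable] = True
    rng.shuffle(unstable_flags)

    loci = []
    for i in range(n_loci):
        loci.append(
            {
                "locus_id": f"MS{i:04d}",
                "chrom": f"chr{(i % 22) + 1}",
                "pos": int(rng.integers(1, 10_000_000)),
                "repeat_unit": str(rng.choice(["A", "T", "AT", "CA"])),
                "ref_repeat_count": int(rng.integers(10, 26)),
            }
        )

    def draw_profile(locus: dict, shift_level: float) -> MicrosatelliteProfile:
        total = max(1, int(rng.poisson(reads_per_locus)))
        shifted = int(rng.binomial(total, shift_level))
        ref_len = locus["ref_repeat_count"]
        hist = {ref_len: total - shifted}
        if shifted:
            parts = rng.multinomial(shifted, [0.5, 0.3, 0.2])
            for offset, count in zip((-1, -2, 1), parts):
                if count:
                    hist[ref_len + offset] = hist.get(ref_len + offset, 0) + int(count)
        return MicrosatelliteProfile(length_histogram=hist, **locus)

    sample = [
        draw_profile(locus, unstable_shift if flag else stable_shift)
        for locus, flag in zip(loci, unstable_flags)
    ]
    normals = [
        [draw_profile(locus, stable_shift) for locus in loci] for _ in range(n_normals)
    ]
    truth = pd.DataFrame(
        {
            "locus_id": [l["locus_id"] for l in loci],
            "unstable": unstable_flags,
        }
    )
    return sample, normals, truth


_FUSION_GENE_POOL = [
    "ALK", "ROS1", "RET", "NTRK1", "NTRK2", "NTRK3", "EWSR1", "ATF1",
    "FGFR2", "FGFR3", "EML4", "KIF5B", "CD74", "TPM3", "ETV6", "BCR",
    "ABL1", "TMPRSS2", "ERG", "PAX8",
]


def simulate_fusion_table(
    n_true: int = 3,
    n_low_support: int = 2,
    n_orf_lost: int = 1,
    seed: int = 0,
) -> tuple[list[FusionCall], pd.DataFrame]:
    """Simulate a fusion call table with truth labels for the prioritizer.

    True calls are high-confidence with 5-100 junction reads and a retained
    ORF; low-support decoys have 1-4 reads; lost-ORF decoys have adequate
    support but a broken reading frame. Truth marks which calls the
    prioritizer should retain.
    """
    for name, n in (("n_true", n_true), ("n_low_support", n_low_support),
                    ("n_orf_lost", n_orf_lost)):
        if n < 0:
            raise DomainError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    calls: list[FusionCall] = []
    truth_rows: list[dict] = []

    def make(junction_reads: int, orf_status: str, expected: bool) -> None:
        g5, g3 = rng.choice(_FUSION_GENE_POOL, size=2, replace=False)
        calls.append(
            FusionCall(
                gene_5p=str(g5),
                gene_3p=str(g3),
                junction_reads=junction_reads,
                confidence="high",
                orf_status=orf_status,
                chrom_5p=f"chr{int(rng.integers(1, 23))}",
                pos_5p=int(rng.integers(1, 10_000_000)),
                chrom_3p=f"chr{int(rng.integers(1, 23))}",
                pos_3p=int(rng.integers(1, 10_000_000)),
            )
        )
        truth_rows.append(
            {"gene_5p": str(g5), "gene_3p": str(g3),
             "junction_reads": junction_reads, "expected_retained": expected}
        )

    for _ in range(n_true):
        make(int(rng.integers(5, 101)), "retained", True)
    for _ in range(n_low_support):
        make(int(rng.integers(1, 5)), "retained", False)
    for _ in range(n_orf_lost):
        make(int(rng.integers(5, 101)), "lost", False)
    order = rng.permutation(len(calls))
    calls = [calls[i] for i in order]
    truth = pd.DataFrame(
        [truth_rows[i] for i in order],
        columns=["gene_5p", "gene_3p", "junction_reads", "expected_retained"],
    )
    return calls, truth


def simulate_depth_track(
    target_bases: int = 2000,
    mean_depth: float = 220.0,
    off_target_bases: int = 400,
    off_target_depth: float = 50.0,
    chrom: str = "chr1",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, int, int]]]:
    """Simulate a per-base depth track and its target BED region.

    Target bases draw Poisson(mean_depth); a downstream off-target flank
    draws Poisson(off_target_depth), so the on-target fraction is below 1.
    """
    rng = np.random.default_rng(seed)
    target_depths = rng.poisson(mean_depth, size=target_bases)
    off_depths = rng.poisson(off_target_depth, size=off_target_bases)
    rows = {
        "chrom": [chrom] * (target_bases + off_target_bases),
        "pos": list(range(1, target_bases + 1))
        + list(range(target_bases + 1001, target_bases + 1001 + off_target_bases)),
        "depth": [int(d) for d in target_depths] + [int(d) for d in off_depths],
    }
    regions = [(chrom, 0, target_bases)]
    return pd.DataFrame(rows), regions
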