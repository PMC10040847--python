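# Methods

This note documents the models, rules and parameters behind `exomark`, the
assumptions of the synthetic-data generators, and the design choices made
where the underlying procedure was genuinely open.

## Scope and data flow

`exomark` starts where primary analysis ends. An upstream aligner/caller
produces an annotated VCF of small variants, a gene-level copy-number
table, an RNA fusion table, per-locus microsatellite repeat-length
histograms, and a per-base depth track. The engine applies the clinical
filtering/scoring layer and emits biomarker verdicts. Alignment, variant
calling, and annotation-database lookups are out of scope; population
frequencies and gene annotations are consumed as VCF INFO fields.

## Small-variant reportability

A call is reportable iff all of:

1. the caller marked it good quality (any FILTER entry that this pipeline
   did not itself assign counts as a caller-quality failure);
2. `alt_count >= min_alt_reads` (default 10);
3. `VAF >= LOD` for its class — `lod_snv = 0.05` for SNV/MNV,
   `lod_indel = 0.10` for INS/DEL;
4. for deletions, deleted length `< max_deletion_bp` (default 20): longer
   deletions are not reliably recoverable from fragmented FFPE DNA with
   short-read hybrid capture.

The LOD is enforced on the observed VAF *in addition to* the read-count
floor so that low-depth sites cannot pass on count alone; the two rules are
consistent at the assay's operating point, since 10 reads at 200× is
exactly 5% (`min_detectable_vaf(200, 10) = 0.05`). Failed records are
labeled with every failed criterion, making filtering idempotent on its
PASS output and auditable on the rest.

Insertions use the INDEL LOD. Multi-allelic VCF records are split into one
record per ALT allele before filtering so per-allele thresholds apply.

## Copy number and fusions

Amplification is a simple gene-level threshold: `copy_number >= 6`,
*inclusive*. (Assay documentation varies between "≥6" and ">6"; the
clinical-validation table's inclusive form is used and the cutoff is
configurable.)

Fusions are retained when confidence is at least `high`, at least 5 unique
junction-spanning reads support the call, and the open reading frame is not
lost. ORF-`unknown` calls are retained by default — only demonstrated loss
of frame excludes a call — with a configurable strict mode
(`fusion_drop_unknown_orf`) for pipelines that require positive frame
evidence. Retained calls sort by descending junction reads with
gene-pair lexicographic tie-breaks, so output order is a pure function of
content. Known-fusion annotation matches the *ordered* (5′, 3′) pair
against a curated TSV; orientation matters because reciprocal products are
biologically distinct.

## Tumor-only TMB

The three-level cascade runs strictly in order 1 → 2 → 3, each level a pure
subset filter:

* **Level 1 (tolerant)** removes records with global *or* South-Asian
  population AF `> max_pop_af` (strict >, default 0.01). Records with both
  annotations absent are retained — absence of evidence is not
  polymorphism.
* **Level 2 (stringent)** removes germline-looking VAFs: inside the
  heterozygous window `[0.40, 0.60]` (inclusive both ends) or at/above the
  homozygous floor `0.90`. The window bounds are this package's
  concretization of "remove germline heterozygous variants by VAF"; at
  200× depth, a true 50% heterozygote falls outside ±0.10 of 0.5 in well
  under 1% of draws, while somatic VAFs at realistic purity (≤ ~0.25
  expected here) essentially never reach 0.40.
* **Level 3 (baseline)** removes sites carried by
  `baseline_min_occurrence >= 2` normals in the panel. The floor of 2
  balances recurrent-artifact removal against discarding real variants
  that one normal happens to share. A missing panel makes level 3 a
  pass-through in `compute_tmb` (the count is still reported); calling
  `level3_baseline_filter` directly with an empty panel is an error.

TMB = survivors / `exome_size_mb`. The coding footprint is not fixed by
any standard; the default is 30 Mb, the conventional size of the
protein-coding exome, and it is configurable because the denominator
should match the capture design actually used. Classification is
TMB-high at `>= 20` mut/Mb (inclusive; some summaries print ">20" — the
inclusive reading is used and configurable). The numerator counts all
coding SNVs/MNVs/INDELs surviving the cascade; a
`tmb_consequence_whitelist` can restrict it (e.g. to nonsynonymous calls),
and is off by default.

## MSI scoring

The upstream genome-wide microsatellite caller is replaced by a defined,
deterministic per-locus statistic with the same score semantics
(score = percent unstable loci):

* per locus, `shift_fraction` = reads with repeat length ≠ reference
  length / total reads;
* the baseline stores, per locus present in *all* normals, the mean and
  population standard deviation of the shift fraction across ≥ 2 normals;
* a locus with `>= msi_min_locus_coverage` (20) reads is **unstable** when
  its shift fraction exceeds `mean + 3·max(sd, 0.01)`.

The coverage floor keeps binomial noise at stutter-level fractions from
mimicking instability (at 20 reads and a 5% stutter rate, the 3-sd
exceedance probability is well below 1%); the sd floor of 0.01 protects
against degenerate panels whose empirical sd is ~0. PCR stutter is modeled
only through the baseline — normals and tumor share the stutter process —
with no explicit stutter correction. Score = 100 · unstable/evaluated;
MSI-High at `>= 15%` (inclusive, configurable). Zero evaluable loci yield
an explicit `Not-Assessable` result rather than an error.

## QC gates and validation statistics

Specimen/library gates use ≥ boundaries (tumor content ≥ 0.10, area
≥ 5 mm², library ≥ 10 nM, fragment peak within 300 ± 100 bp, mean depth
≥ 200×); sequencing-fraction gates are strict (on-target > 0.80,
uniformity > 0.90), matching how the respective acceptance rules are
stated. Unmeasured metrics are reported as such and skipped in the overall
verdict. Uniformity is the fraction of target bases covered at
≥ 0.2 × mean target depth — the common industry definition — and
on-target fraction is depth-weighted (aligned bases on target over all
aligned bases).

Concordance requires an explicit negative universe: specificity is
meaningless without enumerating the assayed, truth-negative sites, so the
caller must supply truth positives and truth negatives with disjoint keys;
observed features outside that universe are ignored. Reproducibility is
the percentage of truth features recovered in *every* replicate.

## Synthetic-data generators

The generators emulate the statistical structure the engines exploit, at
the assay's operating point, and all are pure functions of their arguments
including the seed:

* **Tumor-only VCF** — depth ~ Poisson(200); common germline variants with
  population AF ~ U(0.02, 0.5), heterozygous or (with the Hardy–Weinberg
  conditional carrier probability) homozygous, expected VAF 0.5 / 1.0;
  rare germline with AF < 0.001, heterozygous; somatic variants with no
  population annotation and expected VAF `purity · U(0.2, 1.0) / 2`
  (heterozygous hit scaled by tumor purity, defaults purity 0.5 → expected
  VAF 0.05–0.25, mean 0.15). Observed alt counts are
  Binomial(depth, expected VAF). About 10% of sites are short indels.
  Variants are simulated at the pileup level: there is no read-level
  error, strand, or FFPE-artifact model, so passing tests demonstrate the
  filtering logic, not robustness to artifact-heavy real data.
* **Panel baseline** — each germline site is carried by
  Binomial(n_normals, HWE carrier frequency) normals (floored at 1);
  somatic sites never enter the panel.
* **MSI profiles** — stable loci (and all normal-panel loci) draw their
  shifted-read count Binomial(reads, 0.05); unstable loci use 0.35; reads
  per locus ~ Poisson(100); shifted reads land on ref−1/ref−2/ref+1 with
  probabilities 0.5/0.3/0.2 (deletion slippage dominates).
* **Fusion tables** — reportable calls (high confidence, 5–100 junction
  reads, ORF retained) mixed with low-support (1–4 reads) and lost-ORF
  decoys.
* **Depth track** — Poisson target coverage plus a lower-coverage
  off-target flank, with the matching BED.

## Validation problem sizes

The recovery checks in the test suite run at desk scale, chosen so the
binomial/Poisson noise terms are small relative to the tolerances being
asserted: the TMB cascade is checked over seeds 1–10 with 200 common +
100 rare germline variants and 30/300/900 somatic mutations on 30 Mb
(recovery within ±10% and correct high/low classification in all 30
runs — note the cascade is measured on the full call set, with the
reportability filter validated separately, since the read-support floor
deliberately removes somatic calls at the LOD boundary and that is an
assay property, not a germline-filtering property); MSI classification is
checked over 200 seeded replicates each of fully stable and 30%-unstable
samples with 30 loci and 5 normals (≥ 99% correct); oracle-equivalence
checks run 100 randomized instances per operation.

## Numerical and degenerate-input choices

* Boundary semantics are exactly as configured: inclusive ≥ for read
  support, LODs, CN cutoff, junction reads, TMB-high and MSI-High; strict
  > for the population-AF rule and the deletion-scope bound (< 20 bp in
  scope).
* `min_detectable_vaf` returns the correctly rounded float quotient
  `m / d`; the product identity `vaf · d = m` holds to one ulp.
* VCF Float INFO fields round-trip with ~6 significant digits (text
  rendering); integer counts round-trip exactly.
* Zero-depth records have VAF 0 by convention and cannot pass the LOD
  gate; empty inputs flow through every filter as empty outputs.
* Reports are serialized with sorted keys and fixed float rounding, so a
  fixed seed and configuration reproduce byte-identical artifacts.

## Known limitations

* Level-2 VAF windows misclassify somatic mutations in copy-neutral LOH
  or high-purity clonal peaks near 50% VAF; a matched normal, when
  available, is strictly better than any tumor-only cascade.
* The MSI statistic assumes the normals share the sample's stutter
  process (same chemistry and capture); a baseline from a different
  protocol will miscalibrate the k·sd threshold.
* The generators do not model FFPE deamination artifacts, sequencing
  error, GC-dependent coverage, or subclonal structure beyond a single
  uniform clonal fraction.
* Concordance statistics are only as meaningful as the supplied negative
  universe; the package deliberately refuses to invent one.
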