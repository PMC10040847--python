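# exomark

A post-variant-calling biomarker engine for whole-exome (DNA + RNA) tumor
profiling. Clinical comprehensive-genomic-profiling assays run an upstream
aligner/caller and then apply a validated layer of filtering and scoring
rules to turn raw calls into reportable biomarkers. `exomark` implements
that layer:

* **Reportability filtering** of SNVs/MNVs/INDELs — a variant is reported
  only with ≥ 10 good-quality mutant reads, VAF at or above the limit of
  detection (5% for SNVs/MNVs, 10% for INDELs), and, for deletions, fewer
  than 20 deleted bases (longer deletions are outside the validated scope
  of hybrid-capture exome sequencing on FFPE tissue).
* **Copy-number amplification** calling at gene level, copy number ≥ 6.
* **Tumor-only TMB** via a sequential three-level germline-filter cascade:
  (1) remove polymorphisms with global or South-Asian population allele
  fraction > 1%; (2) remove germline-patterned VAFs (heterozygous window
  0.40–0.60, homozygous ≥ 0.90); (3) remove sites recurrent in a
  panel of normals pooled from healthy blood samples. TMB = surviving
  coding mutations / exome megabases; TMB-high at ≥ 20 mut/Mb.
* **MSI scoring**: per locus, the fraction of reads whose microsatellite
  repeat length differs from the reference is compared against the
  panel-of-normals mean + 3·sd; the MSI score is the percentage of
  evaluated loci that are unstable, MSI-High at ≥ 15%.
* **Fusion prioritization**: high caller confidence, ≥ 5 unique
  junction-spanning reads, open reading frame not lost; retained calls are
  annotated against a curated known-fusion pair list.
* **QC gates** (tumor content ≥ 10%, tumor area ≥ 5 mm², library ≥ 10 nM
  with a ~300 bp peak, mean depth ≥ 200×, on-target > 80%,
  uniformity > 90%) and the **validation statistics** used to accredit such
  an assay: sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP),
  accuracy, and reproducibility across replicate libraries.

A seeded synthetic-data module generates every input format with truth
labels, so the whole pipeline is exercisable and testable without any
sequencing data.

## Worked example

Simulate a tumor-only exome call set — 200 common polymorphisms, 100 rare
germline heterozygotes, 300 somatic mutations at purity 0.5 over a 30 Mb
footprint, sequenced at ~200× — together with a matching panel-of-normals
baseline, then compute TMB:

```sh
exomark simulate vcf --n-somatic 300 --seed 7 \
    --out-vcf tumor.vcf --out-baseline baseline.tsv
exomark tmb --vcf tumor.vcf --baseline baseline.tsv
```

```
tmb: 578 -> 378 -> 279 -> 279; 9.30 mut/Mb (low)
{
  "classification": "low",
  "n_after_level1": 378,
  "n_after_level2": 279,
  "n_after_level3": 279,
  "n_input": 578,
  "tmb_mut_per_mb": 9.3
}
```

Reading the counts: 600 simulated variants enter, 578 survive reportability
filtering; level 1 removes the 200 common polymorphisms, level 2 removes
the ~100 rare germline heterozygotes by their ~50% VAF, and level 3 finds
nothing new (the panel sites were already polymorphic). The 279 survivors
estimate the 300 true somatic mutations within 10%, giving 9.3 mut/Mb —
correctly below the 20 mut/Mb TMB-high cutoff.

Scoring a simulated sample in which 30% of microsatellite loci are truly
unstable, against its own stable normal panel:

```sh
exomark simulate msi --fraction-unstable 0.3 --seed 7 --out-dir msi/
exomark msi --sample-tsv msi/sample.tsv --baseline-dir msi/normals
```

```
msi: 9/30 unstable (MSI-High)
{
  "classification": "MSI-High",
  "n_evaluated": 30,
  "n_unstable": 9,
  "score_percent": 30.0
}
```

All 9 truly unstable loci (and no stable ones) exceed their baseline
threshold: score 30% ≥ 15%, hence MSI-High.

`exomark run --vcf … --cnv … --fusions … --msi-sample … --out-dir report/`
runs every stage at once and writes a consolidated JSON biomarker report
with the full configuration echoed for auditability. See
`docs/methods.md` for the model, parameter and design details.

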