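# chtriage

UMI-consensus variant calling and clonal-hematopoiesis-aware triage for
matched tumor / peripheral-blood-cell (PBC) / plasma sequencing panels.

Plasma cell-free DNA carries variants from the tumor, from clonally expanded
blood cells (clonal hematopoiesis, CH), and of unknown origin. Without
matched PBC sequencing, persistent CH variants in postoperative plasma are
easily misread as residual disease. This package implements the full
analysis chain:

- **`umi_caller`** — groups UMI-tagged reads into molecular families,
  builds strict-majority consensus alleles, and calls variants with
  family-count thresholds (defaults: ≥3 reads per functional family, ≥2
  supporting families per call). VAFs are percentages of functional
  families (molecular depth).
- **`triage`** — labels every variant by compartment co-detection:
  PBC-detected ⇒ `CH_RELATED` (precedence over tumor detection), tumor and
  plasma ⇒ `TUMOR_DERIVED_CONCORDANT`, plasma-only ⇒ `UNKNOWN_PLASMA_ONLY`,
  tumor-only ⇒ `TUMOR_ONLY`; plus cohort concordance, per-stage detection
  rates with and without CH exclusion, and monitorable-marker rates.
- **`monitoring`** — tracks baseline plasma variants through serial
  postoperative samples and raises a discordance warning when a naive
  reading (any persistent variant = residual disease) disagrees with the
  CH-aware reading (tumor-derived markers only).
- **`cohort_stats`** — two-sided Mann–Whitney rank-sum test (exact
  enumeration for small groups, tie-corrected normal approximation
  otherwise), tumor-derived vs CH VAF comparisons per compartment, and CH
  prevalence by age decade.
- **`synthetic_data`** — a seed-deterministic simulator of matched
  three-compartment cohorts: age-dependent CH clones (logistic prevalence,
  0.05–1.5% VAF), tumor clones from per-gene frequencies, stage-dependent
  circulating tumor fractions, leukocyte infiltration of tumor tissue,
  Poisson molecular families with per-read substitution errors, and
  cured/residual/relapse postoperative scenarios with ground truth.
- **`io_cli`** — TSV/VCF/YAML I/O and the `chtriage` command.
- **`datasets`** — the packaged 11-row PBC-mutation fixture table and a
  38-patient cohort reconstruction constrained by published marginal counts.

## CLI

```sh
chtriage simulate --seed 7 --out sim/ --n-patients 8   # reads + truth + manifest
chtriage call --reads sim/S01_plasma_preop.reads.tsv --panel panel.tsv --out calls.tsv
chtriage triage --fixture table1                       # packaged fixture summary
chtriage triage --calls cohort_calls.tsv --out-prefix out/cohort
chtriage monitor --calls cohort_calls.tsv --out monitoring.json
chtriage report --calls cohort_calls.tsv --ages ages.tsv --out stats.json
```

`triage`, `monitor`, and `report` consume a combined call TSV (columns
`patient compartment timepoint months_from_surgery chrom pos ref alt gene
vaf_pct alt_families total_families read_depth`) covering tumor, PBC, and
serial plasma rows.

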