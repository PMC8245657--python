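# neoprofiler

Neoantigen profiling for tumor/normal sequencing cohorts: somatic variant
calling by Fisher's exact test, exhaustive mutant-peptide enumeration, HLA
class I binding and expression filtering, and the cohort statistics that
relate mutational burden to neoantigen load.

## The problem

Neoantigens are tumor-specific peptides created by somatic non-synonymous
mutations; because they are absent from normal tissue they can be presented
on HLA class I molecules and recognized by CD8+ cytotoxic T cells. Profiling
them from sequencing data is the first step both for immune-landscape
analyses (does a mutation-rich tumor carry more neoantigens? does the load
track T-cell marker expression?) and for selecting peptides for vaccines or
adoptive T-cell therapy. This package implements that profiling pipeline for
breast-cancer-style tumor/normal cohorts, together with a synthetic-cohort
generator with known ground truth so every stage is testable without access
to patient sequencing data.

## The method

1. **Somatic calling.** At each site with tumor/normal ref/alt read counts
   (base quality ≥ 15 assumed upstream), a variant is somatic iff all of:
   depth ≥ 10 in both samples; tumor alt reads ≥ 4; tumor VAF ≥ 10%;
   normal VAF < 2%; and the two-sided Fisher exact p on
   [[tumor_ref, tumor_alt], [normal_ref, normal_alt]] is < 0.05.
2. **Classification** into six classes against a transcript model:
   nsSNV, sSNV, stopgain, stoploss, splicing (SNV in the window flanking
   an exon junction), INDEL.
3. **Epitope enumeration.** For each nsSNV, every 8–11mer window of the
   mutant protein containing the substituted residue (38 windows for an
   internal position), paired with its wildtype counterpart.
4. **Neoantigen filters.** A peptide is a predicted binder if its IC50
   against ≥ 1 patient HLA class I allele is < 500 nM; the variant counts
   toward the **neoantigen load** if additionally RNA-seq reads cover the
   mutated position (read count ≥ 1). Affinities come from an external
   NetMHC-style table, or from a deterministic built-in position-weight
   model for self-contained runs.
5. **Cohort statistics.** Pearson correlations (burden vs nsSNVs vs
   predicted binders vs load, load vs immune-gene FPKM for CD8A, CD4,
   TCRB, GZMA, GZMB, PRF1), Student's t comparison of TNBC vs non-TNBC
   loads, ELISpot positivity (> 50% over control) and calcein-release
   cytotoxicity ((control − sample)/control × 100%).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
31-patient cohort (13 TNBC, twice the mutation burden of non-TNBC):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_call_variants.py
python analysis/03_predict_neoantigens.py
python analysis/04_cohort_statistics.py --seed 1
python analysis/05_ctl_assays.py --seed 1
```

which prints (seed 1):

```
simulated 31 patients (13 TNBC / 18 non-TNBC) -> results/cohort
mean spiked exonic burden: TNBC 140.3, non-TNBC 74.7 (designed ratio 2x)
called 2839 exonic somatic mutations across 31 patients; 1771 nsSNVs (62.4% of exonic calls)
neoantigen load: mean 98, range 20-317 (predicted binders mean 201)
ranked HLA-A*02:06 vaccine candidates (read count >= 2) for 12 carrier patients
  n_exonic_vs_n_nssnv: r = 0.993 (p = 1.8e-28)
  n_nssnv_vs_predicted_binders: r = 0.949 (p = 4.6e-16)
  n_nssnv_vs_neoantigen_load: r = 0.928 (p = 6.2e-14)
immune panel vs load (independent by construction): max |r| = 0.433
TNBC vs non-TNBC load: t = 2.59, p = 0.015
ELISpot positive peptides (>50% over control): peptide3, peptide9
CTL_P9_vs_tumor: cytotoxicity 62.4% +/- 0.5 (n=4)
```

Reading the output: nsSNVs dominate the exonic calls (62.4%) and track
total burden almost perfectly (r = 0.99); each patient carries tens to
hundreds of predicted binders, roughly half of which survive the
expression filter to form the load; the TNBC group's doubled burden
propagates into a significantly higher load; and the immune-gene panel —
drawn independently of load in the simulation — shows no significant
correlation, as expected under the null. The assay script demonstrates the
ELISpot positivity rule and the cytotoxicity formula on synthetic plate
readings.

The same stages are available as a CLI (`neoprofiler simulate | call |
classify | neoantigens | cohort-stats | assay | run`) for running on
externally supplied allele-count tables, VCFs, HLA genotypes and affinity
tables.

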