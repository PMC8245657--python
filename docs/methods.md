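# Methods

## Scope and coordinate model

The pipeline operates in CDS space: a transcript is a coding sequence
(ATG … stop) with recorded exon-junction offsets, and all positions
(allele counts, variants, RNA read counts) are 1-based CDS coordinates
with the transcript id serving as the chromosome surrogate. This removes
genome-scale plumbing (liftover, intronic coordinates, multi-transcript
annotation) while preserving everything the analysis depends on: codon
arithmetic, splice-site adjacency, window enumeration over the protein.
Read alignment, duplicate marking, base-quality filtering (counts are
assumed to reflect reads with base quality ≥ 15 and mapping quality
filters applied) and HLA typing are upstream of this package's inputs.

## Somatic calling

Evidence at a site is the 2×2 table [[tumor_ref, tumor_alt],
[normal_ref, normal_alt]]. The two-sided Fisher exact p-value is computed
by summing, over the hypergeometric support fixed by the margins, the
probabilities of all tables no more likely than the observed one
(minimum-likelihood convention). Log-probabilities come from
`scipy.special.gammaln`; a relative tie guard of 1e-11 — comfortably above
the ~1e-13 noise of the log-gamma route and far below genuine probability
gaps at these depths — keeps exact mirror-table ties in the sum. The unit
tests check this against both `scipy.stats.fisher_exact` and an exhaustive
enumeration oracle with exact integer tie comparisons.

Filter semantics follow the printed inequalities literally: depth ≥ 10
(applied to **both** samples — the conservative reading where the source
is ambiguous), tumor alt reads ≥ 4, tumor VAF ≥ 10% (inclusive), normal
VAF < 2% (exclusive), p < 0.05 (exclusive). Relaxing any single threshold
can only grow the call set (tested). Cheap count filters run before the
exact test so the Fisher computation is only paid for surviving sites.

## Classification

Precedence: an insertion/deletion token is INDEL; an SNV inside the
splice window is splicing; otherwise the mutated codon is translated
(standard code, via Biopython) and compared — new stop → stopgain, lost
terminal stop → stoploss, same residue → sSNV, else nsSNV. Splice-site
variants are conventionally the two intronic bases at each junction; this
coordinate system has no intronic positions, so the window is defined as
the two CDS bases on each side of every interior exon junction
(positions j−1…j+2 for a junction after base j), taking precedence over
the codon-level class. The cohort generator places coding-class variants
outside these windows, so ground-truth classes are recoverable exactly.

## Epitope enumeration and binding

For an nsSNV at protein position i in a protein of length n, the windows
of length L containing the substitution number
min(i, n−L+1) − max(1, i−L+1) + 1 (verified exhaustively against a
brute-force scan); enumeration emits each window once, ordered by length
then start, with the wildtype counterpart taken at the same coordinates.
Peptides never extend past the protein termini and are never padded.

Binding affinities are an interface, not a model we claim: real runs
consume NetMHC-style tables (tab-separated allele/peptide/IC50; duplicate
rows keep the minimum IC50 in lenient mode — conservative toward calling
a binder — or raise in strict mode). For self-contained runs the package
ships a deterministic position-weight model: per allele, a 20×9 weight
matrix (text asset versioned in the repository; alleles outside the asset
get a matrix derived from SHA-256 of the allele name, so any genotype is
scorable identically on any platform). Peptide positions map onto the 9
slots NetMHC-style (first four, last five; middle residues of 10/11mers
fold onto the central slot with 0.3 weight), anchors at P2 and the
C-terminus carry 2.5× weight, and the summed score s maps monotonically
onto (0, 50000] nM via ic50 = 50000·logistic(−(s − 4.3)/1.0). The
midpoint/scale were fixed once, at design time, so that a random peptide
passes IC50 < 500 nM for a given allele about 1–3% of the time — the
regime in which a patient with ~60 nsSNVs carries on the order of 200
predicted binders, matching the scale of real class I predictors on exome
data. The toy model is not a stand-in for any particular predictor's
scores; it exists so tests have a fixed, seedless oracle.

## Neoantigen load

A variant's peptides pass on IC50 strictly below threshold (default
500 nM) against the patient's deduplicated HLA alleles; the variant
qualifies if additionally the RNA read count at the mutated position
meets the floor (default ≥ 1; "covering" reads by default, with a
mutant-supporting mode selectable when the table provides it — covering
is the default because expression confirmation, not allelic imbalance, is
the filter's purpose). The load counts **distinct mutant peptide
sequences** by default; peptide–allele pairs and qualifying variants are
selectable units, because published load definitions are not uniform on
this point. Load is non-increasing as the IC50 threshold tightens or the
read-count floor rises, and invariant to duplicating a homozygous allele
(both tested). Vaccine-candidate selection restricts to one allele and a
stricter read-count floor (default ≥ 2), ranks by ascending IC50 with
lexicographic tie-break, and returns the top k with wildtype
counterparts — the ranking rule is made explicit and deterministic since
selection procedures in practice are not fully printed.

## Synthetic cohorts

The generator emulates the structure of a 31-patient breast-cancer
cohort; since the study data it stands in for are not public, its
defaults are scale choices, not reconstructions:

| parameter | default | rationale |
|---|---|---|
| patients / TNBC fraction | 31, 13/31 | study-scale cohort split |
| exonic burden (non-TNBC) | NB(mean 70, size 5) | cohort nsSNV mean ≈ 64/patient at 62.4% nsSNV; over-dispersed so patients vary as real cohorts do |
| TNBC burden multiplier | 2.0 | encodes the higher TNBC burden |
| class mix | 62.4% nsSNV, 25% sSNV, 4% stopgain, 0.3% stoploss, 3.3% splicing, 5% INDEL | nsSNV fraction from the studied cohort; minor classes at typical exome proportions |
| depths | Poisson(100)/Poisson(100) | exome-like coverage |
| tumor VAF | Beta(2, 5) truncated to [0.05, 1] | spans the 10% calling threshold so sensitivity boundaries are exercised |
| sequencing error | 1e-3 per base | normal-sample alt reads arise only from this |
| RNA counts | zero-inflated Poisson (π₀ = 0.5, λ = 5) | ≈ half of predicted binders expressed, matching the observed attrition from predicted binders to load |
| decoys | 30 germline-het (VAF ≈ 0.5 both samples) + 30 noise sites per patient | specificity targets for the caller |

Every patient records its ground truth (true variants with class and VAF,
decoy labels), so sensitivity, specificity and class recovery are scored
exactly. A single integer seed determines the entire cohort byte-for-byte.

What the generator does **not** emulate: read-level artifacts (strand
bias, mapping error, FFPE damage), tumor purity and subclonal structure,
germline variation beyond decoy sites, linked mutations within one codon,
and any dependence of immune-gene expression on load (it is drawn
independently — log-normal FPKM, μ = 2, σ = 1 on the log scale — so the
immune-panel correlations are null-calibration checks). Passing tests
therefore demonstrate the pipeline's correctness and statistical
behavior under these idealized conditions, not concordance with any
particular patient dataset.

## Cohort and assay statistics

Pearson r with the t-transform p (n−2 df) via scipy; the two-group load
comparison uses the unpaired equal-variance Student's t — a paired test
is undefined for the unequal subtype groups, and the output row notes
this choice rather than silently resolving it; a paired mode exists for
genuinely paired readings. Medians and ranges accompany the test.
ELISpot positivity is strict (> 50% above control; a zero control with
positive sample is positive with unbounded fold). Cytotoxicity is
(control − sample)/control × 100 with negative values reported, not
clipped. p-values are unadjusted. FPKM = reads·10⁹/(total·length).

## Numerical and format conventions

All tabular outputs are UTF-8, tab-separated, one header row, floats at 6
significant digits — reruns with the same seed are byte-identical (the
run manifest's timestamps are the only exception, and it also records the
config hash and per-file checksums). Variants interchange as minimal
VCF 4.2 (transcript as CHROM; class, p, VAFs and depths in INFO;
insertion/deletion tokens as `<INS>`/`<DEL>`); writers sort by position.
Readers validate invariants and reject rather than coerce, reporting line
numbers. CLI exit codes: 0 success, 3 parse, 4 validation, 5 stage error.

## Problem sizes used in tests

The test and acceptance workloads use a 40-transcript panel (CDS
300–1200 nt): large enough that per-patient variants rarely collide and
every mutation class is placeable, small enough that the full acceptance
suite (including 100 replicate 31-patient cohorts and the exhaustive
Fisher-oracle sweep over all 164,175 tables with margins ≤ 30) completes
in a few minutes on one CPU.

## Known limitations

Only substitution neoepitopes are scored (INDEL, fusion and class II
epitopes are out of scope); multi-allelic sites are not modeled; the toy
binding model shares no weights with trained predictors, so absolute
IC50 values are meaningful only relative to its own threshold; tumor
purity is not corrected for; and the splicing-window convention differs
from intron-based annotation tools as described above.
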