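#!/usr/bin/env python
"""Enumerate 8-11mer mutant peptides per nsSNV, filter by HLA class I
binding (IC50 < 500 nM) and RNA coverage (read count >= 1), and compute
each patient's neoantigen load.

Also ranks vaccine candidates for one allele under the stricter CTL rule
(read count >= 2, top 10 by ascending IC50), as done when selecting
peptides for synthesis. Writes the per-patient profile table under
results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neoprofiler import (NeoantigenParams, ToyBindingModel,
                         build_neoantigen_records, neoantigen_load,
                         select_vaccine_candidates)
from neoprofiler.io import (read_hla_genotype, read_reference,
                            read_rna_counts, read_variants_vcf,
                            write_results_table)

CANDIDATE_ALLELE = "HLA-A*02:06"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--variants", type=Path, default=Path("results/variants"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    models = {m.gene_symbol: m for m in read_reference(
        args.cohort / "reference_cds.fasta",
        args.cohort / "reference_annotation.tsv")}
    predictor = ToyBindingModel()
    params = NeoantigenParams()
    rows = []
    candidate_rows = []
    for vcf in sorted(args.variants.glob("*.variants.vcf")):
        patient_id = vcf.name.split(".")[0]
        nssnvs = [v for v in read_variants_vcf(vcf)
                  if v.mutation_class == "nsSNV"]
        alleles = read_hla_genotype(args.cohort / f"{patient_id}.hla.txt")
        rna = read_rna_counts(args.cohort / f"{patient_id}.rna_counts.tsv")
        records, n_binders = build_neoantigen_records(
            nssnvs, models, alleles, predictor, rna, params)
        load = neoantigen_load(records, params)
        rows.append({"patient_id": patient_id, "n_nssnv": len(nssnvs),
                     "n_predicted_binders": n_binders,
                     "neoantigen_load": load})
        if CANDIDATE_ALLELE in alleles:
            for rank, c in enumerate(select_vaccine_candidates(
                    records, CANDIDATE_ALLELE, min_read_count=2, top_k=10,
                    patient_alleles=alleles), start=1):
                candidate_rows.append({
                    "patient_id": patient_id, "rank": rank,
                    "peptide": c.sequence, "wildtype": c.wildtype_sequence,
                    "ic50_nm": c.ic50_nm,
                    "rna_read_count": c.rna_read_count})
    table = pd.DataFrame(rows)
    write_results_table(table, args.out / "neoantigen_loads.tsv")
    loads = table["neoantigen_load"]
    print(f"neoantigen load: mean {loads.mean():.0f}, "
          f"range {loads.min()}-{loads.max()} "
          f"(predicted binders mean {table['n_predicted_binders'].mean():.0f})")
    if candidate_rows:
        cands = pd.DataFrame(candidate_rows)
        write_results_table(cands, args.out / "vaccine_candidates.tsv")
        n_pat = cands["patient_id"].nunique()
        print(f"ranked {CANDIDATE_ALLELE} vaccine candidates "
              f"(read count >= 2) for {n_pat} carrier patients "
              f"-> {args.out / 'vaccine_candidates.tsv'}")


if __name__ == "__main__":
    main()
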