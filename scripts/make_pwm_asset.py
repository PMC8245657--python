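"""One-off generator for the versioned toy PWM asset (run once; the asset
is committed and treated as frozen)."""
import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLELES = [
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*02:06", "HLA-A*24:02",
    "HLA-B*07:02", "HLA-B*35:01", "HLA-B*40:02", "HLA-C*04:01",
    "HLA-C*07:02", "HLA-C*12:02",
]
ANCHOR_SLOTS = (1, 8)
ANCHOR_SCALE = 2.5
N_SLOTS = 9

rng = np.random.default_rng(739421)  # fixed once; asset is versioned text
rows = []
for allele in ALLELES:
    w = rng.normal(0.0, 1.0, size=(20, N_SLOTS))
    w[:, list(ANCHOR_SLOTS)] *= ANCHOR_SCALE
    w -= w.mean(axis=0, keepdims=True)   # zero column means
    for i, aa in enumerate(AMINO_ACIDS):
        rows.append((allele, aa, *("%.6f" % v for v in w[i])))

with open("src/neoprofiler/data/pwm_alleles.tsv", "w") as fh:
    fh.write("# toy HLA class I position-weight matrices (versioned asset)\n")
    fh.write("# score(peptide) = sum_i W[aa_i, slot(i, L)]; slots: first 4 "
             "positions -> 0..3, last 5 -> 4..8, middle (L>9) -> slot 4 "
             "damped x0.3\n")
    fh.write("# ic50_nM = 50000 * logistic(-(score - midpoint)/scale)\n")
    fh.write("#midpoint=4.3\n")
    fh.write("#scale=1.0\n")
    fh.write("allele\taa\t" + "\t".join(f"s{j}" for j in range(N_SLOTS)) + "\n")
    for r in rows:
        fh.write("\t".join(r) + "\n")
print("wrote", len(rows), "rows")
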