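#!/usr/bin/env python
"""Quantify CTL-induction assay readouts: IFN-gamma ELISpot responses
against the >50%-over-control positivity rule, and calcein-release
cytotoxicity percentages.

The replicate readings here are a synthetic demonstration table (this
repository ships no wet-lab data); the computations are exactly those a
real plate export would go through.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neoprofiler import cytotoxicity_percent, elispot_response
from neoprofiler.io import write_results_table


def synthetic_readings(seed: int) -> pd.DataFrame:
    """Synthetic plate readings: 10 pulsed peptides vs a no-peptide
    control, two of which respond, plus CTL cytotoxicity replicates."""
    rng = np.random.default_rng(seed)
    rows = []
    for pep in range(1, 11):
        boost = 2.1 if pep in (3, 9) else rng.uniform(0.8, 1.3)
        for _ in range(2):
            control = int(rng.normal(100, 8))
            rows.append({"assay": "elispot", "label": f"peptide{pep}",
                         "control": control,
                         "sample": int(control * boost + rng.normal(0, 6))})
    for label, kill in (("CTL_P9_vs_tumor", 0.65), ("CTL_WT_vs_tumor", 0.1)):
        for _ in range(4):
            control = rng.normal(2000, 120)
            rows.append({"assay": "cytotoxicity", "label": label,
                         "control": round(control, 1),
                         "sample": round(control * (1 - kill)
                                         + rng.normal(0, 80), 1)})
    return pd.DataFrame(rows)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    df = synthetic_readings(args.seed)
    summary = []
    for (kind, label), grp in df.groupby(["assay", "label"]):
        if kind == "elispot":
            res = elispot_response(int(grp["sample"].sum()),
                                   int(grp["control"].sum()))
            values = grp["sample"] / grp["control"]
            summary.append({"assay": kind, "label": label,
                            "n": len(grp), "mean": values.mean(),
                            "sem": values.std(ddof=1) / len(grp) ** 0.5,
                            "positive": res["positive"]})
        else:
            values = [cytotoxicity_percent(c, s)
                      for c, s in zip(grp["control"], grp["sample"])]
            s = pd.Series(values)
            summary.append({"assay": kind, "label": label, "n": len(s),
                            "mean": s.mean(),
                            "sem": s.std(ddof=1) / len(s) ** 0.5,
                            "positive": ""})
    out = pd.DataFrame(summary)
    write_results_table(out, args.out / "assay_summary.tsv")
    positives = out[(out["assay"] == "elispot") & (out["positive"] == True)]
    print("ELISpot positive peptides (>50% over control): "
          + ", ".join(positives["label"]))
    cyto = out[out["assay"] == "cytotoxicity"]
    for _, row in cyto.iterrows():
        print(f"{row['label']}: cytotoxicity {row['mean']:.1f}% "
              f"+/- {row['sem']:.1f} (n={row['n']})")


if __name__ == "__main__":
    main()
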