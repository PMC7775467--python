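#!/usr/bin/env python
"""Knockdown quantification: nested ddCt with the unrelated-value rank test.

Simulates the four-condition qPCR design (growth control, transfection-agent
control, target siRNA, scrambled siRNA; three biological replicates x three
plates, technical duplicates) with a planted -1.2-cycle knockdown effect on
both target amplicons, runs the nested ddCt scheme with the index-matched
unrelated subset and exact Wilcoxon test, and compares simulated EMSA band
intensities between probe alleles with an exact Mann-Whitney U test.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from sibmod.simulate import knockdown_effects, simulate_ct
from sibmod.validation import (
    SIRNA_SCRAMBLED,
    SIRNA_TARGET,
    BandIntensity,
    average_technical_duplicates,
    compare_band_intensities,
    ddct_nested,
    delta_ct,
    unrelated_subset,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/qpcr"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    raw = simulate_ct(knockdown_effects(-1.2, -1.2), seed=args.seed)
    raw.to_csv(args.out / "ct_records.tsv", sep="\t", index=False)
    ct = average_technical_duplicates(raw)

    report = {}
    for amp in ("target_wildtype", "target_alternative"):
        dct = delta_ct(ct, amp)
        for treatment in (SIRNA_TARGET, SIRNA_SCRAMBLED):
            res = unrelated_subset(ddct_nested(dct, treatment, amplicon=amp))
            vals = np.asarray(res.ddct_values)
            key = f"{amp}:{treatment}"
            report[key] = {
                "mean_ddct": float(vals.mean()),
                "n_combinations": len(vals),
                "n_unrelated": len(res.unrelated_indices),
                "wilcoxon_p": res.p_value,
                "direction": res.direction,
            }
            print(f"{key}: mean ddCt {vals.mean():+.3f} "
                  f"({len(res.unrelated_indices)} unrelated values, "
                  f"p = {res.p_value:.4g}, {res.direction})")

    # EMSA densitometry: planted 2-fold allele-T effect over 6 experiments
    rng = np.random.default_rng(args.seed + 1)
    bands = []
    for e in range(6):
        for allele, fold in (("C", 1.0), ("T", 2.0)):
            iso = rng.uniform(4, 6)
            bands.append(BandIntensity(f"e{e}", allele, "isotype_control", iso))
            bands.append(
                BandIntensity(
                    f"e{e}", allele, "specific",
                    fold * iso * rng.lognormal(0.0, 0.25),
                )
            )
    p_u, norm = compare_band_intensities(bands, "C", "T")
    norm.to_csv(args.out / "band_intensities.tsv", sep="\t", index=False)
    med = norm.groupby("allele")["normalized"].median()
    print(f"band intensities: median C {med['C']:.2f} vs T {med['T']:.2f}, "
          f"Mann-Whitney p = {p_u:.4g}")
    report["band_intensity_mannwhitney_p"] = p_u
    (args.out / "ddct_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
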