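#!/usr/bin/env python
"""Divergent-site identification on the published resequencing matrix, and probes.

Runs the divergent-site finder on the packaged allele matrix of the three
resequenced contrasting haplotypes (18 variant positions across the candidate
fragment), then designs centered 35-mer probes and +/-20 bp scan windows for
both alleles of every divergent SNP on a seed-deterministic synthetic
reference sequence (the real fragment sequence is not redistributed here).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sibmod.cohort import MarkerDef
from sibmod.datasets import scnn1b_resequencing_matrix
from sibmod.resequencing import (
    build_probe,
    build_window,
    divergent_sites,
    write_probes_fasta,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/divergent"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = scnn1b_resequencing_matrix()
    sites = divergent_sites(matrix)
    print(f"{len(sites)} divergent positions of {len(matrix.positions)}: "
          f"{', '.join(sites)}")

    rows = []
    disc = matrix.alleles[matrix.tags.index("discordance")]
    for j, pos in enumerate(matrix.positions):
        rows.append(
            {
                "position": pos,
                "divergent": pos in sites,
                **{
                    lab: matrix.alleles[i][j]
                    for i, lab in enumerate(matrix.haplotype_labels)
                },
            }
        )
    pd.DataFrame(rows).to_csv(args.out / "sites.tsv", sep="\t", index=False)

    # synthetic reference: the divergent SNPs spaced 1 kb apart
    rng = np.random.default_rng(args.seed)
    ref = "".join(rng.choice(list("ACGT"), size=len(sites) * 1000))
    probes, windows = [], []
    for k, pos in enumerate(sites):
        j = matrix.positions.index(pos)
        alleles = sorted({row[j] for row in matrix.alleles})
        snp = MarkerDef(id=pos, chrom="16", position=500 + 1000 * k,
                        alleles=alleles)
        for allele in alleles:
            probes.append(build_probe(ref, 1, snp, allele, length=35))
            windows.append(build_window(ref, 1, snp, allele, flank=20))
    with open(args.out / "probes.fasta", "w") as fh:
        write_probes_fasta(probes, fh)
    with open(args.out / "windows.fasta", "w") as fh:
        write_probes_fasta(windows, fh)
    print(f"wrote {len(probes)} probes (35-mer) and {len(windows)} windows "
          f"(41 nt) -> {args.out}")


if __name__ == "__main__":
    main()
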