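"""Small published reference tables shipped with the package.

These are printed results usable as inputs: the resequencing allele matrix
for the SCNN1B candidate fragment, the published group-wise haplotype
frequencies used as the simulator's founder-pool preset, and the published
allele-specific binding-site counts.
"""

from __future__ import annotations

from .resequencing import CONCORDANCE, DISCORDANCE, AlleleMatrix

#: Variant positions across the ~8 kb rs152730-rs152740 fragment, in genomic order.
SCNN1B_FRAGMENT_POSITIONS = [
    "rs152730", "rs62029384", "rs8044970", "rs8044984", "rs80443907",
    "rs152731", "rs152732", "rs180878", "rs152733",
    "rs63982", "rs152745", "rs8062922", "rs152744", "rs62029385",
    "rs152743", "rs152741", "rs57406669", "rs152740",
]


def scnn1b_resequencing_matrix() -> AlleleMatrix:
    """Alleles observed on the three resequenced contrasting SCNN1B haplotypes.

    Rows are the haplotypes named by their alleles at the five mapping
    markers rs152730-rs8044970-rs63982-rs152745-rs152740: TTAGA is associated
    with intrapair discordance, GGAAT and GTCAT with concordance.  Columns
    cover the 18 variant positions of the resequenced fragment.
    """
    return AlleleMatrix(
        haplotype_labels=["TTAGA", "GGAAT", "GTCAT"],
        tags=[DISCORDANCE, CONCORDANCE, CONCORDANCE],
        positions=list(SCNN1B_FRAGMENT_POSITIONS),
        alleles=[
            # rs152730 .. rs152733 | rs63982 .. rs152740
            list("TCTTCTCTT") + list("AGCACGCCA"),
            list("GTGGTCCTT") + list("AATGTGTGT"),
            list("GCTTCCTGC") + list("CACGCATCT"),
        ],
    )


#: Published 5-marker haplotype frequencies among discordant / concordant pairs.
SCNN1B_HAPLOTYPE_FREQUENCIES = {
    "TTAGA": {"discordant": 0.839, "concordant": 0.599},
    "GTCAT": {"discordant": 0.051, "concordant": 0.185},
    "GGAAT": {"discordant": 0.036, "concordant": 0.129},
    "other": {"discordant": 0.074, "concordant": 0.087},
}

#: Allele-specific predicted TF binding sites unique to each contrasting
#: six-marker haplotype (concordance-associated GCAGTT vs discordance-
#: associated TTGACA).
TFBS_UNIQUE_SITE_COUNTS = {"concordance": 6, "discordance": 21}
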