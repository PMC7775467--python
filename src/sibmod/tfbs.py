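"""Generic PWM scanning of allele windows and allele-specific site comparison.

The scanner is a plain additive position-weight-matrix scorer: a site is
reported wherever the sum of per-position weights meets the matrix threshold,
on either strand.  Matrices (and their thresholds) are inputs — no
pseudocount or background logic lives in the scanner, so log-odds matrices
behave as log-odds and count-derived weight matrices as supplied.

For a SNP with two contrasting alleles, a (factor, offset, strand) site is
*allele-unique* when it is predicted on one allele's window and absent from
the other's.  Unique-site counts are pooled across SNPs per haplotype and
compared to an equal-split expectation with a two-sided exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest, chisquare

from .resequencing import reverse_complement

DNA = "ACGT"


@dataclass
class PWM:
    factor: str
    matrix: np.ndarray  # shape (length, 4), columns ordered A C G T
    threshold: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x ACGT")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PWM weights must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


def load_jaspar(handle, threshold_fraction: float = 0.8) -> list[PWM]:
    """Read JASPAR-format matrices (via Bio.motifs) into PWMs.

    Counts are used directly as additive weights; each matrix's threshold
    defaults to ``threshold_fraction`` of its maximal achievable score.
    """
    from Bio import motifs

    out = []
    for m in motifs.parse(handle, "jaspar"):
        mat = np.array([[m.counts[b][i] for b in DNA] for i in range(m.length)])
        pwm = PWM(factor=m.name or m.matrix_id, matrix=mat, threshold=0.0)
        pwm.threshold = threshold_fraction * pwm.max_score()
        out.append(pwm)
    return out


@dataclass(frozen=True)
class TFBSHit:
    window_id: str
    factor: str
    offset: int  # 1-based start of the site on the forward strand
    strand: str  # "+" or "-"
    score: float

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.factor, self.offset, self.strand)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([DNA.index(b) for b in seq.upper()], dtype=np.int64)
    except ValueError as err:
        raise ValueError(f"non-ACGT base in window: {err}") from err


def scan_pwm(window: str, pwm: PWM, window_id: str = "") -> list[TFBSHit]:
    """All offsets and strands where the additive score reaches the threshold."""
    L = len(pwm)
    if len(window) < L:
        return []
    hits = []
    for strand, seq in (("+", window), ("-", reverse_complement(window))):
        enc = _encode(seq)
        for start in range(len(seq) - L + 1):
            score = float(
                pwm.matrix[np.arange(L), enc[start : start + L]].sum()
            )
            if score >= pwm.threshold:
                if strand == "+":
                    offset = start + 1
                else:
                    # leftmost base of the site on the forward strand
                    offset = len(window) - (start + L) + 1
                hits.append(
                    TFBSHit(window_id, pwm.factor, offset, strand, score)
                )
    return sorted(hits, key=lambda h: (h.strand, h.offset, h.factor))


@dataclass
class AlleleSiteComparison:
    unique_sites: dict[str, set]  # per haplotype tag: {(snp, factor, offset, strand)}
    k_concordance: int
    k_discordance: int
    p_equal: float


def allele_unique_sites(
    hits_by_allele: dict[str, dict[str, list[TFBSHit]]],
    haplotype_of_allele: dict[str, dict[str, str]],
) -> AlleleSiteComparison:
    """Pool allele-unique (factor, site) predictions per contrasting haplotype.

    ``hits_by_allele[snp][allele]`` holds the scan results of each allele
    window; ``haplotype_of_allele[snp][allele]`` assigns each allele to
    "concordance" or "discordance".  A site is unique to a haplotype when
    present for that haplotype's allele and absent from the other allele of
    the same SNP.
    """
    unique: dict[str, set] = {"concordance": set(), "discordance": set()}
    for snp, per_allele in hits_by_allele.items():
        alleles = list(per_allele)
        if len(alleles) != 2:
            raise ValueError(f"{snp}: need hits for exactly two alleles")
        sites = {a: {h.site for h in per_allele[a]} for a in alleles}
        for a, other in (alleles, alleles[::-1]):
            tag = haplotype_of_allele[snp][a]
            for site in sites[a] - sites[other]:
                unique[tag].add((snp, *site))
    k_conc = len(unique["concordance"])
    k_disc = len(unique["discordance"])
    p = equal_distribution_test(k_conc, k_disc) if k_conc + k_disc else float("nan")
    return AlleleSiteComparison(
        unique_sites=unique,
        k_concordance=k_conc,
        k_discordance=k_disc,
        p_equal=p,
    )


def equal_distribution_test(k1: int, k2: int, chi_square: bool = False) -> float:
    """Two-sided test of an equal split of k1 + k2 sites between haplotypes.

    Default: exact binomial with p0 = 0.5 (summing point probabilities no
    larger than the observed one).  ``chi_square=True`` switches to a 1-df
    chi-square on the 2-cell count table for sensitivity analysis.
    """
    n = k1 + k2
    if n < 1:
        raise ValueError("no allele-unique sites to test")
    if chi_square:
        return float(chisquare([k1, k2]).pvalue)
    return float(binomtest(k1, n, 0.5, alternative="two-sided").pvalue)
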