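"""Divergent-site identification on resequenced contrasting haplotypes, and probe design.

After fine-mapping isolates a candidate fragment, representative homozygotes
for the contrasting haplotypes are resequenced.  A variant position is
*divergent* when every discordance-associated haplotype carries an allele that
differs from the allele of every concordance-associated haplotype — i.e. the
two tag groups have disjoint allele sets at that position.  Divergent SNPs
seed probe design: odd-length double-stranded oligos carrying one allele at
the exact center, or symmetric +/- flank windows for in-silico binding-site
scans.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .cohort import MarkerDef

DISCORDANCE = "discordance"
CONCORDANCE = "concordance"


@dataclass
class AlleleMatrix:
    """Complete haplotype-label x variant-position allele matrix with tags."""

    haplotype_labels: list[str]
    tags: list[str]  # per haplotype: "discordance" | "concordance"
    positions: list[str]  # ordered variant ids
    alleles: list[list[str]]  # row per haplotype, column per position

    def __post_init__(self) -> None:
        if len(self.haplotype_labels) != len(self.tags) or len(
            self.haplotype_labels
        ) != len(self.alleles):
            raise ValueError("label/tag/row count mismatch")
        for row in self.alleles:
            if len(row) != len(self.positions):
                raise ValueError("incomplete allele matrix")
            if any(not a for a in row):
                raise ValueError("missing entries are not allowed")

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.alleles]


def divergent_sites(matrix: AlleleMatrix) -> list[str]:
    """Positions whose discordance- and concordance-tagged allele sets are disjoint.

    Invariant to row and column permutation; requires both tags present.
    """
    disc_rows = [i for i, t in enumerate(matrix.tags) if t == DISCORDANCE]
    conc_rows = [i for i, t in enumerate(matrix.tags) if t == CONCORDANCE]
    if not disc_rows or not conc_rows:
        raise ValueError("need at least one haplotype per association tag")
    out = []
    for j, pos in enumerate(matrix.positions):
        col = matrix.column(j)
        disc = {col[i] for i in disc_rows}
        conc = {col[i] for i in conc_rows}
        if disc.isdisjoint(conc):
            out.append(pos)
    return out


@dataclass
class Probe:
    snp_id: str
    allele: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 == 0:
            raise ValueError("probe length must be odd")
        center = (len(self.sequence) + 1) // 2  # 1-based
        if self.sequence[center - 1] != self.allele:
            raise ValueError("variant base must sit at the probe center")

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_probe(
    reference: str,
    ref_start: int,
    snp: MarkerDef,
    allele: str,
    length: int = 35,
) -> Probe:
    """Odd-length probe centered on the SNP, carrying the requested allele.

    ``reference`` is the plus-strand sequence starting at 1-based genomic
    coordinate ``ref_start``.
    """
    if length % 2 == 0:
        raise ValueError("probe length must be odd")
    flank = (length - 1) // 2
    offset = snp.position - ref_start  # 0-based index of the SNP in reference
    if offset - flank < 0 or offset + flank >= len(reference):
        raise ValueError(
            f"flank {flank} exceeds available sequence around {snp.id}"
        )
    seq = reference[offset - flank : offset + flank + 1]
    seq = seq[:flank] + allele + seq[flank + 1 :]
    return Probe(snp_id=snp.id, allele=allele, sequence=seq)


def build_window(
    reference: str, ref_start: int, snp: MarkerDef, allele: str, flank: int = 20
) -> Probe:
    """Symmetric +/- flank window (length 2*flank + 1) around the SNP."""
    return build_probe(reference, ref_start, snp, allele, length=2 * flank + 1)


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def write_probes_fasta(probes: list[Probe], sink) -> None:
    for p in probes:
        sink.write(f">{p.snp_id}_{p.allele}\n{p.sequence}\n")
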