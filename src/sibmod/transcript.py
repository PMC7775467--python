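"""Spliced and intron-retention transcripts, ORF translation, amplicon sizes.

A read-through transcript splices exons 1..k normally and then continues into
the genomic sequence past exon k's splice donor.  If the donor junction falls
on a codon boundary of the open reading frame, translation proceeds in frame
into the retained intron until the first intronic stop codon, yielding a
truncated protein with a countable number of intron-derived residues.

All genomic and transcript coordinates are 1-based inclusive; the junction is
the last base of exon k in transcript coordinates.  Standard genetic code
only.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq


@dataclass
class GeneModel:
    gene_id: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # genomic (start, end), 1-based inclusive
    cds_start: int  # transcript coordinate of the A of the start codon

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        for s, e in exons:
            if s < 1 or e < s:
                raise ValueError(f"bad exon interval ({s}, {e})")
        # store in transcription order: genomic order for +, reversed for -
        self.exons = exons if self.strand == "+" else exons[::-1]
        if self.cds_start < 1 or self.cds_start > self.transcript_length:
            raise ValueError("cds_start outside the transcript")

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def junction(self, after_exon: int) -> int:
        """Transcript coordinate of the last base of exon ``after_exon``."""
        if not 1 <= after_exon < len(self.exons):
            raise ValueError("after_exon out of range")
        return sum(e - s + 1 for s, e in self.exons[:after_exon])


def _slice(genome: str, start: int, end: int) -> str:
    if start < 1 or end > len(genome):
        raise ValueError(f"exon ({start}, {end}) outside the genome")
    return genome[start - 1 : end]


def splice(model: GeneModel, genome: str) -> str:
    """Concatenated exon sequence, reverse-complemented for minus strand."""
    parts = [_slice(genome, s, e) for s, e in sorted(model.exons)]
    mrna = "".join(parts)
    if model.strand == "-":
        mrna = str(Seq(mrna).reverse_complement())
    return mrna


def readthrough_transcript(
    model: GeneModel,
    genome: str,
    after_exon: int,
    retained_length: int | None = None,
) -> str:
    """mRNA of exons 1..k plus retained genomic sequence past exon k's 3' end.

    The retention extends ``retained_length`` bases (or to the template end).
    The precise 3' end of such transcripts is typically undetermined, so the
    retained length is a parameter, not a claim.
    """
    if not 1 <= after_exon < len(model.exons):
        raise ValueError("after_exon out of range")
    head = GeneModel(
        gene_id=model.gene_id,
        strand=model.strand,
        exons=list(model.exons[:after_exon]),
        cds_start=1,
    )
    mrna_head = splice(head, genome)
    if model.strand == "+":
        donor_end = model.exons[after_exon - 1][1]
        tail_start = donor_end + 1
        tail_end = (
            len(genome)
            if retained_length is None
            else min(len(genome), donor_end + retained_length)
        )
        tail = _slice(genome, tail_start, tail_end) if tail_end >= tail_start else ""
    else:
        donor_start = model.exons[after_exon - 1][0]
        tail_end = donor_start - 1
        tail_start = (
            1
            if retained_length is None
            else max(1, donor_start - retained_length)
        )
        tail = (
            str(Seq(_slice(genome, tail_start, tail_end)).reverse_complement())
            if tail_end >= tail_start
            else ""
        )
    return mrna_head + tail


@dataclass
class TranslationResult:
    protein_length: int
    stop_found: bool
    residues_past_junction: int
    protein: str


def translate_cds(
    mrna: str, cds_start: int, junction: int | None = None
) -> TranslationResult:
    """Translate from cds_start to the first in-frame stop.

    ``junction`` (transcript coordinate of the last exonic base before a
    retained intron) enables counting the residues encoded past it.  Those
    residues are only defined when the junction preserves the reading frame
    (falls on a codon boundary); an out-of-frame junction yields 0 while the
    total length still reflects the shifted frame.
    """
    if not 1 <= cds_start <= len(mrna):
        raise ValueError("cds_start outside the transcript")
    cds = mrna[cds_start - 1 :]
    cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate())
    stop_at = aa.find("*")
    stop_found = stop_at >= 0
    protein = aa[:stop_at] if stop_found else aa
    past = 0
    if junction is not None:
        offset = junction - cds_start + 1  # coding bases before the junction
        if offset >= 0 and offset % 3 == 0:
            # junction on a codon boundary: codons starting at/after junction+1
            past = max(0, len(protein) - offset // 3)
    return TranslationResult(
        protein_length=len(protein),
        stop_found=stop_found,
        residues_past_junction=past,
        protein=protein,
    )


@dataclass
class PrimerPair:
    forward: tuple[int, int]  # template coordinates, 1-based inclusive
    reverse: tuple[int, int]

    def __post_init__(self) -> None:
        if self.forward[0] > self.forward[1] or self.reverse[0] > self.reverse[1]:
            raise ValueError("primer coordinates must be ordered")
        if self.reverse[1] < self.forward[0]:
            raise ValueError("reverse primer upstream of forward primer")


def amplicon_size(template: str, primers: PrimerPair) -> int:
    """Product length: reverse 3'-end coordinate - forward 5'-start + 1."""
    if primers.reverse[1] > len(template) or primers.forward[0] < 1:
        raise ValueError("primer outside the template")
    return primers.reverse[1] - primers.forward[0] + 1


def read_exon_table(source) -> list[GeneModel]:
    """GFF3-like exon table -> gene models.

    Accepts tab-separated GFF3 lines (exon features; gene id from the Parent
    or ID attribute) plus a ``cds_start=N`` attribute on the first exon line
    of each gene (transcript coordinate; defaults to 1).
    """
    import io
    import os

    if isinstance(source, (str, os.PathLike)):
        fh = open(source)
    else:
        fh = io.StringIO(source.read())
    genes: dict[str, dict] = {}
    with fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2].lower() != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gid = attrs.get("Parent") or attrs.get("ID") or "gene"
            rec = genes.setdefault(
                gid, {"strand": cols[6], "exons": [], "cds_start": 1}
            )
            rec["exons"].append((int(cols[3]), int(cols[4])))
            if "cds_start" in attrs:
                rec["cds_start"] = int(attrs["cds_start"])
    return [
        GeneModel(
            gene_id=gid,
            strand=rec["strand"],
            exons=rec["exons"],
            cds_start=rec["cds_start"],
        )
        for gid, rec in genes.items()
    ]
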