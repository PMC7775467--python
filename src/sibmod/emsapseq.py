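"""EMSA-PSeq noise filtering: from per-sample protein identifications to candidates.

A bait-probe pulldown followed by mass spectrometry identifies hundreds of
proteins per sample; almost all are comigrating complexes, sticky DNA
binders, or handling contaminants.  Running many probe and control samples in
parallel lets a presence/absence cascade isolate SNP-specific interactors.  A
protein is a candidate for a target SNP iff it

1. is absent from every empty negative control,
2. is absent from every native-gel sample of the other SNP probes,
3. has a known tissue abundance strictly below a ppm cutoff (unknown fails),
4. is annotated as nucleic-acid binding.

Denaturing-gel samples lack the multiprotein complexes and are excluded from
criteria 1-2 by default.  Spliceosome components survive the cascade but are
flagged for exclusion from prioritization, not deleted.  MASCOT protein
scores are -10*log10 of the match probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

EMPTY_NEGATIVE = "empty_negative"
CONSENSUS_PROBE = "consensus_probe"


@dataclass(frozen=True)
class MsSample:
    sample_id: str
    probe: tuple[str, str] | None = None  # (snp_id, allele)
    control: str | None = None  # EMPTY_NEGATIVE | CONSENSUS_PROBE
    gel: str = "native"  # or "denaturing"

    def __post_init__(self) -> None:
        if (self.probe is None) == (self.control is None):
            raise ValueError("a sample carries either a SNP probe or a control kind")

    @property
    def probe_group(self) -> str:
        """Alleles of one SNP count as one probe group; each control kind is its own."""
        return self.probe[0] if self.probe else self.control


@dataclass(frozen=True)
class ProteinHit:
    sample_id: str
    protein_id: str
    mascot_score: float
    n_peptides: int = 1

    def __post_init__(self) -> None:
        if self.mascot_score < 0:
            raise ValueError("MASCOT score must be >= 0")
        if self.n_peptides < 1:
            raise ValueError("a hit needs at least one peptide")


def score_to_probability(score: float) -> float:
    """MASCOT score -> match probability P = 10^(-score/10)."""
    if score < 0:
        raise ValueError("MASCOT score must be >= 0")
    return 10.0 ** (-score / 10.0)


def order_of_magnitude(score: float) -> int:
    """Nearest integer power of ten of the match probability (e.g. 119 -> -12)."""
    return round(math.log10(score_to_probability(score)))


def read_hits_table(source) -> list[ProteinHit]:
    """Minimal delimited MASCOT export: sample, accession, score, peptide count."""
    df = pd.read_csv(source, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return [
        ProteinHit(
            sample_id=str(r["sample"]),
            protein_id=str(r["protein"]),
            mascot_score=float(r["score"]),
            n_peptides=int(r.get("peptides", 1)),
        )
        for r in df.to_dict("records")
    ]


def presence_matrix(
    hits: list[ProteinHit], samples: list[MsSample]
) -> pd.DataFrame:
    """Protein x sample boolean matrix; duplicate hits collapse to one presence."""
    sample_ids = [s.sample_id for s in samples]
    known = set(sample_ids)
    orphans = sorted({h.sample_id for h in hits} - known)
    if orphans:
        raise ValueError(f"hits reference unregistered samples: {orphans}")
    proteins = sorted({h.protein_id for h in hits})
    mat = pd.DataFrame(False, index=proteins, columns=sample_ids)
    for h in hits:
        mat.loc[h.protein_id, h.sample_id] = True
    return mat


@dataclass
class CandidateRecord:
    protein_id: str
    passes: bool
    criteria: dict[str, bool]
    scores_per_allele: dict[str, float] = field(default_factory=dict)
    spliceosome_excluded: bool = False


@dataclass
class CandidateReport:
    snp_id: str
    records: list[CandidateRecord]

    @property
    def candidates(self) -> list[str]:
        return [r.protein_id for r in self.records if r.passes]


def filter_candidates(
    matrix: pd.DataFrame,
    samples: list[MsSample],
    abundance: dict[str, float],
    annotation: pd.DataFrame,
    target_snp: str,
    ppm_cutoff: float = 200.0,
    include_denaturing: bool = False,
    hits: list[ProteinHit] | None = None,
) -> CandidateReport:
    """Apply the four-criterion cascade for one target SNP.

    ``annotation`` is indexed by protein id with boolean columns
    ``nucleic_acid_binding`` and ``spliceosome_component``.  Per-criterion
    flags are reported for every protein seen in a target-SNP sample, whether
    or not it passes.  ``include_denaturing`` lets denaturing-gel samples
    count as evidence in criteria 1-2.
    """
    by_id = {s.sample_id: s for s in samples}

    def usable(s: MsSample) -> bool:
        return include_denaturing or s.gel == "native"

    target_cols = [
        s.sample_id for s in samples if s.probe and s.probe[0] == target_snp
    ]
    negative_cols = [
        s.sample_id
        for s in samples
        if s.control == EMPTY_NEGATIVE and usable(s)
    ]
    other_snp_cols = [
        s.sample_id
        for s in samples
        if s.probe and s.probe[0] != target_snp and usable(s)
    ]
    for name, cols in (
        ("target-SNP probe", target_cols),
        ("empty negative control", negative_cols),
        ("other-SNP probe", other_snp_cols),
    ):
        if not cols:
            raise ValueError(f"no {name} samples in the design")

    score_lookup: dict[tuple[str, str], float] = {}
    if hits is not None:
        for h in hits:
            s = by_id.get(h.sample_id)
            if s and s.probe and s.probe[0] == target_snp:
                key = (h.protein_id, s.probe[1])
                score_lookup[key] = max(score_lookup.get(key, 0.0), h.mascot_score)

    records = []
    seen = matrix[target_cols].any(axis=1)
    for protein in matrix.index[seen]:
        row = matrix.loc[protein]
        ppm = abundance.get(protein)
        ann = annotation.loc[protein] if protein in annotation.index else None
        criteria = {
            "absent_from_negative_controls": not row[negative_cols].any(),
            "absent_from_other_snp_probes": not row[other_snp_cols].any(),
            "low_abundance": ppm is not None and ppm < ppm_cutoff,
            "nucleic_acid_binding": bool(ann["nucleic_acid_binding"])
            if ann is not None
            else False,
        }
        records.append(
            CandidateRecord(
                protein_id=protein,
                passes=all(criteria.values()),
                criteria=criteria,
                scores_per_allele={
                    allele: sc
                    for (p, allele), sc in score_lookup.items()
                    if p == protein
                },
            )
        )
    return CandidateReport(snp_id=target_snp, records=records)


def unique_signal(
    protein: str, matrix: pd.DataFrame, samples: list[MsSample]
) -> tuple[bool, str | None]:
    """Is the protein confined to the samples of exactly one probe group?

    Probe groups pool the two allele probes of a SNP; the consensus positive
    control is its own group.  Empty negative controls do not form a group —
    presence there disqualifies uniqueness outright.
    """
    groups = {s.probe_group for s in samples if s.control != EMPTY_NEGATIVE}
    if len(groups) < 2:
        raise ValueError("need at least two distinct probes")
    if protein not in matrix.index:
        return False, None
    row = matrix.loc[protein]
    present_groups = set()
    for s in samples:
        if row.get(s.sample_id, False):
            if s.control == EMPTY_NEGATIVE:
                return False, None
            present_groups.add(s.probe_group)
    if len(present_groups) == 1:
        return True, next(iter(present_groups))
    return False, None


def flag_spliceosome(
    report: CandidateReport, annotation: pd.DataFrame
) -> CandidateReport:
    """Mark spliceosome-component candidates excluded from prioritization (kept)."""
    for rec in report.records:
        if rec.protein_id in annotation.index:
            rec.spliceosome_excluded = bool(
                annotation.loc[rec.protein_id]["spliceosome_component"]
            )
    return report
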