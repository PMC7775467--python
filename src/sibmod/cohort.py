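"""Cohort model and file IO: LINKAGE-style PED/MAP, VCF genotypes, phenotype tables.

The cohort is the shared substrate of every association stage: an ordered marker
panel, family records, and id-indexed individuals holding unphased genotype
calls.  Phase never enters through input files here — it is estimated later by
EM — so VCF phase separators are deliberately collapsed to unphased calls.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field

import pandas as pd

MISSING_ALLELE = "0"


class ParseError(ValueError):
    """Malformed pedigree/genotype input."""


@dataclass
class MarkerDef:
    """A genetic marker: a SNP or a microsatellite.

    Microsatellites are plain multiallelic markers with integer-labelled
    alleles; they get no special storage.
    """

    id: str
    chrom: str
    position: int
    alleles: list[str] = field(default_factory=list)
    kind: str = "SNP"

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"marker {self.id}: position must be positive")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"marker {self.id}: duplicate alleles")

    def allele_index(self, label: str, register: bool = False) -> int:
        try:
            return self.alleles.index(label)
        except ValueError:
            if not register:
                raise
            self.alleles.append(label)
            return len(self.alleles) - 1


@dataclass(frozen=True)
class GenotypeCall:
    """Unphased pair of allele indices; missing is all-or-nothing."""

    allele_a: int | None
    allele_b: int | None

    def __post_init__(self) -> None:
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError("half-missing genotype call")

    @property
    def missing(self) -> bool:
        return self.allele_a is None

    def as_set(self) -> frozenset[int]:
        return frozenset((self.allele_a, self.allele_b))


MISSING_CALL = GenotypeCall(None, None)


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "0"
    phenotype_code: str = "0"
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def role(self) -> str:
        return "offspring" if (self.father_id and self.mother_id) else "founder"

    def call(self, marker_id: str) -> GenotypeCall:
        return self.genotypes.get(marker_id, MISSING_CALL)


@dataclass
class Cohort:
    """Ordered marker panel + families + id-indexed individuals."""

    panel: list[MarkerDef] = field(default_factory=list)
    individuals: dict[str, Individual] = field(default_factory=dict)

    @property
    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals.values():
            fams.setdefault(ind.family_id, []).append(ind)
        return fams

    def marker(self, marker_id: str) -> MarkerDef:
        for m in self.panel:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    def add_individual(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise ParseError(f"duplicate individual id {ind.id!r}")
        self.individuals[ind.id] = ind

    def subset(self, ids: list[str]) -> "Cohort":
        sub = Cohort(panel=self.panel)
        for i in ids:
            sub.individuals[i] = self.individuals[i]
        return sub

    def genotype_vectors(self, marker_ids: list[str], ids=None):
        """Per-individual tuples of (a, b) index pairs (None for missing)."""
        ids = list(self.individuals) if ids is None else ids
        out = []
        for i in ids:
            ind = self.individuals[i]
            vec = []
            for m in marker_ids:
                c = ind.call(m)
                vec.append(None if c.missing else (c.allele_a, c.allele_b))
            out.append(tuple(vec))
        return ids, out

    def mendelian_violations(self) -> list[tuple[str, str]]:
        """(individual_id, marker_id) pairs inconsistent with parental genotypes.

        Violations are reported, never silently fixed.
        """
        viol = []
        for ind in self.individuals.values():
            if ind.role != "offspring":
                continue
            fa = self.individuals.get(ind.father_id)
            mo = self.individuals.get(ind.mother_id)
            if fa is None or mo is None:
                continue
            for m in self.panel:
                c, cf, cm = ind.call(m.id), fa.call(m.id), mo.call(m.id)
                if c.missing or cf.missing or cm.missing:
                    continue
                ok = any(
                    {x, y} == {c.allele_a, c.allele_b}
                    for x in (cf.allele_a, cf.allele_b)
                    for y in (cm.allele_a, cm.allele_b)
                )
                if not ok:
                    viol.append((ind.id, m.id))
        return viol


# ---------------------------------------------------------------------------
# PED/MAP


def _as_lines(source) -> list[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            return fh.read().splitlines()
    return source.read().splitlines()


def read_pedigree(ped_source, map_source) -> Cohort:
    """Read a LINKAGE-style PED + MAP pair into a Cohort.

    MAP rows: chrom, marker id, position (a 3rd genetic-distance column, if
    present, is ignored).  PED rows: family, id, father, mother, sex,
    phenotype, then two allele columns per mapped marker; "0" = missing.
    Unknown allele labels are registered in order of first appearance.
    Markers are ordered by (chrom, position).
    """
    markers: list[MarkerDef] = []
    for ln, line in enumerate(_as_lines(map_source), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) == 3:
            chrom, mid, pos = parts
        elif len(parts) == 4:
            chrom, mid, _, pos = parts
        else:
            raise ParseError(f"MAP line {ln}: expected 3 or 4 columns")
        markers.append(MarkerDef(id=mid, chrom=chrom, position=int(pos)))
    if len({m.id for m in markers}) != len(markers):
        raise ParseError("duplicate marker id in MAP")
    markers.sort(key=lambda m: (m.chrom, m.position))

    cohort = Cohort(panel=markers)
    ncols = 6 + 2 * len(markers)
    for ln, line in enumerate(_as_lines(ped_source), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != ncols:
            raise ParseError(
                f"PED line {ln}: expected {ncols} columns, got {len(parts)}"
            )
        fam, iid, fa, mo, sex, phe = parts[:6]
        ind = Individual(
            id=iid,
            family_id=fam,
            father_id=None if fa == "0" else fa,
            mother_id=None if mo == "0" else mo,
            sex=sex,
            phenotype_code=phe,
        )
        for k, m in enumerate(markers):
            a, b = parts[6 + 2 * k], parts[7 + 2 * k]
            if a == MISSING_ALLELE or b == MISSING_ALLELE:
                ind.genotypes[m.id] = MISSING_CALL
            else:
                ind.genotypes[m.id] = GenotypeCall(
                    m.allele_index(a, register=True),
                    m.allele_index(b, register=True),
                )
        cohort.add_individual(ind)
    return cohort


def write_pedigree(cohort: Cohort, ped_sink, map_sink) -> None:
    for m in cohort.panel:
        map_sink.write(f"{m.chrom}\t{m.id}\t{m.position}\n")
    for ind in cohort.individuals.values():
        row = [
            ind.family_id,
            ind.id,
            ind.father_id or "0",
            ind.mother_id or "0",
            ind.sex,
            ind.phenotype_code,
        ]
        for m in cohort.panel:
            c = ind.call(m.id)
            if c.missing:
                row += [MISSING_ALLELE, MISSING_ALLELE]
            else:
                row += [m.alleles[c.allele_a], m.alleles[c.allele_b]]
        ped_sink.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf_genotypes(vcf_source, pedigree: Cohort) -> Cohort:
    """Merge GT calls from a VCF onto an existing pedigree structure.

    Sample names must match individual ids; phase separators in GT are
    ignored (calls are stored unphased).  Variants are added to the panel
    if their ID is not already present.
    """
    from cyvcf2 import VCF

    tmp = None
    try:
        if isinstance(vcf_source, (str, os.PathLike)):
            path = os.fspath(vcf_source)
        else:
            tmp = tempfile.NamedTemporaryFile(
                "w", suffix=".vcf", delete=False
            )
            tmp.write(vcf_source.read())
            tmp.close()
            path = tmp.name
        vcf = VCF(path)
        unmatched = [s for s in vcf.samples if s not in pedigree.individuals]
        if unmatched:
            raise ParseError(f"VCF samples absent from pedigree: {unmatched}")
        samples = list(vcf.samples)
        for var in vcf:
            mid = var.ID or f"{var.CHROM}:{var.POS}"
            alleles = [var.REF] + list(var.ALT)
            known = {m.id for m in pedigree.panel}
            if mid in known:
                marker = pedigree.marker(mid)
                for a in alleles:
                    marker.allele_index(a, register=True)
            else:
                marker = MarkerDef(
                    id=mid, chrom=str(var.CHROM), position=var.POS,
                    alleles=alleles,
                )
                pedigree.panel.append(marker)
            idx = {a: marker.alleles.index(a) for a in alleles}
            for s, g in zip(samples, var.genotypes):
                a, b = g[0], g[1]
                call = (
                    MISSING_CALL
                    if a < 0 or b < 0
                    else GenotypeCall(idx[alleles[a]], idx[alleles[b]])
                )
                pedigree.individuals[s].genotypes[mid] = call
        pedigree.panel.sort(key=lambda m: (m.chrom, m.position))
        return pedigree
    finally:
        if tmp is not None:
            os.unlink(tmp.name)


def write_vcf(cohort: Cohort, sink) -> None:
    """Minimal uncompressed VCF 4.2 with GT-only genotype columns."""
    ids = list(cohort.individuals)
    sink.write("##fileformat=VCFv4.2\n")
    sink.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    chroms = sorted({m.chrom for m in cohort.panel})
    for c in chroms:
        sink.write(f"##contig=<ID={c}>\n")
    sink.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(ids)
        + "\n"
    )
    for m in cohort.panel:
        ref, alts = m.alleles[0], m.alleles[1:]
        cols = [
            m.chrom, str(m.position), m.id, ref,
            ",".join(alts) if alts else ".", ".", ".", ".", "GT",
        ]
        for i in ids:
            c = cohort.individuals[i].call(m.id)
            cols.append("./." if c.missing else f"{c.allele_a}/{c.allele_b}")
        sink.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(source) -> pd.DataFrame:
    """Delimited phenotype table -> DataFrame indexed by individual id.

    First column is the id; remaining columns are coerced to numeric with
    non-numeric cells becoming missing.  Duplicate ids are an error.
    """
    if isinstance(source, (str, os.PathLike)):
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(io.StringIO(source.read()), sep=None, engine="python", dtype=str)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dupes = df[id_col][df[id_col].duplicated()].tolist()
        raise ParseError(f"duplicate individual ids in phenotype table: {dupes}")
    df = df.set_index(id_col)
    return df.apply(pd.to_numeric, errors="coerce")


def write_phenotypes(table: pd.DataFrame, sink) -> None:
    table.to_csv(sink, sep="\t", index_label="id")
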