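"""Synthetic study generator: the cis x trans phenotype model and planted-truth inputs.

The cohort generator embodies the working model of the study design: a
cis-regulatory haplotype at the candidate locus is *receptive* to a
trans-acting partner, so the phenotype of a receptive-haplotype carrier is
shaped by their genotype at the trans locus:

    y = mu - scale * (beta_cis * X_cis + beta_int * R * (X_trans - 1)) + u + v + eps

with X_cis the receptive-haplotype dosage, R the receptive exposure
(carrier indicator by default, dosage/2 under additive coding), X_trans the
trans-allele dosage, u a family-shared component (environment + polygenic
background), v an individual component shared by both phenotypes, and eps
independent per phenotype.  The two trans alleles are *functionally
divergent*: the interaction acts through the centered dosage, pushing
receptive carriers toward the mild or severe extreme depending on their
trans genotype.  Phenotypes are scaled like clinical percent-of-predicted
values: lower is worse, so beta > 0 worsens severity.  Because sibs share
cis haplotypes but segregate at the trans locus, a strong interaction
inflates intra-pair variance specifically in receptive pairs — the mechanism
that enriches the receptive haplotype among discordant pairs while
family-driven concordance keeps concordant pairs near the founder frequency.

Every generator is seed-deterministic and emits enough truth for planted-
recovery tests: cohort truth labels, planted mass-spec binders, planted Ct
shifts, and mini-genes with known read-through truncations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, GenotypeCall, Individual, MarkerDef
from .emsapseq import CONSENSUS_PROBE, EMPTY_NEGATIVE, MsSample, ProteinHit
from .transcript import GeneModel
from .validation import (
    CONDITIONS,
    GROWTH_CONTROL,
    SIRNA_SCRAMBLED,
    SIRNA_TARGET,
    TRANSFECTION_CONTROL,
)

# ---------------------------------------------------------------------------
# Cohort simulation

#: Founder-pool preset mirroring the published 5-marker haplotype spectrum:
#: a common receptive haplotype, two mid-frequency alternatives, and two rare
#: haplotypes.  The founder frequency sits below the pooled extreme-pair
#: estimate, which is inflated by the discordant-pair enrichment.
PUBLISHED_PATTERN_POOL = {
    "TTAGA": 0.600,
    "GTCAT": 0.172,
    "GGAAT": 0.124,
    "GTAGA": 0.052,
    "TTCAT": 0.052,
}

CIS_MARKER_IDS = ["rs152730", "rs8044970", "rs63982", "rs152745", "rs152740"]
CIS_MARKER_POSITIONS = [23378, 23380, 23382, 23384, 23386]  # kb-scale toy coords
TRANS_MARKER_ID = "trans_locus"


@dataclass
class SimParams:
    seed: int
    n_families: int = 318
    sibs_per_family: int = 2
    haplotype_pool: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_PATTERN_POOL)
    )
    receptive_haplotype: str = "TTAGA"
    trans_allele_freq: float = 0.5
    beta_cis: float = 0.3
    beta_interaction: float = 1.5
    receptive_coding: str = "dominant"  # or "additive"
    mu: float = 100.0
    noise_sd: float = 4.0
    family_sd: float = 12.0  # shared environment + polygenic background per family
    individual_sd: float = 4.0  # shared across both phenotypes of one sib
    phenotype_scale: float = 10.0  # phenotype units per model unit of beta
    n_filler: int = 0
    filler_copy_prob: float = 0.9

    def __post_init__(self) -> None:
        total = sum(self.haplotype_pool.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"haplotype pool frequencies sum to {total}, not 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.receptive_haplotype not in self.haplotype_pool:
            raise ValueError("receptive haplotype absent from the pool")
        if not 0 < self.trans_allele_freq < 1:
            raise ValueError("degenerate trans allele frequency")


def null_params(seed: int, n_families: int = 318, **kw) -> SimParams:
    """No genetic effect: phenotypes are pure noise around mu."""
    return SimParams(seed=seed, n_families=n_families, beta_cis=0.0,
                     beta_interaction=0.0, **kw)


def alternative_params(seed: int, n_families: int = 318, **kw) -> SimParams:
    """Strong cis x trans interaction scenario (the model's alternative).

    Uses additive receptive coding: homozygosity for the receptive haplotype
    doubles the exposure to the divergent trans alleles, the dosage structure
    that concentrates receptive homozygotes among discordant pairs.
    """
    kw.setdefault("receptive_coding", "additive")
    return SimParams(seed=seed, n_families=n_families, beta_cis=0.3,
                     beta_interaction=4.0, **kw)


@dataclass
class SimulatedCohort:
    cohort: Cohort
    phenotypes: pd.DataFrame  # per individual: two clinical parameters
    truth: pd.DataFrame  # per individual: dosages, carrier flag, haplotypes
    pairs: list[tuple[str, str, str]]  # (family, sib1, sib2)
    params: SimParams


def _make_panel(params: SimParams) -> tuple[list[MarkerDef], list[str]]:
    hap_labels = list(params.haplotype_pool)
    panel = []
    for k, (mid, pos) in enumerate(zip(CIS_MARKER_IDS, CIS_MARKER_POSITIONS)):
        alleles = sorted({h[k] for h in hap_labels})
        panel.append(MarkerDef(id=mid, chrom="16", position=pos, alleles=alleles))
    panel.append(
        MarkerDef(id=TRANS_MARKER_ID, chrom="16", position=68200,
                  alleles=["A", "G"])
    )
    for j in range(params.n_filler):
        panel.append(
            MarkerDef(id=f"filler{j + 1}", chrom="16",
                      position=23390 + 2 * j, alleles=["A", "B"])
        )
    return panel, hap_labels


def simulate_cohort(params: SimParams) -> SimulatedCohort:
    """Nuclear families of sibling pairs under the cis x trans phenotype model."""
    rng = np.random.default_rng(params.seed)
    panel, hap_labels = _make_panel(params)
    pool_freqs = np.array([params.haplotype_pool[h] for h in hap_labels])
    receptive_idx = hap_labels.index(params.receptive_haplotype)

    cohort = Cohort(panel=panel)
    pairs: list[tuple[str, str, str]] = []
    chrom_records = []  # (individual id, cis hap idx pair, trans pair, fillers)

    def draw_filler(n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0, dtype=np.int64)
        out = np.empty(n, dtype=np.int64)
        out[0] = rng.integers(0, 2)
        for j in range(1, n):
            out[j] = (
                out[j - 1]
                if rng.random() < params.filler_copy_prob
                else rng.integers(0, 2)
            )
        return out

    for fam_no in range(1, params.n_families + 1):
        fam = f"F{fam_no:04d}"
        # founder chromosomes: (cis haplotype, linked filler haplotype)
        founder_chroms = {}
        founder_trans = {}
        for pid, role in ((f"{fam}_fa", "father"), (f"{fam}_mo", "mother")):
            founder_chroms[pid] = [
                (int(rng.choice(len(hap_labels), p=pool_freqs)),
                 draw_filler(params.n_filler))
                for _ in range(2)
            ]
            founder_trans[pid] = [
                int(rng.random() < params.trans_allele_freq) for _ in range(2)
            ]
        members = []
        for pid in (f"{fam}_fa", f"{fam}_mo"):
            members.append((pid, None, None))
        sib_ids = [f"{fam}_s{j + 1}" for j in range(params.sibs_per_family)]
        for sid in sib_ids:
            members.append((sid, f"{fam}_fa", f"{fam}_mo"))
        for j in range(len(sib_ids) - 1):
            pairs.append((fam, sib_ids[j], sib_ids[j + 1]))

        for pid, fa, mo in members:
            if fa is None:
                chroms = founder_chroms[pid]
                trans = founder_trans[pid]
            else:
                chroms = [
                    founder_chroms[fa][rng.integers(0, 2)],
                    founder_chroms[mo][rng.integers(0, 2)],
                ]
                trans = [
                    founder_trans[fa][rng.integers(0, 2)],
                    founder_trans[mo][rng.integers(0, 2)],
                ]
            ind = Individual(
                id=pid, family_id=fam,
                father_id=fa, mother_id=mo,
                sex="1" if pid.endswith("_fa") else "2",
            )
            for k, m in enumerate(CIS_MARKER_IDS):
                marker = cohort.panel[k]
                a = marker.alleles.index(hap_labels[chroms[0][0]][k])
                b = marker.alleles.index(hap_labels[chroms[1][0]][k])
                ind.genotypes[m] = GenotypeCall(a, b)
            ind.genotypes[TRANS_MARKER_ID] = GenotypeCall(trans[0], trans[1])
            for j in range(params.n_filler):
                ind.genotypes[f"filler{j + 1}"] = GenotypeCall(
                    int(chroms[0][1][j]), int(chroms[1][1][j])
                )
            cohort.add_individual(ind)
            chrom_records.append(
                (pid, (chroms[0][0], chroms[1][0]), tuple(trans))
            )

    truth_rows = []
    phen_rows = []
    family_effect = {
        fam: rng.normal(0.0, params.family_sd)
        for fam in {pid.rsplit("_", 1)[0] for pid, _, _ in chrom_records}
    }
    for pid, cis_pair, trans_pair in chrom_records:
        x_cis = sum(1 for h in cis_pair if h == receptive_idx)
        if params.receptive_coding == "dominant":
            r = 1.0 if x_cis >= 1 else 0.0
        else:
            r = x_cis / 2.0
        x_trans = float(sum(trans_pair))
        # The trans alleles are functionally divergent: one pushes receptive
        # carriers toward the mild, the other toward the severe extreme, so
        # the interaction acts through the centered dosage (X_trans - 1).
        genetic = -(
            params.beta_cis * x_cis
            + params.beta_interaction * r * (x_trans - 1.0)
        )
        score = params.mu + params.phenotype_scale * genetic
        shared = family_effect[pid.rsplit("_", 1)[0]] + rng.normal(
            0.0, params.individual_sd
        )
        eps = rng.normal(0.0, params.noise_sd, size=2)
        if cohort.individuals[pid].role == "offspring":
            # clinical phenotypes exist for the affected sibs only; centiles
            # are computed over this patient population
            phen_rows.append(
                {"id": pid, "lung_function": score + shared + eps[0],
                 "weight_for_height": score + shared + eps[1]}
            )
        truth_rows.append(
            {
                "id": pid,
                "hap1": hap_labels[cis_pair[0]],
                "hap2": hap_labels[cis_pair[1]],
                "receptive_dosage": x_cis,
                "receptive_carrier": int(x_cis >= 1),
                "trans_dosage": int(x_trans),
                "genetic_score": score,
            }
        )
    phenotypes = pd.DataFrame(phen_rows).set_index("id")
    truth = pd.DataFrame(truth_rows).set_index("id")
    return SimulatedCohort(cohort, phenotypes, truth, pairs, params)


def simulate_trios(
    n_trios: int,
    transmission_ratio: float = 0.5,
    allele_freq: float = 0.5,
    seed: int = 0,
) -> Cohort:
    """Parent-parent-child trios with transmission distortion at one SNP.

    Heterozygous parents transmit the first allele with probability
    ``transmission_ratio`` (0.5 = Mendelian null).
    """
    rng = np.random.default_rng(seed)
    marker = MarkerDef(id="snp1", chrom="1", position=1000, alleles=["A", "B"])
    cohort = Cohort(panel=[marker])
    for t in range(1, n_trios + 1):
        fam = f"T{t:04d}"
        parent_gts = []
        for pid in (f"{fam}_fa", f"{fam}_mo"):
            gt = (
                int(rng.random() >= allele_freq),
                int(rng.random() >= allele_freq),
            )
            parent_gts.append(gt)
            ind = Individual(id=pid, family_id=fam)
            ind.genotypes["snp1"] = GenotypeCall(*gt)
            cohort.add_individual(ind)
        child_alleles = []
        for gt in parent_gts:
            if gt[0] == gt[1]:
                child_alleles.append(gt[0])
            else:
                child_alleles.append(
                    0 if rng.random() < transmission_ratio else 1
                )
        child = Individual(
            id=f"{fam}_c", family_id=fam,
            father_id=f"{fam}_fa", mother_id=f"{fam}_mo",
        )
        child.genotypes["snp1"] = GenotypeCall(*child_alleles)
        cohort.add_individual(child)
    return cohort


# ---------------------------------------------------------------------------
# EMSA-PSeq simulation


@dataclass
class PlantedBinder:
    protein_id: str
    snp_id: str
    abundance_ppm: float = 50.0
    na_binding: bool = True
    spliceosome: bool = False
    mascot_score: float = 100.0


@dataclass
class EmsaPseqDataset:
    hits: list[ProteinHit]
    samples: list[MsSample]
    abundance: dict[str, float]
    annotation: pd.DataFrame
    planted: list[PlantedBinder]


def default_sample_layout(
    snps=("rs152730", "rs152731", "rs152744"),
    alleles_per_snp=2,
    replicates=3,
    n_consensus=2,
    n_negative=5,
    n_denaturing=3,
) -> list[MsSample]:
    """The 25-native-sample parallel design plus denaturing-gel extras.

    3 SNP probes x 2 alleles x 3 replicates + 2 consensus positive controls
    + 5 empty negative controls = 25 native samples; denaturing samples are
    appended last (the #26-28 analog).
    """
    samples = []
    n = 0
    for snp in snps:
        for allele_no in range(alleles_per_snp):
            for _ in range(replicates):
                n += 1
                samples.append(
                    MsSample(
                        sample_id=f"S{n:02d}",
                        probe=(snp, "CT"[allele_no % 2]),
                    )
                )
    for _ in range(n_consensus):
        n += 1
        samples.append(MsSample(sample_id=f"S{n:02d}", control=CONSENSUS_PROBE))
    for _ in range(n_negative):
        n += 1
        samples.append(MsSample(sample_id=f"S{n:02d}", control=EMPTY_NEGATIVE))
    for k in range(n_denaturing):
        snp = snps[k % len(snps)]
        n += 1
        samples.append(
            MsSample(sample_id=f"S{n:02d}", probe=(snp, "C"), gel="denaturing")
        )
    return samples


def simulate_emsapseq(
    planted: list[PlantedBinder],
    n_background: int = 30,
    dropout: float = 0.3,
    seed: int = 0,
    samples: list[MsSample] | None = None,
    ppm_cutoff: float = 200.0,
) -> EmsaPseqDataset:
    """Planted SNP-specific binders on a background of realistic contaminants.

    Each background protein occupies one disqualifying stratum — presence in
    an empty negative control, abundance at/above the cutoff, or no
    nucleic-acid-binding annotation — so the planted binders are the only
    proteins that can survive the filter cascade.  Backgrounds appear across
    samples with the stated dropout.
    """
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = default_sample_layout()
    snps = sorted({s.probe[0] for s in samples if s.probe})
    for pb in planted:
        if pb.snp_id not in snps:
            raise ValueError(f"planted binder targets unknown SNP {pb.snp_id}")
    negatives = [s for s in samples if s.control == EMPTY_NEGATIVE]
    if len(snps) < 2 or not negatives:
        raise ValueError("need >= 2 SNP probes and >= 1 empty negative control")

    hits: list[ProteinHit] = []
    abundance: dict[str, float] = {}
    ann_rows = []

    for pb in planted:
        for s in samples:
            if s.probe and s.probe[0] == pb.snp_id and s.gel == "native":
                score = max(10.0, rng.normal(pb.mascot_score, 10.0))
                hits.append(
                    ProteinHit(s.sample_id, pb.protein_id, score,
                               int(rng.integers(2, 8)))
                )
        abundance[pb.protein_id] = pb.abundance_ppm
        ann_rows.append(
            {"protein_id": pb.protein_id, "nucleic_acid_binding": pb.na_binding,
             "spliceosome_component": pb.spliceosome}
        )

    strata = ["negative_control", "high_abundance", "non_na_binding"]
    for b in range(n_background):
        pid = f"BG{b + 1:03d}"
        stratum = strata[b % 3]
        present = [s for s in samples if rng.random() > dropout]
        if stratum == "negative_control":
            neg = negatives[int(rng.integers(0, len(negatives)))]
            if all(s.sample_id != neg.sample_id for s in present):
                present.append(neg)
            abundance[pid] = float(rng.uniform(5, ppm_cutoff - 10))
            na = True
        elif stratum == "high_abundance":
            present = [s for s in present if s.control != EMPTY_NEGATIVE]
            abundance[pid] = float(rng.uniform(ppm_cutoff, 5 * ppm_cutoff))
            na = True
        else:
            present = [s for s in present if s.control != EMPTY_NEGATIVE]
            abundance[pid] = float(rng.uniform(5, ppm_cutoff - 10))
            na = False
        for s in present:
            hits.append(
                ProteinHit(s.sample_id, pid,
                           max(10.0, rng.normal(60.0, 15.0)),
                           int(rng.integers(1, 5)))
            )
        ann_rows.append(
            {"protein_id": pid, "nucleic_acid_binding": na,
             "spliceosome_component": bool(stratum == "high_abundance" and b % 6 == 1)}
        )
    annotation = pd.DataFrame(ann_rows).set_index("protein_id")
    return EmsaPseqDataset(hits, samples, abundance, annotation, planted)


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_ct(
    condition_effects: dict[tuple[str, str], float],
    baselines: dict[str, float] | None = None,
    noise_sd: float = 0.15,
    sample_sd: float = 0.3,
    tech_sd: float = 0.1,
    n_replicates: int = 3,
    n_plates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table with technical duplicates under planted condition effects.

    ``condition_effects[(condition, amplicon)]`` shifts the Ct baseline (a
    negative shift means more template, e.g. a knockdown of a repressor).  A
    per-plate sample effect is shared by all amplicons of that plate and
    cancels in dCt, emulating loading variation.
    """
    rng = np.random.default_rng(seed)
    if baselines is None:
        baselines = {
            "target_wildtype": 28.0,
            "target_alternative": 32.0,
            "housekeeping": 20.0,
        }
    rows = []
    for rep_no in range(1, n_replicates + 1):
        rep = f"bio{rep_no}"
        for cond in CONDITIONS:
            for plate in range(1, n_plates + 1):
                sample_shift = rng.normal(0.0, sample_sd)
                for amp, base in baselines.items():
                    mean_ct = (
                        base
                        + condition_effects.get((cond, amp), 0.0)
                        + sample_shift
                        + rng.normal(0.0, noise_sd)
                    )
                    for tech in (1, 2):
                        rows.append(
                            {
                                "replicate": rep,
                                "plate": plate,
                                "condition": cond,
                                "amplicon": amp,
                                "tech_rep": tech,
                                "ct": mean_ct + rng.normal(0.0, tech_sd),
                            }
                        )
    return pd.DataFrame(rows)


def knockdown_effects(
    shift_wildtype: float = -1.2, shift_alternative: float = -1.2
) -> dict[tuple[str, str], float]:
    """Planted siRNA effect on the target amplicons (Ct cycles)."""
    return {
        (SIRNA_TARGET, "target_wildtype"): shift_wildtype,
        (SIRNA_TARGET, "target_alternative"): shift_alternative,
    }


# ---------------------------------------------------------------------------
# Mini-gene construction


STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass
class MiniGene:
    model: GeneModel
    genome: str
    truth: dict


def make_minigene(
    seed: int,
    exon_sizes: list[int],
    cds_start: int,
    protein_codons: int,
    readthrough_exon: int,
    intron_stop_codons: int,
    intron_size: int = 120,
) -> MiniGene:
    """Toy gene with a planted read-through truncation of known length.

    The spliced CDS encodes ``protein_codons`` residues plus a stop.  The
    intron after ``readthrough_exon`` carries, continuing in the reading
    frame active at the junction, ``intron_stop_codons`` stop-free codons and
    then a planted stop.  The junction frame follows from ``exon_sizes`` and
    ``cds_start``; truth records whether it is codon-aligned and the expected
    read-through protein length.
    """
    rng = np.random.default_rng(seed)
    transcript_len = sum(exon_sizes)
    cds_len = 3 * (protein_codons + 1)
    if cds_start + cds_len - 1 > transcript_len:
        raise ValueError("CDS does not fit in the transcript")
    if not 1 <= readthrough_exon < len(exon_sizes):
        raise ValueError("readthrough_exon out of range")

    def rand_bases(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    def rand_codons(n: int) -> str:
        return "".join(rng.choice(_CODONS, size=n))

    cds = "ATG" + rand_codons(protein_codons - 1) + "TAA"
    spliced = rand_bases(cds_start - 1) + cds
    spliced += rand_bases(transcript_len - len(spliced))

    junction = sum(exon_sizes[:readthrough_exon])
    frame_offset = (junction - cds_start + 1) % 3
    in_frame = frame_offset == 0 and junction >= cds_start

    # build the retained intron
    retained = ""
    if in_frame:
        retained = rand_codons(intron_stop_codons) + "TAA"
    else:
        completion = 3 - frame_offset
        retained = "C" * completion + rand_codons(intron_stop_codons) + "TAA"
    retained += rand_bases(max(0, intron_size - len(retained)))
    retained = retained[:intron_size] if len(retained) <= intron_size else retained

    # assemble the genome: exon chunks from the spliced sequence + introns
    genome_parts = []
    exons = []
    cursor_t = 0  # transcript cursor
    cursor_g = 0  # genome cursor
    for k, size in enumerate(exon_sizes):
        chunk = spliced[cursor_t : cursor_t + size]
        exons.append((cursor_g + 1, cursor_g + size))
        genome_parts.append(chunk)
        cursor_t += size
        cursor_g += size
        if k < len(exon_sizes) - 1:
            intron = (
                retained
                if k + 1 == readthrough_exon
                else rand_bases(intron_size)
            )
            genome_parts.append(intron)
            cursor_g += len(intron)
    genome = "".join(genome_parts)

    wildtype_len = protein_codons
    if in_frame:
        readthrough_len = (junction - cds_start + 1) // 3 + intron_stop_codons
        past = intron_stop_codons
    else:
        # straddling codon + completion codons before the planted stop
        readthrough_len = (junction - cds_start + 1 - frame_offset) // 3 + 1 + intron_stop_codons
        past = 0
    truth = {
        "wildtype_protein_length": wildtype_len,
        "readthrough_protein_length": readthrough_len,
        "residues_past_junction": past,
        "junction": junction,
        "in_frame": in_frame,
    }
    model = GeneModel(gene_id="minigene", strand="+", exons=exons, cds_start=cds_start)
    return MiniGene(model=model, genome=genome, truth=truth)


def scnn1b_minigene_analog(seed: int = 0) -> MiniGene:
    """Synthetic analog of the candidate gene's read-through architecture.

    A 640-codon CDS over 5 exons whose third splice donor is codon-aligned
    195 codons into the ORF; the retained intron encodes 26 stop-free codons
    before a planted stop, so the read-through protein is 221 aa with 26
    intron-derived residues.  This is a constructed stand-in for the real
    gene model (which would require genome + annotation downloads), built so
    the same code path exercises the published truncation arithmetic.
    """
    return make_minigene(
        seed=seed,
        exon_sizes=[200, 245, 200, 700, 650],
        cds_start=61,
        protein_codons=640,
        readthrough_exon=3,
        intron_stop_codons=26,
        intron_size=120,
    )
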