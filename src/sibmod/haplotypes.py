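"""EM estimation of multilocus haplotype frequencies from unphased genotypes.

The phase-ambiguity model is the classical multinomial EM (Excoffier-Slatkin):
an unphased multilocus genotype is explained by every compatible unordered
haplotype pair (h1, h2), with probability f(h1) * f(h2) * (2 if h1 != h2 else 1)
under Hardy-Weinberg.  Individuals with missing calls contribute through all
compatible completions rather than being dropped.  A *training-set* mode fixes
the frequencies to a prior table and only computes explanation weights,
mirroring designs where a larger training cohort anchors rare-haplotype
assignment.

Haplotypes are tuples of allele indices, ordered lexicographically for
deterministic output; initialization is the product of single-marker allele
frequencies, so the fit is deterministic given the data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort

Haplotype = tuple[int, ...]


@dataclass
class HaplotypeFreqTable:
    marker_ids: list[str]
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    log_likelihood: float
    n_chromosomes: float
    converged: bool
    iterations: int

    def freq(self, hap: Haplotype) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(hap)])
        except ValueError:
            return 0.0

    def as_dict(self) -> dict[Haplotype, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.frequencies)}


@dataclass
class ExplanationList:
    individual_id: str
    explanations: list[tuple[tuple[Haplotype, Haplotype], float]]


@dataclass
class LDResult:
    marker_a: str
    marker_b: str
    D: float
    D_prime: float
    maf_a: float
    maf_b: float


class PhaseModel:
    """Phase-explanation structure for a marker subset, shared across EM runs.

    Individuals are collapsed into distinct genotype classes; each class
    carries its compatible unordered haplotype pairs as index arrays so a
    single EM iteration is a handful of vectorized operations.  The same
    model (hence the same haplotype universe and likelihood scale) is reused
    for pooled and per-group fits inside permutation loops.
    """

    def __init__(self, genotype_vectors, n_alleles: list[int]):
        self.n_alleles = list(n_alleles)
        self.n_markers = len(n_alleles)
        classes: dict[tuple, int] = {}
        self.class_of: list[int] = []
        for vec in genotype_vectors:
            key = tuple(
                None if g is None else tuple(sorted(g)) for g in vec
            )
            if key not in classes:
                classes[key] = len(classes)
            self.class_of.append(classes[key])
        self.class_keys = list(classes)
        self.n_classes = len(self.class_keys)
        self.class_of = np.asarray(self.class_of, dtype=np.int64)

        hap_index: dict[Haplotype, int] = {}
        pair_i, pair_j, mult, cls_idx = [], [], [], []
        for ci, key in enumerate(self.class_keys):
            for h1, h2 in self._compatible_pairs(key):
                for h in (h1, h2):
                    if h not in hap_index:
                        hap_index[h] = len(hap_index)
                pair_i.append(hap_index[h1])
                pair_j.append(hap_index[h2])
                mult.append(1.0 if h1 == h2 else 2.0)
                cls_idx.append(ci)
        # reorder haplotypes lexicographically for deterministic output
        haps = sorted(hap_index)
        remap = np.empty(len(haps), dtype=np.int64)
        for new, h in enumerate(haps):
            remap[hap_index[h]] = new
        self.haplotypes: list[Haplotype] = haps
        self.n_haplotypes = len(haps)
        self.pair_i = remap[np.asarray(pair_i, dtype=np.int64)]
        self.pair_j = remap[np.asarray(pair_j, dtype=np.int64)]
        self.mult = np.asarray(mult)
        self.pair_class = np.asarray(cls_idx, dtype=np.int64)

    def _compatible_pairs(self, key):
        per_marker = []
        for m, g in enumerate(key):
            if g is None:
                k = self.n_alleles[m]
                per_marker.append(
                    [(x, y) for x in range(k) for y in range(k)]
                )
            else:
                a, b = g
                per_marker.append([(a, b)] if a == b else [(a, b), (b, a)])
        seen = set()
        for combo in itertools.product(*per_marker):
            h1 = tuple(x for x, _ in combo)
            h2 = tuple(y for _, y in combo)
            if h2 < h1:
                h1, h2 = h2, h1
            if (h1, h2) not in seen:
                seen.add((h1, h2))
                yield h1, h2

    def class_counts(self, individual_mask=None) -> np.ndarray:
        if individual_mask is None:
            return np.bincount(self.class_of, minlength=self.n_classes).astype(float)
        return np.bincount(
            self.class_of[individual_mask], minlength=self.n_classes
        ).astype(float)

    def default_init(self, counts: np.ndarray) -> np.ndarray:
        """Product of single-marker allele frequencies (uniform where unobserved)."""
        hap_arr = np.asarray(self.haplotypes)
        f = np.ones(self.n_haplotypes)
        for m in range(self.n_markers):
            k = self.n_alleles[m]
            ac = np.zeros(k)
            for ci, key in enumerate(self.class_keys):
                g = key[m]
                if g is not None:
                    ac[g[0]] += counts[ci]
                    ac[g[1]] += counts[ci]
            ac = ac + (1.0 if ac.sum() == 0 else 0.0)
            af = (ac + 1e-9) / (ac + 1e-9).sum()
            f *= af[hap_arr[:, m]]
        return f / f.sum()

    def log_likelihood(self, counts: np.ndarray, f: np.ndarray) -> float:
        pp = self.mult * f[self.pair_i] * f[self.pair_j]
        denom = np.bincount(self.pair_class, pp, self.n_classes)
        active = counts > 0
        with np.errstate(divide="ignore"):
            ll = counts[active] @ np.log(denom[active])
        return float(ll)

    def em(
        self,
        counts: np.ndarray,
        init: np.ndarray | None = None,
        fixed: np.ndarray | None = None,
        tol: float = 1e-8,
        max_iter: int = 1000,
    ) -> tuple[np.ndarray, float, bool, int]:
        """Run EM on genotype-class counts; returns (f, ll, converged, iters).

        ``fixed`` switches to training-set mode: frequencies stay at the
        given values and only the likelihood is evaluated.
        """
        n_chrom = 2.0 * counts.sum()
        if fixed is not None:
            return fixed, self.log_likelihood(counts, fixed), True, 0
        f = self.default_init(counts) if init is None else init.copy()
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            pp = self.mult * f[self.pair_i] * f[self.pair_j]
            denom = np.bincount(self.pair_class, pp, self.n_classes)
            active = denom > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                w = pp * np.where(active, counts / np.where(active, denom, 1.0), 0.0)[
                    self.pair_class
                ]
            new = np.bincount(self.pair_i, w, self.n_haplotypes)
            new += np.bincount(self.pair_j, w, self.n_haplotypes)
            f = new / n_chrom
            ll = counts[counts > 0] @ np.log(
                np.maximum(denom[counts > 0], 1e-300)
            )
            if ll - ll_prev < tol and it > 1:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        return f, float(ll_prev), converged, it

    def posterior_pairs(self, f: np.ndarray):
        """Per-class normalized explanation weights under frequencies ``f``."""
        pp = self.mult * f[self.pair_i] * f[self.pair_j]
        denom = np.bincount(self.pair_class, pp, self.n_classes)
        out = []
        for ci in range(self.n_classes):
            sel = np.flatnonzero(self.pair_class == ci)
            if denom[ci] > 0:
                w = pp[sel] / denom[ci]
            else:
                w = np.full(sel.size, 1.0 / sel.size)
            out.append(
                [
                    ((self.haplotypes[self.pair_i[s]], self.haplotypes[self.pair_j[s]]), float(wi))
                    for s, wi in zip(sel, w)
                ]
            )
        return out


def _model_for(cohort: Cohort, marker_ids: list[str], ids=None):
    ids, vecs = cohort.genotype_vectors(marker_ids, ids)
    n_alleles = [max(len(cohort.marker(m).alleles), 1) for m in marker_ids]
    return ids, PhaseModel(vecs, n_alleles)


def em_haplotype_frequencies(
    cohort: Cohort,
    marker_ids: list[str],
    prior: HaplotypeFreqTable | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    founders_only: bool = False,
) -> HaplotypeFreqTable:
    """Estimate multilocus haplotype frequencies for a marker subset.

    With ``prior`` given, frequencies are fixed to the prior table
    (training-set mode) and only the likelihood is evaluated.  By default all
    individuals enter the estimation (pooled case+reference convention);
    ``founders_only`` restricts to founders.
    """
    if not marker_ids:
        raise ValueError("empty marker set")
    ids = None
    if founders_only:
        ids = [i for i, ind in cohort.individuals.items() if ind.role == "founder"]
    ids, model = _model_for(cohort, marker_ids, ids)
    counts = model.class_counts()
    if counts.sum() == 0:
        raise ValueError("no genotyped individuals for the marker set")
    fixed = None
    if prior is not None:
        pdict = prior.as_dict()
        fixed = np.array([pdict.get(h, 0.0) for h in model.haplotypes])
        s = fixed.sum()
        if s <= 0:
            raise ValueError("prior covers none of the compatible haplotypes")
        fixed = fixed / s
    f, ll, converged, iters = model.em(counts, fixed=fixed, tol=tol, max_iter=max_iter)
    keep = np.flatnonzero(f > 1e-12) if fixed is None else np.arange(f.size)
    return HaplotypeFreqTable(
        marker_ids=list(marker_ids),
        haplotypes=[model.haplotypes[k] for k in keep],
        frequencies=f[keep] / f[keep].sum(),
        log_likelihood=ll,
        n_chromosomes=2.0 * counts.sum(),
        converged=converged,
        iterations=iters,
    )


def explanation_lists(
    cohort: Cohort, freq_table: HaplotypeFreqTable, ids=None
) -> list[ExplanationList]:
    """Weighted phase explanations per individual under fixed frequencies."""
    ids, model = _model_for(cohort, freq_table.marker_ids, ids)
    fdict = freq_table.as_dict()
    f = np.array([fdict.get(h, 0.0) for h in model.haplotypes])
    per_class = model.posterior_pairs(f)
    pp = model.mult * f[model.pair_i] * f[model.pair_j]
    class_total = np.bincount(model.pair_class, pp, model.n_classes)
    out = []
    for i, ind_id in enumerate(ids):
        ci = model.class_of[i]
        if class_total[ci] == 0.0:
            warnings.warn(
                f"{ind_id}: incompatible with all positive-frequency haplotypes; "
                "uniform explanation weights",
                stacklevel=2,
            )
        out.append(ExplanationList(ind_id, per_class[ci]))
    return out


# ---------------------------------------------------------------------------
# Marker informativeness and linkage disequilibrium


def allele_frequencies(cohort: Cohort, marker_id: str, ids=None) -> np.ndarray:
    marker = cohort.marker(marker_id)
    counts = np.zeros(max(len(marker.alleles), 1))
    pool = cohort.individuals.values() if ids is None else (
        cohort.individuals[i] for i in ids
    )
    for ind in pool:
        c = ind.call(marker_id)
        if not c.missing:
            counts[c.allele_a] += 1
            counts[c.allele_b] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def minor_allele_frequency(cohort: Cohort, marker_id: str) -> float:
    """MAF = 1 - frequency of the most common allele (multiallelic-safe)."""
    af = allele_frequencies(cohort, marker_id)
    return float(1.0 - af.max()) if af.sum() > 0 else 0.0


def informative_markers(cohort: Cohort, maf_threshold: float = 0.4) -> list[str]:
    """Markers with MAF strictly above the threshold, in panel order."""
    return [
        m.id
        for m in cohort.panel
        if minor_allele_frequency(cohort, m.id) > maf_threshold
    ]


def d_prime(cohort: Cohort, marker_a: str, marker_b: str) -> LDResult:
    """Pairwise D and D' from EM two-marker haplotype frequencies.

    Multiallelic markers are reduced to major-allele vs rest.  Monomorphic
    markers leave D' undefined and raise.
    """
    afa = allele_frequencies(cohort, marker_a)
    afb = allele_frequencies(cohort, marker_b)
    if afa.max() >= 1.0 or afb.max() >= 1.0 or afa.sum() == 0 or afb.sum() == 0:
        raise ValueError("monomorphic marker: D' undefined")
    major_a, major_b = int(afa.argmax()), int(afb.argmax())
    table = em_haplotype_frequencies(cohort, [marker_a, marker_b])
    p_ab = sum(
        f
        for h, f in table.as_dict().items()
        if h[0] == major_a and h[1] == major_b
    )
    p_a = sum(f for h, f in table.as_dict().items() if h[0] == major_a)
    p_b = sum(f for h, f in table.as_dict().items() if h[1] == major_b)
    return ld_from_frequencies(p_ab, p_a, p_b, marker_a, marker_b)


def ld_from_frequencies(
    p_ab: float, p_a: float, p_b: float, marker_a: str = "A", marker_b: str = "B"
) -> LDResult:
    """D and D' from the joint and marginal frequencies of two alleles."""
    D = p_ab - p_a * p_b
    if D >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dp = 0.0 if dmax == 0 else abs(D) / dmax
    return LDResult(
        marker_a=marker_a,
        marker_b=marker_b,
        D=float(D),
        D_prime=float(min(dp, 1.0)),
        maf_a=float(min(p_a, 1 - p_a)),
        maf_b=float(min(p_b, 1 - p_b)),
    )


def define_blocks(
    cohort: Cohort, marker_ids: list[str], threshold: float = 0.8
) -> list[list[str]]:
    """Greedy haplotype blocks: adjacent markers join while pairwise D' > threshold.

    Markers are taken in panel (chrom, position) order; a block never spans
    chromosomes.
    """
    ordered = [m.id for m in cohort.panel if m.id in set(marker_ids)]
    blocks: list[list[str]] = []
    for mid in ordered:
        chrom = cohort.marker(mid).chrom
        if blocks and cohort.marker(blocks[-1][-1]).chrom == chrom:
            ld = d_prime(cohort, blocks[-1][-1], mid)
            if ld.D_prime > threshold:
                blocks[-1].append(mid)
                continue
        blocks.append([mid])
    return blocks


def block_intervals(cohort: Cohort, blocks: list[list[str]]):
    """BED-like (chrom, start, end, markers) rows for a block partition."""
    rows = []
    for b in blocks:
        ms = [cohort.marker(m) for m in b]
        rows.append(
            (ms[0].chrom, min(m.position for m in ms), max(m.position for m in ms), b)
        )
    return rows
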