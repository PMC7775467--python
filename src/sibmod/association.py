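"""Haplotype association contrasts with pair-preserving permutation statistics.

Two groups of individuals (e.g. the sibs of discordant vs concordant pairs,
or mild vs severe sibs within discordant pairs) are contrasted on the
haplotype distribution of a marker subset using a likelihood-ratio statistic
on EM-estimated frequencies:

    LR = 2 * (LL1(f1_hat) + LL2(f2_hat) - LL_pooled(f_pooled_hat))

Significance is always assessed by permutation, so the statistic's null
distribution need never be chi-square:

* ``group_flip`` reassigns a whole sibling pair's group with probability 1/2,
  keeping both sibs together (the pair is the exchangeable sampling unit);
* ``within_pair_swap`` swaps the mild/severe labels inside each discordant
  pair independently with probability 1/2.

Multiple testing over marker combinations uses Westfall-Young min-p
correction: the same relabelings drive every combination, the per-permutation
minimum raw p forms the reference distribution.  The pooled data set is
label-invariant, so pooled frequencies are estimated once per combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .cohort import Cohort
from .haplotypes import HaplotypeFreqTable, PhaseModel, _model_for
from .phenotypes import SibPair


@dataclass
class PermutationPlan:
    unit: str = "pair"
    n_perm: int = 1000
    seed: int | None = None
    scheme: str = "group_flip"  # or "within_pair_swap"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme not in ("group_flip", "within_pair_swap"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for permutation runs")


@dataclass
class AssociationResult:
    marker_ids: list[str]
    statistic: float
    p_raw: float
    p_corr: float | None = None
    group_tables: dict[str, HaplotypeFreqTable] = field(default_factory=dict)
    n_perm: int = 0
    seed: int | None = None


@dataclass
class SegmentSignal:
    left: str
    right: str
    p_raw: float


class _Contrast:
    """LR machinery for one marker combination over a fixed individual pool."""

    def __init__(self, cohort: Cohort, marker_ids, ids):
        self.ids, self.model = _model_for(cohort, marker_ids, list(ids))
        self.index = {i: k for k, i in enumerate(self.ids)}
        self.marker_ids = list(marker_ids)
        pooled_counts = self.model.class_counts()
        self._monomorphic = self.model.n_haplotypes < 2
        self.pooled_f, self.pooled_ll, _, _ = self.model.em(pooled_counts)

    def counts_for(self, ids) -> np.ndarray:
        idx = np.asarray([self.index[i] for i in ids], dtype=np.int64)
        return self.model.class_counts(idx)

    def lr(self, counts1: np.ndarray, counts2: np.ndarray) -> float:
        if self._monomorphic:
            return 0.0
        _, ll1, _, _ = self.model.em(counts1)
        _, ll2, _, _ = self.model.em(counts2)
        # pooled is label-invariant: evaluate its ll on these counts
        llp = self.model.log_likelihood(counts1 + counts2, self.pooled_f)
        return max(0.0, 2.0 * (ll1 + ll2 - llp))

    def freq_table(self, counts: np.ndarray) -> HaplotypeFreqTable:
        f, ll, conv, it = self.model.em(counts)
        keep = np.flatnonzero(f > 1e-12)
        return HaplotypeFreqTable(
            marker_ids=self.marker_ids,
            haplotypes=[self.model.haplotypes[k] for k in keep],
            frequencies=f[keep] / f[keep].sum(),
            log_likelihood=ll,
            n_chromosomes=2.0 * counts.sum(),
            converged=conv,
            iterations=it,
        )


def lr_statistic(
    cohort: Cohort, group1_ids, group2_ids, marker_ids
) -> float:
    """Likelihood-ratio statistic between two groups of individuals."""
    if not group1_ids or not group2_ids:
        raise ValueError("both groups must be non-empty")
    contrast = _Contrast(cohort, marker_ids, list(group1_ids) + list(group2_ids))
    if contrast._monomorphic:
        warnings.warn("monomorphic marker combination: statistic 0", stacklevel=2)
    return contrast.lr(
        contrast.counts_for(group1_ids), contrast.counts_for(group2_ids)
    )


def _pair_members(
    pairs1: list[SibPair],
    pairs2: list[SibPair] | None,
    scheme: str,
):
    """Baseline (group1 ids per pair, group2 ids per pair) member lists."""
    if scheme == "group_flip":
        if pairs2 is None:
            raise ValueError("group_flip needs two labelled pair sets")
        if len(pairs1) < 2 or len(pairs2) < 2:
            raise ValueError("need >= 2 pairs per group")
        units = [(p, 0) for p in pairs1] + [(p, 1) for p in pairs2]
        # canonical unit order: the permutation stream must not depend on
        # which set was labelled group1 (p is invariant to label interchange)
        units.sort(key=lambda u: (u[0].family_id, u[0].sib1_id, u[0].sib2_id))
        members = [[p.sib1_id, p.sib2_id] for p, _ in units]
        base = np.array([g for _, g in units], dtype=np.int64)
    else:  # within_pair_swap: sib1 = mild, sib2 = severe
        if len(pairs1) < 2:
            raise ValueError("need >= 2 discordant pairs")
        members = [[p.sib1_id] for p in pairs1] + [[p.sib2_id] for p in pairs1]
        n = len(pairs1)
        base = np.concatenate([np.zeros(n, np.int64), np.ones(n, np.int64)])
    return members, base


def _apply_flips(base: np.ndarray, flips: np.ndarray, scheme: str) -> np.ndarray:
    """Group assignment per unit after applying a 0/1 flip vector."""
    if scheme == "group_flip":
        return base ^ flips
    n = base.size // 2
    full = np.concatenate([flips, flips])
    return base ^ full


def _perm_stats(
    contrast: _Contrast,
    members,
    base: np.ndarray,
    flip_matrix: np.ndarray,
    scheme: str,
):
    """Observed statistic + statistic per permutation (shared flip matrix)."""
    member_idx = [
        np.asarray([contrast.index[i] for i in ms], dtype=np.int64)
        for ms in members
    ]

    def counts_pair(assign):
        c1 = np.zeros(contrast.model.n_classes)
        c2 = np.zeros(contrast.model.n_classes)
        for u, g in enumerate(assign):
            tgt = c1 if g == 0 else c2
            cls = contrast.model.class_of[member_idx[u]]
            np.add.at(tgt, cls, 1.0)
        return c1, c2

    obs = contrast.lr(*counts_pair(base))
    stats = np.empty(flip_matrix.shape[0])
    for b in range(flip_matrix.shape[0]):
        assign = _apply_flips(base, flip_matrix[b], scheme)
        stats[b] = contrast.lr(*counts_pair(assign))
    return obs, stats


def _add_one_p(obs: float, stats: np.ndarray) -> float:
    return (1.0 + float((stats >= obs - 1e-12).sum())) / (1.0 + stats.size)


def permutation_pvalue(
    cohort: Cohort,
    marker_ids,
    pairs1: list[SibPair],
    pairs2: list[SibPair] | None,
    plan: PermutationPlan,
) -> AssociationResult:
    """Permutation p for one marker combination under a pair-preserving scheme."""
    members, base = _pair_members(pairs1, pairs2, plan.scheme)
    all_ids = [i for ms in members for i in ms]
    contrast = _Contrast(cohort, marker_ids, all_ids)
    rng = np.random.default_rng(plan.seed)
    n_units = len(pairs1) if plan.scheme == "within_pair_swap" else len(members)
    flips = rng.integers(0, 2, size=(plan.n_perm, n_units), dtype=np.int64)
    obs, stats = _perm_stats(contrast, members, base, flips, plan.scheme)
    g1 = [i for ms, g in zip(members, base) for i in ms if g == 0]
    g2 = [i for ms, g in zip(members, base) for i in ms if g == 1]
    return AssociationResult(
        marker_ids=list(marker_ids),
        statistic=obs,
        p_raw=_add_one_p(obs, stats),
        group_tables={
            "group1": contrast.freq_table(contrast.counts_for(g1)),
            "group2": contrast.freq_table(contrast.counts_for(g2)),
        },
        n_perm=plan.n_perm,
        seed=plan.seed,
    )


def corrected_pvalues(
    cohort: Cohort,
    combinations: list[list[str]],
    pairs1: list[SibPair],
    pairs2: list[SibPair] | None,
    plan: PermutationPlan,
) -> list[AssociationResult]:
    """Westfall-Young min-p corrected p-values over marker combinations.

    One flip matrix drives all combinations (required for min-p coherence).
    For each permutation b, the raw p of every combination is computed within
    the permutation distribution; p_corr(c) is the add-one fraction of
    permutations whose minimum raw p falls at or below p_raw(c).
    """
    if not combinations:
        raise ValueError("need at least one marker combination")
    members, base = _pair_members(pairs1, pairs2, plan.scheme)
    all_ids = [i for ms in members for i in ms]
    rng = np.random.default_rng(plan.seed)
    n_units = len(pairs1) if plan.scheme == "within_pair_swap" else len(members)
    flips = rng.integers(0, 2, size=(plan.n_perm, n_units), dtype=np.int64)

    results = []
    perm_p = np.empty((len(combinations), plan.n_perm))
    for ci, marker_ids in enumerate(combinations):
        contrast = _Contrast(cohort, marker_ids, all_ids)
        obs, stats = _perm_stats(contrast, members, base, flips, plan.scheme)
        order = np.sort(stats)
        count_ge = stats.size - np.searchsorted(order, stats - 1e-12, side="left")
        perm_p[ci] = (1.0 + count_ge) / (1.0 + stats.size)
        g1 = [i for ms, g in zip(members, base) for i in ms if g == 0]
        g2 = [i for ms, g in zip(members, base) for i in ms if g == 1]
        results.append(
            AssociationResult(
                marker_ids=list(marker_ids),
                statistic=obs,
                p_raw=_add_one_p(obs, stats),
                group_tables={
                    "group1": contrast.freq_table(contrast.counts_for(g1)),
                    "group2": contrast.freq_table(contrast.counts_for(g2)),
                },
                n_perm=plan.n_perm,
                seed=plan.seed,
            )
        )
    min_p = perm_p.min(axis=0)
    for res in results:
        corr = (1.0 + float((min_p <= res.p_raw + 1e-12).sum())) / (
            1.0 + plan.n_perm
        )
        res.p_corr = max(corr, res.p_raw)
    return results


# ---------------------------------------------------------------------------
# Transmission disequilibrium test


def tdt(cohort: Cohort, marker_id: str, affected_ids=None):
    """TDT counts of transmissions (b) / non-transmissions (c) of the first allele.

    Only heterozygous parents of genotyped affected offspring contribute.
    Ambiguous double-heterozygote configurations are averaged over the
    consistent transmission assignments (the classical 1 A : 1 a split).
    Returns (b, c, chi_square, p); b + c = 0 leaves the test undefined (NaN).
    """
    marker = cohort.marker(marker_id)
    if len(marker.alleles) > 2:
        raise ValueError("TDT requires a biallelic marker")
    affected = (
        [i for i, ind in cohort.individuals.items() if ind.role == "offspring"]
        if affected_ids is None
        else list(affected_ids)
    )
    b = c = 0.0
    for iid in affected:
        child = cohort.individuals[iid]
        fa = cohort.individuals.get(child.father_id or "")
        mo = cohort.individuals.get(child.mother_id or "")
        if fa is None or mo is None:
            continue
        gc, gf, gm = (
            child.call(marker_id), fa.call(marker_id), mo.call(marker_id),
        )
        if gc.missing or gf.missing or gm.missing:
            continue
        child_set = sorted((gc.allele_a, gc.allele_b))
        assignments = [
            (tf, tm)
            for tf in {gf.allele_a, gf.allele_b}
            for tm in {gm.allele_a, gm.allele_b}
            if sorted((tf, tm)) == child_set
        ]
        if not assignments:
            continue  # Mendelian inconsistency: skip, reported elsewhere
        for parent_gt, slot in ((gf, 0), (gm, 1)):
            if parent_gt.allele_a == parent_gt.allele_b:
                continue
            t0 = np.mean([1.0 if a[slot] == 0 else 0.0 for a in assignments])
            b += t0
            c += 1.0 - t0
    if b + c == 0:
        return b, c, float("nan"), float("nan")
    stat = (b - c) ** 2 / (b + c)
    return b, c, stat, float(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Segment localization


def localize_signal(
    segments: list[SegmentSignal], alpha: float = 0.05
) -> list[tuple[str, str]]:
    """Merge maximal runs of consecutive significant adjacent-marker segments.

    Segments must be listed in genomic order with shared boundary markers;
    each maximal run of segments with p_raw <= alpha collapses into one
    candidate fragment spanning its outermost markers.
    """
    fragments: list[tuple[str, str]] = []
    run_left = None
    prev_right = None
    for seg in segments:
        sig = seg.p_raw <= alpha
        contiguous = prev_right is not None and seg.left == prev_right
        if sig:
            if run_left is None or not contiguous:
                if run_left is not None:
                    fragments.append((run_left, prev_right))
                run_left = seg.left
            prev_right = seg.right
        else:
            if run_left is not None:
                fragments.append((run_left, prev_right))
                run_left = None
            prev_right = seg.right
    if run_left is not None:
        fragments.append((run_left, prev_right))
    return fragments
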