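import io
import itertools

import numpy as np
import pytest

from sibmod.cohort import read_pedigree
from sibmod.haplotypes import (
    HaplotypeFreqTable,
    PhaseModel,
    d_prime,
    define_blocks,
    em_haplotype_frequencies,
    explanation_lists,
    informative_markers,
    ld_from_frequencies,
    minor_allele_frequency,
)
from tests.conftest import cohort_from_haplotypes, unrelated_cohort

TWO_SNPS = ["m1", "m2"]
KNOWN_FREQS = {(0, 0): 0.5, (0, 1): 0.3, (1, 0): 0.15, (1, 1): 0.05}


def _grid_best_loglik(model: PhaseModel, counts, step=0.01):
    """Exhaustive 0.01-step simplex search over 2-marker haplotype frequencies."""
    best = -np.inf
    k = model.n_haplotypes
    steps = int(round(1 / step))
    for cuts in itertools.combinations_with_replacement(range(steps + 1), k - 1):
        f = np.diff((0, *cuts, steps)) / steps
        if (f < 0).any():
            continue
        ll = model.log_likelihood(counts, np.asarray(f, dtype=float))
        best = max(best, ll)
    return best


def test_homozygotes_only_equal_direct_counting():
    cohort = cohort_from_haplotypes({(0, 0): 0.7, (1, 1): 0.3}, TWO_SNPS, 50, seed=1)
    # every individual is drawn from two haplotypes; keep only homozygous ones
    hom_ids = [
        i
        for i, ind in cohort.individuals.items()
        if all(ind.call(m).allele_a == ind.call(m).allele_b for m in TWO_SNPS)
    ]
    sub = cohort.subset(hom_ids)
    table = em_haplotype_frequencies(sub, TWO_SNPS)
    counts = {h: 0 for h in table.haplotypes}
    for i in hom_ids:
        hap = tuple(sub.individuals[i].call(m).allele_a for m in TWO_SNPS)
        counts[hap] += 2
    total = 2 * len(hom_ids)
    for h, f in table.as_dict().items():
        assert f == pytest.approx(counts[h] / total, abs=1e-9)


def test_single_double_heterozygote_splits_evenly():
    ped = "F1 I1 0 0 1 0 A B A B\n"
    c = read_pedigree(io.StringIO(ped), io.StringIO("1 m1 100\n1 m2 200\n"))
    table = em_haplotype_frequencies(c, TWO_SNPS)
    lists = explanation_lists(c, table)
    weights = sorted(w for _, w in lists[0].explanations)
    assert weights == pytest.approx([0.5, 0.5])


def test_em_recovers_known_frequencies_and_beats_grid_search():
    cohort = cohort_from_haplotypes(KNOWN_FREQS, TWO_SNPS, 200, seed=3)
    table = em_haplotype_frequencies(cohort, TWO_SNPS)
    assert table.converged
    for h, truth in KNOWN_FREQS.items():
        assert table.freq(h) == pytest.approx(truth, abs=0.03)
    ids, vecs = cohort.genotype_vectors(TWO_SNPS)
    model = PhaseModel(vecs, [2, 2])
    counts = model.class_counts()
    assert table.log_likelihood >= _grid_best_loglik(model, counts) - 1e-9


def test_em_loglik_nondecreasing_and_frequencies_normalized():
    cohort = cohort_from_haplotypes(KNOWN_FREQS, TWO_SNPS, 80, seed=5)
    ids, vecs = cohort.genotype_vectors(TWO_SNPS)
    model = PhaseModel(vecs, [2, 2])
    counts = model.class_counts()
    f = model.default_init(counts)
    prev = -np.inf
    for _ in range(50):
        f, ll, _, _ = model.em(counts, init=f, max_iter=1)
        assert ll >= prev - 1e-9
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        prev = ll


def test_parameter_recovery_improves_with_sample_size():
    def rmse(n, seed):
        cohort = cohort_from_haplotypes(KNOWN_FREQS, TWO_SNPS, n, seed=seed)
        t = em_haplotype_frequencies(cohort, TWO_SNPS)
        return np.sqrt(
            np.mean([(t.freq(h) - f) ** 2 for h, f in KNOWN_FREQS.items()])
        )

    small = np.mean([rmse(100, s) for s in range(5)])
    large = np.mean([rmse(1000, s + 10) for s in range(5)])
    assert large < small


def test_training_set_mode_keeps_prior_frequencies():
    cohort = cohort_from_haplotypes(KNOWN_FREQS, TWO_SNPS, 30, seed=8)
    prior = HaplotypeFreqTable(
        marker_ids=TWO_SNPS,
        haplotypes=list(KNOWN_FREQS),
        frequencies=np.array(list(KNOWN_FREQS.values())),
        log_likelihood=0.0, n_chromosomes=0, converged=True, iterations=0,
    )
    table = em_haplotype_frequencies(cohort, TWO_SNPS, prior=prior)
    for h, f in KNOWN_FREQS.items():
        assert table.freq(h) == pytest.approx(f, abs=1e-12)
    assert table.iterations == 0


def test_explanation_weights_follow_frequency_products():
    """Double heterozygote under f = (0.4, 0.4, 0.1, 0.1): cis vs trans
    explanations weigh 2*0.16 : 2*0.01, i.e. 16/17 vs 1/17."""
    ped = "F1 I1 0 0 1 0 A B A B\n"
    c = read_pedigree(io.StringIO(ped), io.StringIO("1 m1 100\n1 m2 200\n"))
    prior = HaplotypeFreqTable(
        marker_ids=TWO_SNPS,
        haplotypes=[(0, 0), (1, 1), (0, 1), (1, 0)],
        frequencies=np.array([0.4, 0.4, 0.1, 0.1]),
        log_likelihood=0.0, n_chromosomes=0, converged=True, iterations=0,
    )
    expl = explanation_lists(c, prior)[0]
    by_pair = dict(expl.explanations)
    assert by_pair[((0, 0), (1, 1))] == pytest.approx(16 / 17)
    assert by_pair[((0, 1), (1, 0))] == pytest.approx(1 / 17)


def test_fully_missing_individual_enumerates_all_completions():
    ped = "F1 I1 0 0 1 0 0 0\nF1 I2 0 0 1 0 A B\n"
    c = read_pedigree(io.StringIO(ped), io.StringIO("1 m1 100\n"))
    table = em_haplotype_frequencies(c, ["m1"])
    expl = {e.individual_id: e for e in explanation_lists(c, table)}
    weights = [w for _, w in expl["I1"].explanations]
    assert len(weights) == 3  # AA, AB, BB completions
    assert sum(weights) == pytest.approx(1.0)


def test_homozygote_has_single_certain_explanation():
    ped = "F1 I1 0 0 1 0 A A B B\n"
    c = read_pedigree(io.StringIO(ped), io.StringIO("1 m1 100\n1 m2 200\n"))
    table = em_haplotype_frequencies(c, TWO_SNPS)
    expl = explanation_lists(c, table)[0]
    assert len(expl.explanations) == 1
    assert expl.explanations[0][1] == pytest.approx(1.0)


@pytest.mark.parametrize(
    "freqs,expected_informative",
    [
        ({"m": [0.5, 0.5]}, True),
        ({"m": [0.6, 0.4]}, False),  # strict > threshold
        ({"m": [0.5, 0.3, 0.2]}, True),  # multiallelic MAF = 1 - 0.5
    ],
)
def test_informative_marker_rule(freqs, expected_informative):
    cohort = cohort_from_haplotypes(
        {tuple([k]): f for k, f in enumerate(freqs["m"])},
        ["m"], 4000, seed=2, n_alleles=len(freqs["m"]),
    )
    maf = minor_allele_frequency(cohort, "m")
    # the selection rule is strict > on the realized MAF
    assert ("m" in informative_markers(cohort)) == (maf > 0.4)
    assert maf == pytest.approx(1 - max(freqs["m"]), abs=0.03)
    if abs(maf - 0.4) > 0.02:  # away from the boundary the target decides
        assert ("m" in informative_markers(cohort)) == expected_informative


def test_d_prime_complete_ld_is_one():
    cohort = cohort_from_haplotypes({(0, 0): 0.6, (1, 1): 0.4}, TWO_SNPS, 300, seed=4)
    ld = d_prime(cohort, "m1", "m2")
    assert ld.D_prime == pytest.approx(1.0, abs=1e-6)


def test_d_prime_worked_frequency_table():
    ld = ld_from_frequencies(0.4, 0.5, 0.5)
    assert ld.D == pytest.approx(0.15)
    assert ld.D_prime == pytest.approx(0.6)


def test_d_prime_independent_markers_near_zero():
    cohort = unrelated_cohort({"m1": [0.5, 0.5], "m2": [0.5, 0.5]}, 2000, seed=6)
    ld = d_prime(cohort, "m1", "m2")
    assert ld.D_prime < 0.1


def test_d_prime_monomorphic_errors():
    cohort = cohort_from_haplotypes({(0, 0): 1.0}, TWO_SNPS, 20, seed=7)
    with pytest.raises(ValueError):
        d_prime(cohort, "m1", "m2")


def test_blocks_join_only_high_ld_neighbours():
    # m1-m2 in complete LD; m3 independent
    hap_freqs = {}
    rng_freqs = {(0, 0): 0.6, (1, 1): 0.4}
    for (a, b), f in rng_freqs.items():
        hap_freqs[(a, b, 0)] = f / 2
        hap_freqs[(a, b, 1)] = f / 2
    cohort = cohort_from_haplotypes(hap_freqs, ["m1", "m2", "m3"], 500, seed=9)
    blocks = define_blocks(cohort, ["m1", "m2", "m3"], threshold=0.8)
    assert blocks[0] == ["m1", "m2"]
    assert ["m3"] in blocks
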