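import io

import numpy as np
import pytest

from sibmod.cohort import Cohort, GenotypeCall, Individual, MarkerDef, read_pedigree


@pytest.fixture
def nuclear_family_cohort() -> Cohort:
    """One family (2 parents + 2 sibs), 2 SNPs, Mendelian-consistent."""
    ped = (
        "F1 dad 0 0 1 0 A A B b\n"
        "F1 mom 0 0 2 0 A a b b\n"
        "F1 kid1 dad mom 1 2 A A B b\n"
        "F1 kid2 dad mom 2 2 A a b b\n"
    )
    mp = "1 snpA 100\n1 snpB 200\n"
    return read_pedigree(io.StringIO(ped), io.StringIO(mp))


def unrelated_cohort(
    freqs: dict[str, list[float]], n: int, seed: int, positions=None
) -> Cohort:
    """Unrelated individuals with independent markers at given allele freqs."""
    rng = np.random.default_rng(seed)
    panel = []
    for j, (mid, af) in enumerate(freqs.items()):
        pos = (positions or {}).get(mid, 100 * (j + 1))
        panel.append(
            MarkerDef(
                id=mid, chrom="1", position=pos,
                alleles=[chr(ord("A") + k) for k in range(len(af))],
            )
        )
    cohort = Cohort(panel=panel)
    for i in range(n):
        ind = Individual(id=f"u{i}", family_id=f"u{i}")
        for mid, af in freqs.items():
            a, b = rng.choice(len(af), size=2, p=af)
            ind.genotypes[mid] = GenotypeCall(int(a), int(b))
        cohort.add_individual(ind)
    return cohort


def cohort_from_haplotypes(
    hap_freqs: dict[tuple[int, ...], float],
    marker_ids: list[str],
    n: int,
    seed: int,
    n_alleles: int = 2,
) -> Cohort:
    """Unrelated individuals drawing chromosome pairs from known haplotypes."""
    rng = np.random.default_rng(seed)
    haps = list(hap_freqs)
    probs = np.array([hap_freqs[h] for h in haps])
    panel = [
        MarkerDef(
            id=m, chrom="1", position=100 * (j + 1),
            alleles=[chr(ord("A") + k) for k in range(n_alleles)],
        )
        for j, m in enumerate(marker_ids)
    ]
    cohort = Cohort(panel=panel)
    for i in range(n):
        h1, h2 = (haps[k] for k in rng.choice(len(haps), size=2, p=probs))
        ind = Individual(id=f"h{i}", family_id=f"h{i}")
        for j, m in enumerate(marker_ids):
            ind.genotypes[m] = GenotypeCall(h1[j], h2[j])
        cohort.add_individual(ind)
    return cohort
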