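# Methods

`sibmod` re-implements, as a tested pipeline over synthetic data, the analysis
chain by which a discordant-sibling-pair study localizes a cis-regulatory
haplotype in a candidate modifier gene (the ENaC beta-subunit gene *SCNN1B* in
cystic fibrosis) and identifies its trans-acting partner (the epithelial
splicing regulator ESRP2). This note records the models, the parameter
choices, and what the synthetic data do and do not establish.

## Extreme-phenotype selection

Two quantitative clinical parameters (lung function and weight-for-height,
both on percent-of-predicted-like scales where lower is worse) are converted
to cohort centiles by mean rank (ties averaged, missing propagated). A
patient is **severe** when both centiles are strictly below 25, **mild** when
both are strictly above 75, otherwise unclassified; boundary values are
unclassified. Sibling pairs are concordant-mild, concordant-severe,
discordant, or unclassified (any unclassified sib). Centiles are computed
over the full patient cohort, never within families. Discordant pairs are
stored mild-sib-first so intrapair contrasts have a fixed orientation.

## Haplotype frequencies and phase

Unphased multilocus genotypes are phased probabilistically with the classical
multinomial EM under Hardy–Weinberg: a genotype is explained by every
compatible unordered haplotype pair (h1, h2) with probability
f(h1)·f(h2)·(2 if h1 ≠ h2). Individuals with missing calls contribute through
all compatible completions rather than being dropped. Numerical choices:

- initialization at the product of single-marker allele frequencies, so the
  fit is deterministic given the data; haplotypes are ordered
  lexicographically for reproducible output;
- convergence when the log-likelihood gain falls below 1e-8 (cap 1000
  iterations; the flag `converged` records failures);
- a *training-set mode* fixes frequencies to a prior table and only computes
  explanation weights, mirroring designs where a larger training cohort
  anchors rare-haplotype assignment;
- pooled case+reference estimation is the default; founders-only is a flag.

Marker informativeness is MAF strictly greater than 0.4, with MAF defined as
1 − (largest allele frequency) so microsatellites need no special rule.
Pairwise D is taken from EM two-marker frequencies (multiallelic markers
reduced to major-vs-rest), D′ = |D|/Dmax with the standard sign-dependent
Dmax; adjacent informative markers join a haplotype block while D′ > 0.8.

## Association contrasts

Two groups are contrasted on a marker combination with a likelihood ratio on
EM frequencies, LR = 2·(LL₁ + LL₂ − LL_pooled), all three terms maximized by
EM over the same haplotype universe. Significance is always by permutation,
so the statistic's null distribution need not be chi-square:

- **interpair** (e.g. discordant vs concordant pairs): each pair's group
  label flips with probability ½, both sibs moving together — the pair is
  the exchangeable unit;
- **intrapair** (mild vs severe sibs of discordant pairs): the labels swap
  within each pair independently with probability ½.

p-values use the add-one estimator (1 + #{perm ≥ obs})/(1 + n_perm); the
seed is mandatory. Multiple testing over combinations uses Westfall–Young
min-p: one flip matrix drives all combinations, each permutation's minimum
raw p forms the reference distribution. Pooled frequencies are computed once
per combination (the pooled data are label-invariant); group frequencies are
re-estimated per permutation. A transmission disequilibrium test
(χ² = (b−c)²/(b+c) over heterozygous-parent transmissions, the classical
1:1 split for the double-heterozygote ambiguity) covers the family-based
contrast. Candidate fragments are maximal runs of adjacent significant
two-marker segments, merged to their outermost markers.

## Divergent sites, probes, binding-site comparison

On resequenced contrasting haplotypes, a position is divergent when the
allele sets of the discordance- and concordance-associated haplotypes are
disjoint — by construction invariant to row and column order. The packaged
published 18-position matrix yields exactly six divergent SNPs. Probes are
odd-length sequences with the variant base centered (35-mers by default);
scan windows take ±20 bp flanks.

The binding-site scanner is a plain additive PWM scorer over both strands
(sites keyed by factor, offset, strand); matrices and thresholds are inputs,
with JASPAR parsing provided. A site is allele-unique when predicted on one
allele's window and absent from the other's; unique counts pool over the six
SNPs per haplotype and are compared to an equal split by a two-sided exact
binomial (point-probability summation). The source study reports p = 0.048
for its 6-vs-21 comparison using a different procedure; the exact binomial
on those counts gives p ≈ 0.0059 (and the counts sum to 27 where 26 is
quoted). Neither discrepancy is resolvable from the published description; a
chi-square variant is provided behind a flag for sensitivity analysis.

## EMSA-PSeq filtering

Per-sample protein identifications (MASCOT scores, −10·log₁₀ P) reduce to a
presence/absence matrix; a protein is a candidate for a target SNP iff it
(1) is absent from every empty negative control, (2) is absent from every
native-gel sample of other SNP probes, (3) has abundance strictly below
200 ppm — unknown abundance fails, conservatively — and (4) is annotated as
nucleic-acid binding. Denaturing-gel samples lack the multiprotein
complexes and are excluded from criteria 1–2 unless a flag includes them.
The consensus-motif positive-control probe is not an "other SNP" for
criterion 2. Spliceosome components are flagged out of prioritization but
never deleted. Uniqueness pools the two allele probes of a SNP into one
probe group; presence in any empty negative control disqualifies.

## Read-through transcripts

Gene models are 1-based inclusive; the junction is the last base of the
donor exon. A read-through transcript splices exons 1..k and continues into
genomic sequence; the retention length is a parameter because such 3′ ends
are generally undetermined. Translation runs from an explicit CDS start to
the first in-frame stop (standard code only). Residues past the junction
are counted only when the junction falls on a codon boundary; an
out-of-frame junction reports 0 while the total length reflects the shifted
frame. The packaged mini-gene analog mirrors the candidate gene's
architecture — a 640-codon CDS over five exons, third donor codon-aligned
195 codons into the ORF, retained intron encoding 26 stop-free codons — so
the read-through protein is 221 aa with 26 intron-derived residues. The
real-gene computation needs the reference chromosome sequence and RefSeq
exon coordinates; with those on disk, `read_exon_table` + `splice` +
`readthrough_transcript` + `translate_cds` is the same code path.

## Knockdown quantification

Per plate, ΔCt = Ct(target) − Ct(housekeeping) after averaging technical
duplicates. Within a biological replicate the transfection-agent effect is
ΔΔCt(agent) = ΔCt(growth) − ΔCt(transfection) over all 3×3 plate
combinations; a treatment's ΔΔCt subtracts the mean agent effect. Because
the nine combinations share plates, only an index-matched perfect matching
(case_i ↔ ref_i; deterministic, with a seeded random matching available to
show invariance) enters the two-sided Wilcoxon signed-rank test against
zero, exact for n ≤ 25, pooled across biological replicates (3 values per
replicate, 9 in the standard design). Replicates with fewer than two valid
plates in any condition are excluded. Densitometry signals are normalized
to the paired isotype-control lane within each experiment (zero or missing
isotype → experiment excluded, not imputed) and compared between probe
alleles with an exact two-sided Mann–Whitney U test.

## The synthetic study generator

The cohort generator embodies the study's working model. Founders draw two
cis haplotypes from a preset pool (receptive haplotype at 0.60, two
mid-frequency and two rare alternatives — below the ~0.69 pooled
extreme-pair estimate, which is inflated by discordant-pair enrichment) and
two alleles at an unlinked trans locus (frequency 0.5); sibs inherit by
Mendelian transmission. Phenotypes follow

    y = μ − s·(β_cis·X_cis + β_int·R·(X_trans − 1)) + u_fam + v_ind + ε

with X_cis the receptive-haplotype dosage, R the receptive exposure
(carrier indicator by default, dosage/2 under additive coding), and the
trans effect *centered* because the two trans alleles are functionally
divergent — one pushes receptive carriers mild, the other severe. An
uncentered effect would make every receptive carrier uniformly severe and
enrich the receptive haplotype among concordant-severe pairs, the opposite
of the observed pattern. Defaults: μ = 100, scale s = 10, family SD 12,
individual SD 4, residual SD 4 per phenotype — chosen so a 318-family
screen yields a few dozen classified extreme pairs, matching the source
study's 37/318 yield. The strong-interaction scenario
(`alternative_params`) uses additive coding with β_int = 4, reflecting the
observation that homozygosity for the receptive haplotype is what
discordance concentrates; under it the EM-estimated receptive-haplotype
frequency is higher among discordant than concordant pairs in well over 90%
of simulated studies. Optional filler markers use a first-order
haplotype-copying chain with a target adjacent-D′ level.

What the generator does **not** emulate: realistic LD maps or recombination
(haplotypes transmit whole), genotyping error, ascertainment by the original
ranking algorithm (the simple two-threshold centile rule stands in),
age/cohort structure, and any mechanistic link between the simulated trans
genotype and the simulated qPCR/mass-spec layers (those plant their own
truths). Passing tests therefore demonstrate calibration and recovery under
the stated model, not performance on real cohorts.

The mass-spec generator plants binders that appear in all native samples of
their probe SNP and assigns every background contaminant one disqualifying
stratum (negative-control presence, high abundance, or no nucleic-acid
annotation), so planted binders are the only possible survivors — the
design that makes sensitivity/false-positive counts exact oracles. The Ct
generator adds a per-plate loading shift shared by all amplicons (cancelling
in ΔCt) plus amplicon-level and technical noise around planted condition
effects.

## Problem sizes in the test suite

EM recovery is checked at n = 200 against a 0.01-step grid-search oracle;
permutation type-I error over 500 null cohorts of 24 families × 200
permutations at α = 0.05; min-p against the Šidák form with 5 independent
markers × 1500 permutations; filter recovery over 100 simulated 28-sample
datasets; the enrichment direction over 100 simulated 318-family studies;
exact rank tests against full enumeration for n ≤ 8. The full suite runs in
under two minutes on one CPU.

## Known limitations

- The family-likelihood weighting of the original association software is
  not public in detail; the multinomial EM with optional training-set
  frequencies is this package's documented interpretation, and published
  cohort p-values are not reproduction targets (the raw genotypes are not
  public).
- Whether a concordant pair enters the likelihood as one unit or two
  correlated individuals is unspecified in the source; here pairs are the
  permutation unit and individuals the likelihood unit.
- The equal-distribution test cannot reproduce the published p = 0.048 (see
  above); both the count discrepancy and the procedure gap are documented
  rather than resolved.
- Haplotype enumeration is exhaustive over compatible completions and is
  meant for the small marker subsets used here (≤ ~8 markers with missing
  data), not genome-wide scans.
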