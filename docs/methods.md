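# Methods

This note documents the models behind `forensnp`, the defaults and their
rationale, the numerical choices, and what the synthetic-data validation
does and does not demonstrate about real panels.

## Data model and quality control

Genotypes are unordered diploid allele-index pairs over loci with two or
three declared alleles (the targeted panels this package addresses mix
diallelic and tri-allelic autosomal SNPs); a call is missing as a whole,
never per allele. Frequency tables carry per-(population, locus) vectors
that must sum to 1 within 1e-9, plus optional diploid sample counts used by
finite-sample corrections.

Call-rate QC filters samples first, then loci, and iterates the two passes
to a fixed point, so the retained matrix always satisfies both thresholds
and the filter is idempotent. The defaults (1.0/1.0) keep only complete
samples and loci — the regime under which a forensic multiplex is validated.
Raw-read mapping rates are not visible at the genotype level, so the
per-sample filter is expressed as a genotype call rate. Allele frequencies
use pairwise-complete denominators (per-locus counts of non-missing calls),
not listwise deletion; a (population, locus) cell with no data is marked
unavailable and every downstream statistic rejects or skips it explicitly.

The allele coverage ratio (ACR) at a heterozygous call is the less-covered
allele's read depth over the more-covered allele's depth — symmetric in the
two alleles, in [0, 1], undefined (and reported) when both depths are zero.

MAF/LD pruning applies a strict minor-allele-frequency cutoff (MAF computed
as 1 − max allele frequency, which covers tri-allelic loci), then slides a
50-locus window in steps of 5, greedily removing the later locus of any
pair with EM-estimated r² above the threshold. Greedy-later removal makes
the result deterministic in input order. Tri-allelic loci are collapsed to
major-allele-vs-rest for the r² computation only.

## Per-locus forensic parameters

* Observed heterozygosity `Hobs`: heterozygous fraction of non-missing calls.
* Gene diversity: the unbiased estimator GD = n/(n−1)·(1 − Σp²) over n
  sampled alleles. The unbiased form is used because it is the one whose
  diallelic maximum at p = 0.5 and 157 diploids equals 0.5016, the value a
  validation study of this design reports.
* Match probability: PM = Σ of squared *observed* genotype-class
  proportions (not Hardy–Weinberg expectations), PD = 1 − PM enforced
  exactly. Published per-locus tables in this field occasionally print PD
  ranges inconsistent with their PM ranges (complement mismatch); this
  package treats PD ≡ 1 − PM as definitional and surfaces any such
  discrepancy to the caller's attention rather than reproducing it.
* Power of exclusion: Brenner's trio formula PE = h²(1 − 2hH²), H = 1 − h,
  strictly increasing in h. It reproduces the printed PE maximum 0.9744
  from the printed Hobs maximum (155 het of 157 calls). Note the printed PE
  *minimum* of such tables (0.0002) does not follow from the printed Hobs
  minimum via this formula (which gives ≈4e-5); without the per-locus
  table the originating locus cannot be identified, and no test asserts it.
* Per-class medians (diallelic vs tri-allelic) exclude completely
  homozygous and completely heterozygous loci, which carry no usable
  polymorphism signal for these summaries; an empty class yields no median
  rather than NaN.

## Hardy–Weinberg and linkage disequilibrium

The diallelic HWE test is the exact conditional test: conditioning on the
observed allele counts, it sums the probabilities of all heterozygote
configurations no more probable than the observed one (two-sided). The
tri-allelic test enumerates all genotype tables consistent with the allele
counts (Levene's conditional distribution) when the candidate-table count is
below 2e6, and otherwise falls back to a seeded Monte-Carlo permutation of
the allele multiset with p = (hits + 1)/(B + 1). Monomorphic loci return
p = 1 by convention (no test is possible). Significance screening applies a
Bonferroni threshold α/L with α = 0.05 by default, so a 1993-locus panel
reproduces the conventional 2.5e-5 cutoff; both α and the denominator are
configurable.

The exact test has discrete support, so its finite-sample type-I error is
conservative: ~0.035 at 500 diploids, ~0.047 at 1000 diploids for MAF in
(0.2, 0.5) at α = 0.05. The calibration test therefore runs at 1000
diploids, where the null p-value distribution is near-uniform; the
conservativeness at smaller n is expected behavior, not an error.

Pairwise LD uses EM haplotype-frequency estimation from unphased genotypes
(the double heterozygote is the only ambiguous class; tolerance 1e-12, cap
1000 iterations, initialized at linkage equilibrium) and reports
r² = D²/(p_A p_a p_B p_b), flagging pairs above a configurable threshold
(default 0.2). Tri-allelic pairs are skipped and counted, mirroring the
diallelic restriction of standard LD screening tools.

## Cumulative panel power

1−CPD and 1−CPE curves add loci best-first (descending PD or PE, ties
broken by locus id for determinism) and accumulate the products as sums of
natural logs. The log-space values stay finite arbitrarily far past the
double-precision underflow threshold (~1e-308); the linear-scale values
underflow gracefully through subnormals to zero, never to NaN. Panels of
~2000 high-MAF SNPs genuinely reach 1−CPD near 1e-308, which is why the
log-space path is the primary representation.

## Kinship likelihood ratios

Relationships are pairwise IBD-coefficient models (k₀, k₁, k₂): PC (0,1,0),
FS (¼,½,¼), HS and GG (½,½,0), unrelated (1,0,0). For non-inbred pairwise
relationships this model is exact, so full pedigree elimination is not
needed. The single-locus LR against unrelatedness is

LR = k₀ + k₁·P₁(g₂|g₁)/P(g₂) + k₂·[g₂ = g₁]/P(g₂),

with P the HWE genotype probability and P₁ built from one transmission: a
uniformly chosen allele of g₁ is passed with mutation (an allele mutates
with probability μ, redistributing equally over the other A−1 alleles;
default μ = 1.29e-8 per meiosis per locus) and the second allele is drawn
from the population frequencies. Mutation turns apparent parent–child
exclusions into small positive LRs (2μ at p = q = 0.5) instead of zeros.
The mutation model lives inside the relationship likelihood only: the
unrelated hypothesis involves no transmission event, so no mutation applies
there. The law of total probability (Σ over g₂ of the relationship
likelihood = 1 for every g₁, model, and μ) is machine-checked in the tests.

Two O(μ) conventions are worth noting. First, full pedigree enumeration
mutates *every* meiosis, including the random mate's gamete and, for GG,
the intermediate generation; the k-vector model applies one mutation to the
IBD path and draws non-IBD alleles directly from the population. At
μ = 1.29e-8 the two agree to ~1e-8 relative and the test suite checks both
regimes (exact equality at μ = 0, 1e-6 relative at the default rate).
Second, GG is scored with the same single-meiosis mutation as HS (their
shared k-vector), ignoring the two-meiosis path length — an O(μ)
approximation that is invisible at realistic rates.

Panel LRs are sums of per-locus log10 LRs, treating loci as unlinked and
independent — defensible for panels whose LD screen flags only a trivial
fraction of pairs. Loci missing in either genotype vector or lacking
frequencies are skipped with the count surfaced. Monte-Carlo LR
distributions simulate pairs under a generating model (g₁ from HWE, IBD
state per locus from (k₀,k₁,k₂), copied alleles mutated, the rest drawn
from frequencies) and score them under a tested hypothesis; a single seeded
generator with a fixed draw order makes runs bit-reproducible. Separation
reports give each distribution's range, the one-sided overlap counts, and
the empirical misclassification rate at the natural log10 LR = 0 threshold.

## Population structure

F_ST uses Hudson's estimator with finite-sample corrections on both sides,
combined across loci as a ratio of averages (sums of numerators over sums of
denominators) — the combination that is consistent for the generating F and
standard in the EIGENSOFT lineage. When a frequency table carries no sample
sizes (e.g. true population frequencies from a simulation), the correction
terms vanish, which is exact in that limit. Outgroup-f3(O; A, B) subtracts
the outgroup's heterozygosity correction o(1−o)/(n₀−1) (configurable); f4
is uncorrected, matching common practice. Tri-allelic loci are collapsed to
major-vs-rest by default, or excluded by flag.

Uncertainties come from a weighted delete-one-block jackknife (Busing-type
weighting), which reduces exactly to the classic delete-one formula for
equal blocks (tested). Blocks default to one per chromosome — 22 for an
autosomal panel — with fixed-size blocks available; block structure for
such analyses is rarely stated in the literature, and the chromosome
default is the conservative choice for linked loci.

Rosenberg's informativeness for assignment I_n uses natural logarithms,
0·ln 0 = 0, group frequencies as unweighted means of member-population
frequencies, and the unweighted mean over groups for p̄ — the convention of
per-population input to the original infocalc. Loci missing any group's
frequencies are skipped and reported. 0 ≤ I_n ≤ ln K.

PCA standardizes dosages with p̂ = (1 + allele count)/(2 + 2N) and scale
√(p̂(1−p̂)), the EIGENSOFT normalization; missing entries contribute zero
after centering; constant loci are dropped with a warning. Samples outside
the fit set are placed by least squares on their non-missing standardized
entries (the lsqproject behavior); no outlier iterations are run. The
shrinkage correction that some smartpca workflows apply to projected
samples ("shrinkmode") is not implemented — projected coordinates of very
distinct populations can sit slightly closer to the origin than a joint
fit would place them. Tri-allelic dosages count non-major alleles.

Neighbor joining is the Saitou–Nei algorithm with two conventions: negative
branch lengths are clamped to zero with the deficit moved to the sibling
branch, and join ties break on sorted label pairs, making the tree invariant
to input order. Negative input distances (possible under unbiased F_ST) are
clamped to zero for tree building only; the distance matrix itself keeps
them.

## Synthetic data: what it emulates and what it does not

The Balding–Nichols generator draws each population's per-locus frequency
from Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency p (uniform
MAF on (0.05, 0.5] by default, randomly assigned to an allele; symmetric
Dirichlet for tri-allelic loci, which default to 40/1946 ≈ 2% of the panel,
matching the composition of the panel this package was designed around).
Under this model E[(p₁−p₂)²] = 2Fp(1−p) and E[p₁(1−p₂)+p₂(1−p₁)] = 2p(1−p),
so Hudson F_ST recovers F exactly in expectation — F is a usable ground
truth for F_ST, f-statistics, I_n and PCA tests. Frequencies are clipped
away from 0/1 by 1e-12 so HWE genotype probabilities stay positive.

Pedigree pairs are generated by explicit founder-and-transmission
simulation (founders HWE, each meiosis mutated at rate μ), independently of
the k-vector simulator; the two agreeing in distribution is itself a test.
Panel degradation removes a uniform random locus subset of size
round(rate·L) — at rate 0.1 on 1993 loci that is 199 loci, one fewer than
a truncation convention would keep; a "best" mode keeps the head of a
caller-ordered list instead, since real degradation studies sometimes rank
loci by power first.

What passing synthetic tests does *not* show: the generator has no linkage
(loci are exchangeable draws), no genotyping error, no size-biased dropout
of long amplicons in degraded samples, no inbreeding or substructure within
populations, and Balding–Nichols is a star phylogeny — real reference
panels have nested population history. Results on real data therefore
inherit only the correctness of the estimators, not these robustness
properties.

## Problem sizes in the default validation runs

The test suite and acceptance checks run, by design, at desk scale: 5000
loci × 100 diploids per population for F_ST parameter recovery, 10,000 loci
at 1000 diploids for HWE calibration, 2000 replicates × 200 loci for the
HS/GG distribution comparison, 100 replicates × 1000 loci for f4 null
calibration, and exhaustive enumeration for every per-locus oracle. These
sizes give Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

* No θ-corrected (substructure-adjusted) match probabilities; PM/PD are
  sample proportions.
* Kinship models cover pairwise non-inbred relationships only — no trios,
  no inbreeding (Jacquard coefficients), no linked-marker models.
* LD r² is diallelic-only, as in the standard screening tools.
* f-statistics reduce tri-allelic loci to a diallelic encoding.
* PCA projection omits shrinkage correction (see above).
* The HWE Monte-Carlo fallback p-value has resolution 1/(B+1).
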