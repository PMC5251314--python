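# Methods

This note records the models the package implements, the conventions
chosen where the field admits several, and what the synthetic data do
and do not establish about real panels.

## Data model

A `GenotypePanel` is an animals × markers matrix of dosages
c ∈ {0, 1, 2, NaN} counting copies of a per-marker *counted allele*,
plus a marker map (chromosome, 1-based bp) and population/herd labels.
All distances are bp differences / 10⁶ (Mbp); genetic distance assumes
a constant `cm_per_mbp` rate (default 1 cM = 1 Mbp, the usual
approximation for pig autosomes).

When reading PLINK PED/MAP text the counted allele defaults to the
sample-wide minor allele (ties broken lexicographically), the dominant
convention and the one that makes c match MAF-based expectations; a
`first_listed` policy is available. PED text records only observed
alleles, so exact write→read round-trips need the `first_listed`
policy with the writer's A/B coding; under `minor` a marker whose
counted allele has drifted above frequency ½ comes back complemented.
This is a property of the format, not of the implementation.

## Quality control

Four filters, animals first, then markers in the fixed order
MAF → SNP call rate → HWE, each marker attributed to the first
criterion it fails so per-criterion counts are reproducible. Defaults:
animal call rate ≥ 0.90, MAF ≥ 0.05, SNP call rate ≥ 0.90, HWE
χ² (1 df, no continuity correction) p ≥ 10⁻⁶. Monomorphic markers
pass HWE by convention (χ² = 0, p = 1); the MAF filter removes them
anyway. All frequencies use non-missing calls only. QC is idempotent
and order-invariant, and the pipeline applies it within each
population independently.

The misplaced-SNP screen makes explicit a check often done by eye on
LD-decay plots: a marker is suspect when it is in strong LD with many
distant markers on its chromosome but in weak LD with its immediate
neighbours. Per marker we report the fraction of same-chromosome
pairs beyond `d_far_mbp` (default 10) with r² ≥ 0.3, and the mean r²
with up to 10 neighbours within 1 Mbp; flagged when the far fraction
is ≥ 0.05 and the near mean is ≤ 0.1. All five knobs are exposed; the
statistic is one reasonable instantiation of a qualitative idea, and
the output table is meant for inspection rather than silent exclusion.

## Composite LD

Disequilibrium between two SNPs is estimated from unphased genotypes
via the composite measure: with N complete pairs and the 3×3 genotype
table counts,

    D = N/(N−1) · [(4N_AABB + 2(N_AABb + N_AaBB) + N_AaBb)/(2N) − 2 f(A) f(B)]
    r² = D²/(f(A) f(a) f(B) f(b))
    signed r = sign(D)·√r², with sign(0) := +1.

The joint-count term equals Σ c_A c_B over individuals, so D is the
unbiased sample covariance of the two dosage vectors divided by two;
this identity is what the blocked (three-matrix-product) scan uses,
and the per-pair tests verify it against a literal contingency-table
evaluation.

Conventions where the estimator is silent:

* **Missing data**: complete-pairs-only; N in the N/(N−1) factor is
  the complete-pair count, and frequencies are recomputed per pair.
* **Clamping**: the small-sample factor can push D²/denominator above
  1 on tiny or degenerate samples (identical vectors at N = 4 give
  16/9 · 9/16⁻¹…); r² is clamped at 1 so the signed-phase transform
  stays defined.
* **Undefined pairs**: a marker monomorphic among the complete pairs
  has no r²; such pairs are skipped and counted in the log.
* **Binning**: all bins and distance classes are half-open [lo, hi)
  anchored at 0, so a pair at exactly 5.00 Mbp falls outside the
  4–5 class. Pairs are pooled across chromosomes into one genome-wide
  curve per population.

## Persistence of gametic phase

For two populations sharing a marker set *and the counted-allele
coding* (recoding one panel flips every sign, turning r into −r —
the pipeline therefore codes all populations from one source), the
persistence at a distance bin is the Pearson correlation across
matched SNP pairs between the two populations' signed r values.
Bins with fewer than 3 matched pairs are omitted; a bin with zero
variance (e.g. a population against itself where every matched value
agrees) reports r = 1. An alternative reading — correlating the
vectors of bin-mean signed r — is available behind `on_bin_means`;
the pair-level construction is the default because it is the one that
yields a correlation per distance bin.

## Effective population size

Sved's pure-drift expectation E(r²) = 1/(1 + 4 Ne c) (no mutation) is
inverted per distance bin: bins are windows center ± 0.05 Mbp with
centers every 0.10 Mbp over 0.05–10 Mbp and every 0.5 Mbp over
10–20 Mbp; c = center · cm_per_mbp/100 Morgans; Ne = (1/r̄² − 1)/(4c);
T = 1/(2c) generations ago. Bins with fewer than 10 pairs or r̄²
outside (0, 1) are omitted. No sample-size correction of r² is
applied by default (an optional r̄² − 1/n adjustment exists); on the
package's own simulations at n = 100 the uncorrected inversion
recovers a constant Ne = 100 within a few percent over T ∈ [10, 100].

## Runs of homozygosity

A run is a maximal interval of consecutive mapped SNPs with ≥ 40
SNPs, ≤ 1 heterozygote, ≤ 2 missing calls, and homozygous non-missing
endpoints. Detection is a direct left-to-right maximal-interval scan,
not a sliding-window heuristic: from each leftmost eligible start the
run extends as far as the budgets allow, is trimmed to end on a
homozygote, reported if it reaches 40 SNPs, and scanning resumes past
its end. Overlapping maximal candidates (possible when two runs share
a single homozygote between close heterozygotes) are thereby resolved
left-to-right. The scanner is proven equivalent to exhaustive
subinterval enumeration on random strings. No minimum-kb or density
filter is applied beyond the SNP-count rule. Segment length is
endpoint-to-endpoint bp; F_ROH divides total segment bp by the
SNP-covered genome (Σ per chromosome last − first SNP bp). The
summary's `density` is mean kb per SNP within runs (KB_AVG/NSNP).
PLINK's windowed algorithm can give somewhat different segment sets
under the same headline constraints; outputs record the scan method.

## Inbreeding coefficients

* **F_EH**: per animal over its non-missing markers with 0 < p < 1;
  m is that animal's usable-marker count. −1 for a fully heterozygous
  animal at p = ½, +1 for a fully homozygous one.
* **F_VR**: computed as diag(G) − 1 through the GRM code path, so the
  identity with the genomic self-relationship is exact by
  construction. Missing dosages are imputed at 2p (zero
  contribution); the denominator 2Σpq runs over all polymorphic
  markers. Frequencies default to the current sample per population;
  a reference `AlleleStats` can be supplied where base-population
  frequencies are available (they matter: F1 animals evaluated at
  their own pooled frequencies show strongly negative F_VR and F_EH).
* **F_PED**: Wright's coefficient by the tabular numerator-relationship
  recursion (animals in topological order; F = half the parents'
  additive relationship). Colleau's indirect method is an efficiency
  device that produces identical values; for the pedigree sizes here
  the tabular method is the simpler reference and is cross-checked
  against explicit common-ancestor path counting.
* **Correlations**: Pearson, per population, complete cases; a
  zero-variance coefficient (every F_PED = 0 in an F1 cohort) reports
  r = 0 with a `degenerate` flag rather than NaN.

## GRM and principal components

G = ZZᵀ/(2Σpq) with Z column-centered by 2p and missing imputed at 2p.
PCA is the eigendecomposition of the double-centered G — the standard
population-structure construction — with scores eigenvector·√eigenvalue
and variance fractions over the positive spectrum. (Column-wise PCA
of G gives slightly different scores; the double-centered form is used
because relationship matrices are already inner products.)

## The simulator

`simulate_population` runs a monoecious Wright–Fisher population with
random mating excluding selfing, discrete generations, no mutation,
no selection — exactly the regime Sved's formula assumes, with census
size equal to Ne. Founders start at linkage equilibrium with
counted-allele frequencies uniform in `init_maf_range` (default
0.05–0.5); LD then accumulates by drift over `burn_in_generations`.
Gametes are sampled at the marker loci under the Haldane
no-interference model: the source haplotype switches between adjacent
markers with the recombination fraction θ = (1 − e^(−2d))/2 implied by
Poisson crossovers, which reproduces the crossover process exactly at
the (equally spaced) marker positions and vectorizes over a whole
generation. Census size follows an optional trajectory; matings of
the trailing five generations are exported as the pedigree.
`split_populations` evolves independent copies from a saved state
(shared map and allele coding; the pedigree restarts at the split
because pre-split animals are the same individuals under two labels),
and `make_f1` crosses two populations.

Default scales used by the package's own experiments, chosen to be
small but statistically comfortable: the Ne-recovery run uses 10
chromosomes × 100 cM with 300 markers each (3,000 SNPs), Ne = 100 and
200 burn-in generations, which populates every 0.1-Mbp bin out to
20 Mbp with hundreds of pairs; the phase-persistence runs use 2 × 50 cM
with 800 markers (0.063 Mbp spacing) so the 0.05–0.10 Mbp bin holds
several hundred shared pairs.

What the simulator deliberately omits — mutation, selection,
migration, sex chromosomes, overlapping generations, non-uniform
recombination and marker spacing, genotyping error — bounds what
passing tests show: they establish that the estimators recover the
truth of the idealized model that motivates them, not that real
panels satisfy that model. In particular, real chips have strongly
non-uniform marker density and ascertainment-biased allele
frequencies, and real pedigrees are deeper than the five recorded
generations, so absolute F_PED levels from the simulator are floors.

## Numerical notes

* Dosages are float64 with NaN for missing; all LD block computations
  are exact matrix arithmetic, and the streaming/blocked paths agree
  with the brute-force table evaluation to < 10⁻¹² in tests.
* Eigenvalues below max(10⁻¹², 10⁻⁹·λ₁) are treated as zero rank in
  PCA; a GRM with no positive spectrum (identical animals) raises.
* The HWE test is χ² with 1 df; its p-value is cross-checked against
  the closed form erfc(√(x/2)).
* Pipelines are deterministic given (inputs, config, seed); the run
  manifest records SHA-256 checksums of every table, and re-running
  with the same seed reproduces them byte-for-byte.
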