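# Methods

`gcorrnet` estimates and analyses the network of genetic correlations among
a set of complex traits, starting from per-trait GWAS summary statistics.
This note records the statistical model, the numerical conventions, and the
design choices taken where more than one defensible convention exists.

## The LD-score regression model

For SNP *j* with LD score ℓ_j (the sum of squared correlations with nearby
variants), a polygenic trait with SNP heritability h², GWAS sample size N,
and M reference SNPs satisfies, in expectation,

    E[χ²_j] = 1 + a + N h² ℓ_j / M,

where a ≥ 0 absorbs confounding inflation (population stratification,
cryptic relatedness). The univariate estimator regresses χ²_j = z_j² on
ℓ_j and rescales the slope: ĥ² = slope · M / N̄, with N̄ the mean sample
size. For two traits the product of z-scores satisfies

    E[z_{1j} z_{2j}] = c + sqrt(N₁ N₂) (ℓ_j / M) ρ_g,

where c is the cross-trait intercept (non-zero only under sample overlap)
and ρ_g the genetic covariance. The genetic correlation is
r_G = ρ̂_g / sqrt(ĥ²₁ ĥ²₂).

### Weighting

Both regressions are two-pass weighted least squares:

* pass 1: weights 1 / max(ℓ_j, 1), correcting for the over-counting of
  correlated SNPs;
* pass 2: additionally divide by the squared expected statistic from the
  pass-1 fit — (1 + N̄ ĥ²_1 ℓ_j / M)² for χ², and the product
  (1 + N₁ h²₁ ℓ_j / M)(1 + N₂ h²₂ ℓ_j / M) for the z-score product —
  the heteroskedasticity correction. The pass-1 heritability is clipped to
  [0, 1] inside the weight formula only.

Two passes rather than full iterative reweighting: the moment estimator's
target does not change after the first reweighting, and fixed final weights
keep the jackknife linear in per-block sufficient statistics. The intercept
is always free (never constrained to 1).

### Which heritabilities normalize r_G

`fit_bivariate` recomputes the two univariate slope regressions on the
harmonized SNP rows shared by the pair, using the externally supplied
univariate fits only for the pass-2 weights. Consequences: r_G of a trait
with itself is exactly 1, r_G is symmetric in trait order to machine
precision, and the leave-one-block-out ratio used for the jackknife is
internally consistent (numerator and denominators always drop the same
block).

### Block jackknife

Standard errors come from a delete-one-block jackknife over 200 contiguous
blocks in genomic order (configurable). With fixed weights, a weighted
regression is a function of five per-block sums, so all leave-one-out fits
cost one pass over the data. For r_G the full ratio is recomputed per
leave-out block; M and N cancel, leaving
rg_(−b) = slope_biv,(−b) / sqrt(slope₁,(−b) slope₂,(−b)).

Reported point estimates are the full-sample fits (LDSC convention); the
generic `delete_block_jackknife` utility instead returns the bias-corrected
pseudovalue mean, per its own contract. The pseudovalues of every statistic
share one block partition, so the sampling covariance of all K = T(T+1)/2
unique correlation-matrix entries is the across-block covariance of the
stacked pseudovalues divided by the number of blocks. r_G estimates outside
[−1, 1] are reported as-is with a quality flag — ratio estimators
legitimately exceed the bounds in small samples — and M defaults to the
regression SNP count, with an override for a reference-panel convention.

## The synthetic multi-trait generator

Real inputs of this kind (consumer-genomics and biobank summary statistics)
are access-controlled, so the package ships a generator that *inverts* the
moment model: z-vectors across T traits are drawn per SNP from a
multivariate normal whose covariance is exactly the LDSC expectation
(diagonal 1 + a_t + N_t h²_t ℓ_j / M; off-diagonal
c_tu + sqrt(N_t N_u) (ℓ_j/M) r_G,tu sqrt(h²_t h²_u)). LD scores are
1 + Gamma(shape 2, scale 20) — mean 41 with a long right tail, roughly the
HapMap3 LD-score profile. Defaults are the package's reference recovery
design: T = 4 traits, M = 20,000 SNPs, N = 20,000 per trait, h² = 0.4, all
pairwise r_G = 0.5, zero intercepts.

What the generator deliberately does *not* emulate: realized LD between
rows (SNPs are independent given ℓ_j), per-SNP sample-size variation,
allele-frequency-dependent architecture, and ancestry structure. Tests
passing on this generator therefore validate the estimators against the
moment model they target, not robustness to model misspecification in real
GWAS. MAF and HWE-p columns are decorative QC fields, independent of z and
shared across traits — sharing keeps post-QC SNP panels identical across
traits, which the cross-pair jackknife covariance requires. Two percent of
SNPs are placed in the chromosome-6 exclusion window and five percent left
off the include-list so that filters always have casualties.

## QC filtering and harmonization

Defaults: MAF > 0.01 and HWE p > 1e-8 (a row missing either field passes
that rule), restriction to an include-list when given, and exclusion of
chr6:26,000,000–34,000,000 (1-based inclusive) — the conventional MHC
window of LDSC-style pipelines, configurable since conventions differ.
Removed SNPs are attributed to the first failing rule in the fixed order
maf → hwe → region → include-list, which makes report counts deterministic.
Strand-ambiguous (A/T, C/G) SNPs are kept by default with an option to
drop. Allele harmonization intersects on SNP id, flips the sign of z where
the pair's alleles are swapped, and drops SNPs whose allele sets disagree.

## Correlation matrix, sign alignment, FDR

The matrix S carries NaN for pairs whose r_G is undefined (non-positive
heritability); such pairs are excluded downstream rather than imputed,
except that the sign-alignment eigendecomposition zero-fills them
temporarily. Reverse-coded traits are detected from the first unrotated
principal component of S: the leading eigenvector is oriented so its
component sum is non-negative (the eigenvector's sign is otherwise
arbitrary), and every trait loading below −0.05 has its row and column
negated in a single pass. The flip multiplies vech(S) entrywise by ±1, so
V transforms as D V D with D diagonal — magnitudes and the eigenvalue
multiset of S are preserved. P-values of all trait pairs are
Benjamini–Hochberg adjusted in a single family.

## Graph clustering and stability

The clustering graph is complete on the traits with weight |r_G| (sign
disregarded; zero or missing entries contribute no edge). Louvain community
detection is the seeded multi-level modularity heuristic; modularity is the
weighted Newman–Girvan form q = Σ_c [W_in,c/W − (s_c/2W)²]. Hierarchical
ordering uses average linkage on d = 1 − r_G with an infinitesimal
lexicographic tie perturbation and a leaf traversal that puts the subtree
containing the smallest input index first, making tie-bound orders
reproducible. The display graph keeps, per vertex, the 10 largest-|weight|
edges above 0.10 (union over the two endpoints) — a presentation filter
only; clustering always uses the complete graph, with an optional weight
threshold exposed.

Stability: vech(S) is resampled from MVN(vech(S), V). V is projected to
the PSD cone by clipping negative eigenvalues (a jackknife covariance of
~10³ entries from 200 blocks is rank-deficient by construction). Each draw
is symmetrized, its diagonal reset to 1, and *not* clipped to [−1, 1];
resamples are not re-sign-aligned because absolute weights make alignment
irrelevant to the graph. Resample r is clustered with Louvain seed
base + 1 + r. The concordance matrix is the fraction of resamples in which
each pair co-clusters; a focal trait's row gives its co-clustering profile.

## Effective number of independent tests

For a battery of M correlated tests (e.g. one gene's association against
expression in M tissues), the spectral effective df is Nyholt's

    M_eff = 1 + (M − 1)(1 − var(λ)/M),

with λ the eigenvalues of the M×M correlation matrix and var using the
M − 1 denominator (the original publication's convention; it also produces
the non-integer dfs practitioners report). The correlation matrix may come
from pairwise-complete z-scores and hence be indefinite; negative
eigenvalues enter var(λ) as-is, where the formula remains defined. The
Li–Ji partitioning variant (Σ f(|λ|), f(x) = 1_{x≥1} + frac(x), with an
1e-8 tolerance in the floor) is available for comparison — it, not the
smooth formula, reproduces the "B identical blocks → B tests" identity.
The corrected threshold is α / M_eff.

## Pipeline

`run_all` executes simulate → filter → ldsc → corr → cluster → stability →
effdf from one JSON config. All randomness derives from the global seed via
named per-stage substreams (`SeedSequence([seed, stage_index])`), so a rerun
is byte-identical and a stage rerun in isolation matches the full run. The
effdf stage, absent an external z-matrix path, is applied to the aligned
genetic correlation matrix itself — the effective number of independent
traits, a sensible multiple-testing summary for the correlation scan; point
`effdf.zmat` at a TSV to correct an external test battery instead. Each
stage records output hashes and record counts in `manifest.json`; a stage
failure aborts with the stage name, preserving earlier artifacts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use the reference design
(M = N = 20,000) with 25 replicates for recovery and null calibration and
50 two-trait replicates for jackknife calibration; cluster stability uses
an 8-trait planted two-block matrix with 200 resamples; Louvain optimality
is checked against exhaustive partition enumeration on 20 random graphs of
at most 7 vertices. These sizes give Monte-Carlo error comfortably inside
the asserted bands while keeping a full run in tens of seconds.

## Known limitations

* The estimator targets the independent-SNP moment model; with realized LD
  the block jackknife remains valid but finite-sample biases of LDSC on
  real panels (attenuation from mismatched reference LD, MAF-dependent
  architecture) are out of scope.
* No partitioned heritability, no per-SNP sample-size weighting beyond a
  scalar N, no liftover or INFO filtering.
* Louvain is a heuristic: on small graphs it occasionally returns a
  sub-optimal partition (the shipped check requires ≥ 18/20 optimal on
  tiny random graphs).
* Whether to resample the correlation or the covariance form of the
  matrix is ambiguous in practice; this package resamples the correlation
  form (unit diagonal restored after each draw).
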