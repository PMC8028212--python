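# Methods

## Model and procedure

`countperm` assesses the significance of interaction statistics for
tuples (SNP₁, SNP₂, phenotype), with SNPs coded additively
(0 = homozygous major, 1 = heterozygous, 2 = homozygous minor) and a
binary phenotype. Every supported statistic is a function of the 3×3×2
count table `c_ijk`; the plug-in probability estimate is `c_ijk / n` and
entropies are Shannon entropies of its marginals.

A permutation test shuffles the phenotype vector uniformly at random.
Conditional on the genotype data, the only randomness in the permuted
table is how the `n₀` zero-labels land in the nine genotype cells of
sizes `n_ij`; this is sampling without replacement from a finite label
population. The package therefore samples permuted tables directly:
cells are visited in a fixed order (default `(0,0), (1,0), (2,0), (0,1),
…, (2,2)`, column-major), and each cell draws its phenotype-0 count from
a hypergeometric distribution whose population and success counts are
depleted by the cells already assigned. The last populated cell's draw
is mathematically forced (remaining draws equal the remaining
population) but is still routed through the same sampler so the edge
parameterization is exercised. The phenotype-1 layer is `n_ij − c*_ij0`.

Correctness rests on exchangeability: the construction reproduces the
joint law of the permuted phenotype-0 layer exactly, not just per-cell
marginals. The test suite verifies this two ways: (i) for cohorts of
n ≤ 8 the joint PMF of transformed tables is compared by chi-square
against exhaustive enumeration of all `C(n, n₀)` zero-label placements;
(ii) at n = 10⁴ the transform and naive ensembles are compared per cell
with two-sample Epps–Singleton tests across 100 random parameter
settings, and the pooled p-values are checked for uniformity
(Kolmogorov–Smirnov). The Epps–Singleton test is used because the cell
counts are discrete, where a two-sample KS test is invalid; its
characteristic-function evaluation points are left at scipy's defaults
(t = 0.4, 0.8 after standardization).

The per-cell draws are deliberately *not* independent: replacing the
iteration with independent per-cell samplers that match the correct
means (binomial) or even the correct means and variances (rounded
normal) breaks the conservation law `Σ_ij c*_ij0 = n₀` almost surely.
Both wrong samplers are kept in `countperm.equivalence` as negative
controls; the equivalence suite reliably rejects the binomial one, which
demonstrates the suite has power and makes its passes meaningful.

## Parameters that matter

- `maf` (minor allele frequency `p`, default 0.45): genotype category
  probabilities are `P(0) = p²`, `P(1) = 2p(1−p)`, `P(2) = (1−p)²`. This
  assignment is the package's definition of the generator; note that with
  the additive-code semantics above, the homozygous-*major* category then
  carries probability `p²`, so the `maf → 0` limit concentrates on
  genotype 2. The estimator `(2N₀ + N₁)/(2n)` is unbiased for `p` under
  this assignment and is what the acceptance script recomputes.
- `phenotype_zero_prob` (`q`, default 0.66): Bernoulli phenotype with
  `P(0) = q`.
- `n_individuals` (default 10,000): cohort size of the reference
  synthetic condition.
- `n_perm`: permutations per null. Scan default 999 (p-value floor
  1/1000); equivalence-trial minimum 100 (below that the two-sample test
  has too little power to be informative).
- Cell order: configurable but cosmetic — an order-invariance test shows
  ensembles from different orders are statistically indistinguishable.
- Entropies are in bits (log base 2), a documented constant; multiply by
  ln 2 for nats. The choice rescales every measure by the same factor
  and cancels in empirical p-values.

## Synthetic data: what it does and does not emulate

The generator produces independent Hardy–Weinberg SNPs and an
independent Bernoulli phenotype — a *null-only* model. It emulates the
marginal genotype and case/control frequencies of a GWAS cohort, which
is exactly what permutation-null validation and type-I-error calibration
require. It does not emulate linkage disequilibrium between SNPs,
population structure, covariates, quantitative phenotypes, missing
calls, or genuine epistatic effects; passing tests therefore certify
null calibration and distributional correctness of the transform on real
count tables (which are margins-only inputs), not detection power on
real data.

## Numerical and design choices

- Empirical p-value: add-one convention `p = (1 + #{null ≥ obs}) /
  (1 + n_perm)`, one-sided upper tail, ties counted as exceedances. This
  is the standard bias-safe Monte-Carlo permutation estimator; it can
  never return 0 and is never anti-conservative.
- `0·log 0 ≡ 0` is enforced by masking zero cells (`xlogy`), never by
  epsilon padding, which would bias the multi-information.
- Plug-in (maximum-likelihood) entropies with no bias correction; the
  finite-sample bias of the null multi-information (~`df/(2n ln 2)`) is
  shared by observed and null values, so p-values are unaffected. A test
  pins its monotone decrease in n.
- Degenerate phenotypes (`n₀ = 0` or `n₀ = n`) flow through the same
  sampling loop, where every draw is forced; no special-casing.
- Equivalence cells that are constant in both ensembles (e.g. empty
  genotype cells at extreme parameters) admit no two-sample test and are
  reported as NaN and excluded from pooling, so the "9 p-values per
  trial" count holds only when all cells are populated — vanishingly
  rare exceptions at n = 10⁴ away from the parameter boundary.
- Per-pair RNG substreams are spawned from `(seed, snp1_index,
  snp2_index)`, so scan results are identical regardless of pair
  processing order.
- Counts are int64 throughout to support biobank-scale cohorts.
- Missing data: coded −1 internally and `NA` in files; individuals
  missing any of the three variables are dropped per tuple
  (complete-case), keeping the table total exact. The generator never
  emits missing values.
- Problem sizes in the shipped tests are chosen to keep the default
  suite fast while retaining power: the enumeration oracle uses 2×10⁵
  transform draws, the moment laws 10⁵, the equivalence sweep 100 trials
  × 200 permutations at n = 10⁴, and type-I calibration 200 tuples at
  n_perm = 999. The CLI exposes the larger reference settings
  (e.g. `--n-perm 1000000`, `--n-trials 1000`) for full-scale runs; a
  10⁶-table transform ensemble takes a few seconds.

## Known limitations

- Fixed 3×3×2 tables: multi-allelic SNPs, multi-class phenotypes and
  higher-order tuples are out of scope (the construction would
  generalize via multivariate hypergeometric draws, but is neither
  implemented nor validated here).
- No adaptive early stopping of clearly non-significant pairs; `scan`
  runs the full `n_perm` for every pair and reports raw p-values, with
  multiple-testing correction left to the caller.
- Only additive-coded inputs (genotype TSV, PLINK `.raw`); no binary
  PLINK, VCF, BGEN, dosages, phasing or imputation.
- Wall-clock speedups over naive permutation are hardware-dependent and
  are not asserted anywhere; the package instead pins the structural
  property that one transform costs one hypergeometric draw per
  populated genotype cell, independent of n, while naive permutation is
  O(n) per permutation.
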