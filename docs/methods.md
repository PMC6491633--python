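# Methods

## Problem

Given relative abundances of a taxa-set (a genus, family, phylum, or a
whole community of p taxa) measured in two groups of samples, the package
tests the global null hypothesis that the mean composition is the same in
both groups.  The members of the taxa-set are correlated, compositional
(each sample sums to one) and high-dimensional relative to typical sample
sizes, which rules out classical multivariate mean tests that assume
Gaussian data or require a covariance estimate.

## Model and procedure

All inference operates on centered log-ratio (CLR) transformed data.  For
a composition x = (x_1, ..., x_p) with strictly positive entries,

    clr(x)_j = log( x_j / g(x) ),    g(x) = (prod_j x_j)^(1/p),

so each CLR row sums to zero and is invariant to per-sample rescaling.
Zeros are replaced by a pseudo count (default 0.5) before normalization.
Testing equality of compositional means is equivalent to testing equality
of CLR means.

The two-sample statistic is the squared maximum mean discrepancy, in its
biased V-statistic form (all index pairs, including the diagonal):

    MMD^2 = 1/n1^2 sum_{i,j in G1} k(z_i, z_j)
          + 1/n2^2 sum_{i,j in G2} k(z_i, z_j)
          - 2/(n1 n2) sum_{i in G1, j in G2} k(z_i, z_j),

with the Gaussian kernel k(x, y) = exp(-||x - y||^2 / rho).  The bandwidth
rho is the median of the squared pairwise Euclidean distances over the
n(n-1)/2 unordered sample pairs (self-pairs excluded; an option gives the
median of unsquared distances for sensitivity analysis).  Because the
kernel is positive semidefinite the V-statistic is nonnegative; it equals
v'Kv with v_i = 1/n1 on group 1 and -1/n2 on group 2.

The adaptive test (``amda_test``) inserts a selection stage between the
transform and the statistic:

1. Draw one *decoy*: the CLR matrix with its rows jointly re-ordered by a
   uniformly random permutation.  The decoy has exactly the pooled column
   distributions of the data but no association with the labels.
2. For each taxon j compute two-sided two-sample Kolmogorov-Smirnov
   p-values p_j (real matrix) and p̃_j (decoy), both split by the same
   labels, and keep S = { j : p_j < p̃_j } (strict; ties are not
   selected).  Under the null each untied column is kept with probability
   1/2; a differential column is kept more often.
3. Compute MMD^2 on the S-columns, with rho recomputed on those columns
   by the median heuristic.
4. For b = 1..B, permute the labels and repeat steps 1-3 in full — a
   fresh decoy and a fresh selection per permutation.  The p-value is
   pv = (1/B) * #{ b : MMD^2_b >= MMD^2_obs }.

Repeating the selection inside every permutation is essential: the
selected subset is optimised against the observed labels, so freezing it
and only permuting the labels of the statistic biases the observed value
upward relative to the permutation null.  The package keeps that frozen
variant available (``reselect_per_permutation=False``) purely as an
ablation; on null simulations at p = 50, n = 50 it rejects at rate ~0.5
instead of 0.05, while the full procedure is calibrated.  With
re-selection the observed and permuted statistics are exchangeable under
the null, so pv is uniform on the lattice {0, 1/B, ..., 1} (each atom has
probability 1/(B+1)); the test suite verifies this via the randomized
probability integral transform (B*pv + U)/(B+1), which is exactly
Unif(0, 1) under exchangeability.

An empty selection is defined to give statistic 0 (no evidence), which
makes the procedure total and conservative: an empty observed selection
yields p-value 1 because every permuted statistic is >= 0.

### Comparators

``mmd_test`` is the plain MMD permutation test on all p taxa.  Its kernel
is evaluated on the relative-abundance vectors themselves (the original
MMD test applied to compositional data, as kernel association tests of
the MiRKAT family do); ``transform="clr"`` switches to the CLR matrix.
The distinction matters: Euclidean distances between raw compositions are
dominated by the few most abundant taxa, which is precisely the
inefficiency the CLR-based adaptive pipeline removes, and it is what
separates the two tests' power in the simulation study.  Since neither
the pooled rows nor the subset change under label permutation, the Gram
matrix is computed once per dataset.

``max_test`` is the maximum-type test on CLR data: the largest
standardized squared per-taxon mean difference,

    max_j ( mean1_j - mean2_j )^2 / ( s1_j^2/n1 + s2_j^2/n2 ),

calibrated by the same permutation scheme.  The construction follows the
max-type two-sample test for compositional means; because calibration is
by permutation, any monotone variant is valid, and a raw
|mean-difference| variant is available behind a flag.  A column whose two
group variances are both zero contributes 0 when the means agree; if the
means differ the standardized difference is unbounded and is capped at a
large finite value (1e12) with a warning.

### Kolmogorov-Smirnov details

The selection stage runs on the order of 10^5 KS tests per adaptive call
(2 p tests per permutation), so per-column p-values are computed from the
lattice representation of the statistic: for group sizes (n1, n2),
D = d_int / (n1 n2) with d_int = max |i*n2 - j*n1| along the pooled-sort
path, evaluated at the end of each run of tied values.  Exact two-sided
p-values (used when n1*n2 <= 10^4, the scipy/R convention) come from the
classic path-counting recursion and are cached per (n1, n2, d_int);
above the cutoff the asymptotic one-sample KS distribution at effective
size n1*n2/(n1+n2) is used, matching scipy's large-sample formula.  The
same mode is always applied to real and decoy columns, and both the
exact and asymptotic survival functions are strictly decreasing in the
statistic at fixed group sizes, so the engine may compare lattice
statistics directly; the suite cross-checks every path against
scipy.stats.ks_2samp.

### Randomness architecture

A master seed spawns three independent child streams (outer label
permutations, decoy draws, and synthetic data), so each component can be
replayed in isolation and the batched engine consumes randomness in
exactly the same per-stream order as a sequential implementation.  In
experiments, the seed of replicate r in cell c is derived from
(master_seed, c, r) alone, making summaries invariant to worker count and
scheduling order.

## Synthetic data

``simdata`` emulates a correlated taxa community via the logistic-normal
distribution: latent W_i ~ N_p(mu^(k), Sigma) mapped through the softmax
to compositions.  Defaults follow the study design the experiments
reproduce:

| parameter | default | meaning |
|---|---|---|
| mu^(1)_j | Unif(0, 10) | baseline log-abundance per taxon |
| Sigma | D^(1/2) A D^(1/2) | banded covariance; D_jj ~ Unif(1, 3), A tridiagonal with 1 / -0.5 |
| e_j | Unif(-0.5, 0.5) | mean shift on signal taxa (alternative model) |
| sparsity | 0.1 / 0.3 / 0.5 | fraction of taxa carrying signal, |S| = round(sparsity*p) |
| n | 50-200, n1 = n2 | total samples, two equal groups |
| p | 50-500 | taxa-set size |

mu^(1), D and the signal set are re-drawn per replicate, so Monte-Carlo
summaries average over the design randomness as well; a fixed scenario
seed reproduces a dataset bit for bit.  Sampling uses the banded Cholesky
factor of A (cached per p; A is positive definite for every p, with
eigenvalues 1 - cos(k*pi/(p+1))).

The generator produces strictly positive compositions — no zero
inflation, no sequencing-depth (count) noise, no overdispersion beyond
the logistic-normal and no phylogenetic structure.  Calibration and power
results on it therefore speak to the testing machinery under correlated
compositional data with mean shifts, not to robustness against sparsity
or count noise in real 16S/metagenomic tables (where the pseudo-count
stage, a no-op here, becomes active).

A useful identity couples the generator to the transform and is tested
end to end: clr(softmax(w)) = w - mean(w), exactly.

## Numerical choices

* Engine/naive-equivalence: the batched permutation engine must match a
  literal stepwise implementation to 1e-12 relative on the statistic and
  exactly on selections and p-values; the suite enforces this.
* CLR row sums are validated to |sum| < 1e-10 relative to the row's
  largest entry; Gram matrices are PSD up to -1e-8 eigenvalue tolerance.
* The rejection decision in experiments is pv <= alpha (not <): pv is an
  exact multiple of 1/B, including 0 and alpha itself, and with the
  plain count/B convention this is the choice under which the nominal
  level is attainable.  The add-one convention (1+count)/(1+B) is
  available behind a flag but not used in the reported experiments.
* All-identical samples (zero median distance) raise rather than being
  silently floored — such data cannot carry a two-sample signal.
* Tie handling is explicit everywhere: KS evaluates the ECDF gap at the
  end of tied runs, selection excludes tied p-value pairs, and permuted
  statistics equal to the observed one count toward the p-value.

## Problem sizes in the shipped experiments

The acceptance script and the statistical test suite run the null grid at
(p, n) in {(50,50), (100,100), (200,200), (500,100)} with B = 500
permutations and 1000-2000 replicates per cell, and power comparisons at
(p=100, n=100, 30% sparsity) and (p=50, n=100, 10% sparsity) with 500
replicates — a deliberate desk-scale profile of the full study design
(5000/1000 replicates, B up to 10^4), chosen so a complete rerun stays in
the tens of minutes on a single core.  Monte-Carlo tolerances in the
tests are matched to these replicate counts (3 binomial standard errors).

## Known limitations

* Two groups only; no covariates, pairing or longitudinal designs.
* The Gaussian kernel is the only built-in kernel; phylogeny-aware
  kernels (UniFrac, Bray-Curtis) are out of scope.
* Selection interpretability is heuristic: the reported per-taxon KS
  p-values are screening quantities, not FDR-controlled discoveries.
* Exact KS p-values are discrete at small n; ties between real and decoy
  p-values are common and such columns are never selected, which makes
  the expected null subset slightly smaller than p/2 (the permutation
  calibration absorbs this).
* The permutation p-value can be exactly 0; with B = 500 the smallest
  achievable nonzero p-value is 0.002.  Multiple-testing corrections
  across many taxa-sets should take B into account.
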