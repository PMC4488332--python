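# Methods

## The model

All components work with the one-GRM linear mixed model for a quantitative
trait measured on n individuals genotyped at M SNPs:

    y = mu + X alpha + Z u + eps,
    u ~ N(0, sigma_u^2 I_M),   eps ~ N(0, sigma_e^2 I_n),

where Z is the column-standardised genotype matrix (entry
(d_ik - 2 f_k) / sqrt(2 f_k (1 - f_k)) for dosage d and allele frequency
f).  Integrating out the SNP effects,

    Var(y) = sigma_g^2 G + sigma_e^2 I,        G = Z Z' / M,

with sigma_g^2 = M sigma_u^2.  G is the genetic relationship matrix (twice
the Balding–Nichols kinship estimate); heritability is
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Two estimators sit at the core:

* **REML** (`snpherit.reml_fit`): exact restricted maximum likelihood via a
  single eigendecomposition of G.  Rotating y and X to the eigenbasis makes
  V diagonal; the total variance is profiled out and the restricted
  likelihood is maximised over h^2 on [0, 1-1e-6] by a 64-point grid plus
  bounded scalar refinement.  The SE of h^2 comes from the numerical
  curvature of the profile restricted log-likelihood at the optimum
  (one-sided difference at a boundary, flagged); the LRT p-value uses the
  boundary mixture ½ chi2(0) + ½ chi2(1).  The implementation is checked
  against a direct-inversion (explicit V^-1) evaluation to 1e-6 and against
  a 1001-point grid oracle.

* **Score test for H0: sigma_g^2 = 0** (`snpherit.score_statistic`):

      S  = r' G r / sigma_hat^2 - tr(G),
      T2 = N S^2 / (N tr(GG) - tr(G)^2),

  with r the OLS residuals of the null model and sigma_hat^2 = RSS/(N-1).
  Two conventions here are deliberate and load-bearing:

  - *Scaling.*  As defined, T2 is **twice** the canonical efficient-score
    statistic (whose null reference would be chi2(1)).  Its null
    distribution is therefore approximately 2*chi2(1); the nominal 3.84
    threshold is anti-conservative everywhere, and all power statements are
    made against Monte-Carlo-calibrated critical values.  This scaling is
    what the package's own calibration tables are built on.
  - *Variance divisor.*  sigma_hat^2 uses the unbiased divisor N-1 (the
    sample-variance convention) rather than the ML divisor N.  The choice
    shifts S by almost exactly tr(G)/N ≈ 1.  When the signal is strong this
    is invisible, but in the near-degenerate regime (G close to I, S of
    order 1) it changes means, critical values and power materially, and
    the N-1 convention is the one under which the full calibration table is
    internally consistent.  `variance_ddof=0` exposes the ML variant.

  When G = I the denominator N tr(GG) - tr(G)^2 is exactly zero and the
  variance component is unidentifiable (the statistic is 0/0); the
  implementation raises `UnidentifiableError` whenever the denominator
  falls below 1e-8 * N^2.  This degeneracy is the scientific point of the
  power study: with truly unrelated samples, G -> I as M grows, and the
  test must lose its power.

## The power study

For each cell (N, M, K) with K either the identity ("unrelated") or unit
diagonal with iid uniform(0, 0.05) off-diagonals ("moderately related"):
per replicate a fresh G = ZZ'/M is drawn from Gaussian score columns with
covariance K, the trait is drawn as y ~ N(0, sigma_g^2 G + sigma_e^2 I)
with sigma_g^2 = sigma_e^2 = 1 (h^2 = 1/2; sigma_e^2 is pinned to 1
because T2 is scale invariant), and T2 is evaluated with an intercept-only
design.  Under the null sigma_g^2 = 0.  The empirical critical value is
the 95th percentile (type-7 quantile) of the null replicates; power is the
fraction of alternative replicates exceeding it, with a Wilson 95% CI.
One K realisation per cell is drawn and held fixed across replicates
(fresh Z each replicate) — the "a population with this relatedness"
reading; the fraction of null draws above 3.84 is tabulated alongside as
the type-I error of the uncalibrated test.

The column distribution is Gaussian.  The model statement fixes only the
first two moments (mean 0, Var = K); the Gaussian completion is canonical,
and it makes M*G ~ Wishart(M, K) exactly, which the fast engines exploit.
Discrete standardised dosages would perturb fourth moments by O(1/M) here
— invisible at these cell sizes.

### Simulation engines

Three per-replicate engines draw from the *same* distribution of T2 and
are interchangeable (verified by two-sample KS tests among all pairs):

1. `direct` — literal protocol: explicit n x M matrix of scores.  Cost
   grows linearly with M; used for small M (e.g. M = 120 < n, where the
   Wishart is singular but the direct draw is cheap).
2. `wishart` — Bartlett factor of Wishart(M, K): A lower triangular with
   chi_{M-i+1} diagonals and standard-normal subdiagonals; C = L A /
   sqrt(M) gives G = CC' without ever forming Z.  Cost independent of M,
   cubic in n.  The trait is drawn through the same factor
   (y = sigma_g C a + sigma_e b), so no extra Cholesky is needed.  The two
   O(n^3) products (L@A and C'C) run in single precision: this engine is
   used only for structured K, where tr(GG) - tr(G)^2/N ≈ n^2 E[k^2] is
   far from the cancellation regime and the float32 error (~1e-5 relative)
   is orders of magnitude below Monte-Carlo noise.
3. `spectral` — K = I only.  By orthogonal invariance the eigenvectors of
   G are Haar-distributed and independent of the spectrum, so the
   statistic needs only (i) the Wishart eigenvalue law, sampled exactly via
   the bidiagonal beta-ensemble construction (diagonal chi_{d-i},
   subdiagonal chi_{p-1-i}; squared singular values of the bidiagonal
   matrix), at tridiagonal-eigenvalue cost O(n^2); (ii) a uniform unit
   vector q = Q'1/||1|| for the intercept projection; and (iii) rotated
   trait coordinates u ~ N(0, sigma_g^2 Lambda/M + sigma_e^2 I).  For
   M < n the spectrum is padded with structural zeros.  This makes the
   M = 300,000 cells as cheap as the M = 120 cell and is what makes the
   N = 4000 cells affordable on a single CPU.

`method="auto"` picks spectral for identity K at M >= 1000, Bartlett for
structured K at M >= max(N, 2000), and direct otherwise.

### Problem sizes

The calibration/power cells in the acceptance script and test suite run
at: full 2000 alternative / 3000 null replicates for all N = 1000
unrelated cells; 800-1000 per arm for the related N = 1000 cells (Bartlett
engine, ~0.05 s/replicate); and 300-500 alternative / 500-1000 null for
the N = 4000 cells.  At these sizes every Monte-Carlo SE is several times
smaller than the tolerance it is compared against (e.g. SE(mean T2) ≈ 0.14
at the related M = 300k cell, SE(power) ≈ 0.013).  The `analysis/` drivers
default to 600/800 and accept `--full`.

## Phenotype generators

* `simulate_mvn_phenotype` draws y ~ N(Xa, sigma_g^2 G + sigma_e^2 I) via
  a spectral square root of G (works for PSD G of any rank since
  sigma_e^2 > 0).
* `simulate_polygenic_phenotype` implements the finite-causal model:
  u ~ N(0, 1) per causal SNP, polygenic score g = Z_causal u, residuals
  iid N(0, Var(g) (1-h2)/h2) where Var(g) is the *realised* sample
  variance of g.  Using the realised variance (not the theoretical
  M sigma_u^2) makes the realised heritability Var(g)/Var(y) unbiased for
  the target; the generator-level check over 200 replicates at n = 2000
  holds the mean within 0.02 of the 0.5 target.

## GRM construction, pruning, PCs

`build_grm` is the plain product ZZ'/M, symmetrised.  GCTA text-dialect
I/O: `.grm.id` (FID IID) plus gzipped lower-triangle triplets
"i j n_snps value" with 1-based indices and >= 6 significant digits;
reading validates triangularity and index ranges with line numbers.

`prune_related` greedily removes the individual in the most
above-threshold pairs (default threshold 0.025 on the GRM off-diagonal,
i.e. the relationship coefficient) until no pair exceeds it; ties remove
the smaller file-order index.  The GRM off-diagonal stands in for a
moments-based IBD estimate of the relationship coefficient — at these
thresholds both flag the same pairs and the GRM is already in hand.

`ld_prune` slides a `window`-SNP window (step window/2) and greedily
breaks pairs with r^2 >= 0.25, dropping the member of the worst pair with
the larger summed r^2 to the other kept SNPs (tie: the later SNP);
monomorphic SNPs are dropped first with a warning.  Pairwise greedy
pruning was chosen over VIF-style multiple-correlation pruning as the
deterministic, order-stable reading of window-based pruning.

`principal_components` returns the top-k eigenvectors of G with the sign
fixed so each vector's largest-magnitude entry is positive.

## The masking experiment

Synthetic LD is generated by a per-haplotype latent AR(1) Gaussian
(parameter rho, restarted every `block_len` SNPs) thresholded at the
f-quantile — the simplest mechanism giving tunable within-block r^2 decay
and independent blocks.  The experiment: split the cohort into reference
and main halves; pick causal SNPs from the LD-pruned panel; simulate the
trait at h^2 = 0.5; mask causal SNPs from the main half; impute them from
the `flank` nearest observed SNPs (by position index, ties left-first) via
ridge regression (default ridge 0.1 on the correlation scale) trained on
the reference half; score imputation by per-SNP squared Pearson
correlation with the true dosages; and fit REML h^2 in the main half from
GRMs built on observed+causal and observed-only SNPs, adjusting for 10
PCs of the respective GRM (mirroring standard practice even though the
synthetic cohort has no stratification).  Thinning to 50%/25%/12.5%
removes non-causal observed SNPs only, with nested subsets.

Haplotype-reference imputation is deliberately replaced by this linear
imputer: the experiment's logic (tagging quality versus recovered h^2)
needs a controllable imputer, not phased haplotypes.  Consequences: the
absolute imputation R^2 level here (~0.44 at the full panel under the
default LD settings) is far below what haplotype methods reach on real
GWAS panels, and only the *joint decay* of R^2 and h^2-without-causal is
a meaningful comparison, not absolute levels.

Default study conditions for the trajectory (chosen once from generator
pilots so the decay is resolvable above REML noise at desk scale):
n = 1000 samples, M = 3000 SNPs in blocks of 30 at rho = 0.92, 150 causal
SNPs, 12 seeds.  Under these conditions the across-seed mean imputation
R^2 and mean h^2-without-causal are both monotone decreasing across
fractions {1, 1/2, 1/4, 1/8}, and the causal-SNP-GRM fit at the full
panel recovers the simulated h^2 within two standard errors.

## What the synthetic data do and do not emulate

Generated: uniform-band relatedness, block-LD dosages with MAF >= 1%,
polygenic traits at a target h^2, Wishart-exact GRM draws.  Not emulated:
demography/coalescent LD patterns, admixture and stratification, sex
chromosomes, haplotype phase, genotyping error, binary traits.  Passing
tests therefore certify the estimators and the internal consistency of
the simulation findings, not robustness on real cohort data.

## Numerical choices

* Indefinite uniform-band K draws are repaired by eigenvalue clipping at
  1e-8 with diagonal rescaled to 1; the adjustment magnitude is recorded
  on the object.
* Identifiability guard: the score test refuses (raises) when
  N tr(GG) - tr(G)^2 <= 1e-8 N^2; power routines count and exclude such
  replicates (they essentially never occur for finite-M Wishart draws).
* REML boundary optima (h^2 = 0 or 1-1e-6) are flagged and use one-sided
  curvature for the SE; non-convergence of the scalar refinement falls
  back to the best grid point, flagged.
* Missing dosages standardise to score 0 (mean imputation), the standard
  GRM convention.
* Quantiles are type-7 (numpy default), so `alpha = 1` returns the sample
  minimum by contract.
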