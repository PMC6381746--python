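# Methods

## Model

All analyses fit the whole-genome regression

    y = X beta + Z alpha + e,        e ~ N(0, I sigma2_e)

where `y` is either a continuous pseudo-phenotype (deregressed breeding
values, dEBV) or the latent liability underlying an ordinal 1–5 visual
score, `X` holds the fixed effects (contemporary-group indicators and the
age-at-measurement covariate for score analyses; an intercept only for
dEBV analyses), and `Z` is the raw 0/1/2 genotype matrix. Marker effects
`alpha` carry one of two priors:

- **BayesC** (spike-and-slab): `alpha_k = 0` with probability `1 - pi`,
  else `N(0, sigma2_alpha)`. The inclusion proportion `pi` is fixed at
  0.01 by default (estimating it is known to cause convergence trouble at
  these sample sizes); `sigma2_alpha` has a scaled inverse chi-square
  hyperprior.
- **Bayesian LASSO**: double-exponential prior via the Park–Casella
  normal/exponential scale mixture, `alpha_k | tau2_k ~ N(0, tau2_k
  sigma2_e)`, `tau2_k ~ Exp(lambda2/2)`, `lambda2 ~ Gamma(shape, rate)`.
  Because `sigma2_e` enters the effect prior, its full conditional gains
  `m` degrees of freedom and the `sum alpha_k^2 / tau2_k` term; omitting
  that term is a classic implementation error that our prior-invariance
  test (below) catches immediately.

Ordinal scores use a probit threshold model: a standard-normal liability
underlies each score, observed category `c` corresponds to the interval
`(gamma_{c-1}, gamma_c]`, the residual variance is fixed at 1 for
identifiability, and no intercept is included (contemporary-group effects
absorb the location). Liabilities are data-augmentation variables redrawn
each cycle from truncated normals; all four cutpoints are sampled from
their uniform full conditionals between the bracketing order statistics of
the liabilities.

## Gibbs sampler

Single-site updates in fixed order each cycle: liabilities and cutpoints
(ordinal only), fixed effects (flat prior), each marker effect in index
order with the residual maintained incrementally, then the variance
hyperparameters. The residual and genetic-value vectors are refreshed from
scratch every 1000 cycles to cancel float drift. Kernels are numba-compiled;
all randomness flows through one seeded RNG stream, so chains are exactly
reproducible.

Default chain length follows the production setting of 800,000 cycles with
200,000 burn-in. Tests and the analysis drivers use 20,000/5,000 chains
(thinning 10), which our Monte-Carlo-error checks show are ample for the
synthetic problem sizes used here (n = 800–1000, m = 2000–5000); posterior
means at these sizes are stable to well within the tolerances the tests
assert.

### Numerical choices

- Truncated-normal draws use inverse-CDF sampling with a high-accuracy
  rational approximation of the normal quantile (one Halley refinement,
  ~1e-15), switching to Robert's exponential rejection sampler beyond 5 SD
  where the CDF difference underflows.
- The inverse-Gaussian draw for `1/tau2_k` is computed from the stable root
  form `mu (sqrt(1+t) - 1)/(sqrt(1+t) + 1)`, `t = 4 lambda / (mu y)`; the
  textbook quadratic-formula expression overflows catastrophically for the
  very large `mu` that arise when an effect is shrunk towards zero, which
  in early testing silently collapsed `lambda2` and let the m > n ordinal
  fit run away. When `alpha_k` is numerically zero the conditional's
  `mu -> infinity` limit, a Levy(`lambda2`) law, is sampled instead.
- Hyperprior scales follow a prior-R² heuristic (default R² = 0.5): the
  mode of each scaled inverse chi-square (df = 5) is placed at the share of
  phenotypic variance the prior assigns to markers or residual, and the
  `lambda2` Gamma rate (shape 1.1) is mode-matched the same way.
- Cutpoint updates fall back to the nearest occupied category when a
  category is empty, preserving ordering by construction.
- Divergent variance draws (non-finite or > 1e12) abort the chain with an
  error rather than returning garbage summaries.

### Sampler validation

Beyond closed-form oracles (ridge posterior mean at `pi = 1` with fixed
variances; truncated-normal moments; probit quantile inversion for a
0-marker ordinal model; the Gamma conditional of `lambda2`), the suite runs
a Geweke-style successive-conditional simulator on a 5-marker instance:
alternating the Gibbs kernel with data regeneration must leave the prior
invariant, checked by two-sample KS tests on `sigma2_e`, `sigma2_alpha`
and the effect marginals at alpha = 0.01.

## Window criterion

Markers are grouped into 1 Mb windows overlapping every 100 kb, anchored
at bp 0 per chromosome; windows without SNPs are dropped. Window `j`'s
genomic breeding value for animal `i` is `GEBV_ij = sum_k X_ik alpha_hat_k`
over member SNPs, and the association criterion is

    %sigma2_j = sigma2_j / sigma2_SNP * h2 / h2_SNP * 100

with `sigma2_j` and `sigma2_SNP` the variances (population denominator,
the O(1/n) distinction from the sample denominator is immaterial here)
across animals of the window and whole-genome GEBVs, `h2` the trait
heritability and `h2_SNP = sigma2_SNP / (sigma2_SNP + sigma2_e)` the marker
heritability. For a dEBV dependent variable that ratio measures the share
of *additive* variance captured and is rescaled by `h2` to give `h2_SNP`.
For a single-SNP window at exact Hardy–Weinberg counts the criterion
reduces to `2 p (1-p) alpha^2`, which the tests verify. `sigma2_SNP` is
reported as the posterior mean over retained draws of var(Z alpha).

Overlapping windows are scored independently; summaries over the
overlapping grid (e.g. the windows-needed-for-10%-of-variance count)
therefore double-count shared SNPs, mirroring how such tables are usually
reported. For QTL-recovery ranking, however, the top-k list is taken over
*non-overlapping* windows (`top_windows(..., exclusive=True)`): on a
100 kb grid every variance peak spans ~10 overlapping windows, so a literal
top-20 holds at most 2–3 distinct regions and ranking distinct regions is
the meaningful notion of recovery. Windows are called significant above
0.25% of additive genetic variance (strict inequality).

## Quality control

Filters run in fixed order within an iteration — autosomes only, SNP call
rate ≥ 0.95, animal call rate ≥ 0.90, MAF ≥ 0.05, Hardy–Weinberg
chi-square p ≥ 1e-5, within-chromosome LD pruning at r² > 0.98 — and the
cascade repeats until a full pass removes nothing, since animal removals
can re-trigger SNP filters and vice versa. The order within an iteration
and the LD tie-break (drop the larger-bp SNP of an offending pair,
scanning left to right) are frozen for reproducibility; the HWE test is
the chi-square goodness of fit without continuity correction (the 1e-5
cutoff targets gross genotyping error, where the exact test's refinement
is irrelevant). Whether LD pruning should act genome-wide or per
chromosome is not determined by convention; we restrict to within
chromosome. Residual missing genotypes are imputed to the per-SNP modal
genotype (ties to the smaller code), keeping genotypes integral for the
window GEBV computation.

## Deregression

EBVs are deregressed single-animal style: `dEBV = EBV / r2` with weight
`w = (1 - h2) / ((c + (1 - r2)/r2) h2)`, `c = 0.5` by default (the fraction
of genetic variance not captured by markers). Parent-average removal
requires a pedigree and is out of scope. Records with accuracy
`r = sqrt(r2) <= 0.60` are excluded (strict inequality). The samplers use
dEBVs unweighted by default — the weights are emitted for optional use —
because nothing in the modelling chain here requires heteroscedastic
residuals and the unweighted choice is the simpler default to reason
about.

## Synthetic data generator

The generator supplies the statistical structure the analysis assumes:

- **Genotypes**: founder-haplotype LD blocks (default 500 kb, 8 founders
  per block). Founder allele counts are set to `round(p * n_founders)`
  clamped to keep every SNP polymorphic, with `p` uniform on the MAF range
  (default 0.05–0.5); each animal draws two founder haplotypes per block.
  This gives blocky r² within blocks, independence across blocks and
  chromosomes, and exact resampling semantics. SNP positions are evenly
  spaced; the defaults (5 chromosomes × 40 Mb × 1000 SNPs) scale the real
  chip's density down by roughly an order of magnitude.
- **Architecture**: `spike_slab` plants exactly `n_qtl` (default 10)
  normal-drawn effects; `laplace` gives every SNP a double-exponential
  effect. Effects are rescaled so `sum 2p(1-p) alpha^2` hits the target
  genetic variance.
- **Phenotypes**: liability = CG effect (20 groups, SD 0.3) + small linear
  and quadratic age terms (so the fixed-effect machinery is genuinely
  exercised) + `Z alpha` + normal residual with variance set so the
  liability heritability equals `h2` (default 0.44). Scores cut the
  liability at four thresholds, defaulting to empirical quintiles so all
  five categories are populated.
- **EBVs**: `EBV = r * TBV_centred + sqrt(1 - r2) * eps` with `eps` drawn
  at the additive SD, so the realized corr(EBV, TBV) converges to the
  stated accuracy `r`; the reliability column is `r2`.

What the generator does **not** emulate: pedigree structure and
family-induced LD, selection, maternal effects, genotyping-platform error
patterns, MAF spectra skewed towards rare variants, and long-range
admixture LD. Passing tests therefore demonstrate correctness of the
machinery and recoverability under idealized polygenic-plus-major-gene
architectures, not performance on real cattle data.

## Known limitations

- With all four cutpoints sampled and flat location priors, the threshold
  model has one unidentified location direction (absorbed jointly by
  cutpoints and CG effects); effect estimates and variance components are
  unaffected, but individual `beta` and `gamma` chains drift slowly and
  only contrasts such as `gamma_1 - beta` are interpretable.
- The Bayesian LASSO tends to overstate `sigma2_SNP` relative to BayesC
  when m > n and the architecture is sparse, as weak shrinkage leaves
  polygenic noise in the genetic term; the same ordering (BayesC
  explaining variance closer to the simulated heritability) appears in our
  synthetic runs.
- QTLs explaining below ~1% of the genic variance are generally not
  recoverable at n = 1000, so recovery counts plateau around 7–9 of 10
  planted QTLs depending on the drawn effect sizes.
- The windows-needed-for-10% count is architecture-dependent: with 10
  planted QTLs a single window often suffices, unlike highly polygenic
  real traits where hundreds of windows are needed.
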