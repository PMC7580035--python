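# Methods

## Model

`nbburden` tests genomic regions for an excess of somatic mutations
against a covariate-corrected background. The statistical core is a
Gamma–Poisson mixture for pooled counts. For disease *d* with samples
*s = 1…s_d*, the per-sample mutation rate in training bin *i* is an
i.i.d. Gamma random variable; conditional on its rate each sample
contributes Poisson counts. Summing over the cohort, the pooled count
`y_i^d` is marginally negative binomial,

    P(y | mu, sigma) = (1 + sigma*mu)^(-1/sigma)
                       * Gamma(y + 1/sigma) / (Gamma(1/sigma) * y!)
                       * (sigma*mu / (1 + sigma*mu))^y,

with mean `mu` and variance `mu * (1 + mu*sigma)`. `sigma >= 0` is the
overdispersion: it measures how much per-patient mutation rates vary,
`sigma = 0` recovering the Poisson. This is why constant-rate
(binomial/Poisson) burden models break on cancer cohorts: pooled counts
carry the between-patient rate heterogeneity as extra variance, which a
constant-rate null converts into false positives.

Local background rates vary along the genome with replication timing,
chromatin state, expression and GC content. The covariate matrix X
(training bins x features) is built by averaging signal tracks over
fixed-length bins (uncovered bases count as zero — "mean0" semantics)
plus GC content with ambiguous bases excluded from the denominator.
Because such tracks are strongly collinear, X is centered, scaled by
the sample SD, and rotated to principal components; the full-rank score
matrix X' is the regression design (top-k PC regressions are available
for sensitivity analyses). The regression uses log links,

    log mu_i = beta . x'_i        log sigma_i = alpha . x'_i,

fitted by maximum likelihood. Production mode holds `sigma` constant
across bins (only the intercept of `alpha` is estimated); the full
covariate-dependent `sigma` fit exists but is off by default, since
overdispersion reflects cohort heterogeneity rather than local genomic
context.

## Burden testing

A test region of length `l_k <= l` (multi-interval elements use the
summed interval length) inherits background parameters either from the
training bin whose center is nearest the region midpoint (approximation
scheme, the default) or from a fresh covariate evaluation on an
`l`-long window centered on the region (optimal scheme). The mean is
scaled by `l_k / l`; `sigma` is left unadjusted because it is a
population-heterogeneity parameter, not an exposure. The p-value is the
one-sided upper tail `P(Y >= y_k)` evaluated through the regularised
incomplete beta function and floored at 1e-300.

Benjamini–Hochberg adjustment is applied within disease across the
tested region set (the narrowest defensible family; configurable by
slicing the result table). Evidence is combined across diseases, or
across the member genes of a pathway, by Fisher's method:
`T = -2 * sum(ln p) ~ chi^2` with twice-the-count degrees of freedom.
Fisher combination assumes the combined p-values are independent; for
pathways whose genes sit in disjoint genomic regions this is plausible,
and it is documented rather than corrected. With a single p-value the
combination is exactly the identity.

## Baselines and diagnostics

Two constant-rate baselines are provided for comparison: a global
binomial/Poisson model whose per-base rate is the genome-wide MLE
(total mutations / usable bases), and a local binomial whose per-base
success probability is the length-normalised regression mean. The KS
overdispersion diagnostic fits the constant rate, simulates per-bin
count vectors under it (100 replicates by default), and records the
two-sample Kolmogorov–Smirnov statistic against the observed counts;
Poisson-like data gives statistics near zero while overdispersed data
pushes the whole distribution toward one.

The permutation null relocates every variant independently and
uniformly within +/-50 kb (clipped at chromosome ends), preserving
chromosome, sample and disease labels. This destroys element-scale
clustering while keeping the regional rate landscape, so a calibrated
test should report no discoveries on permuted data. Permuted positions
may collide with other variants or fall in blacklisted bins; both are
allowed and are visible in the dropped-variant counts.

## Synthetic data

The generator emulates the full input stack: `m` covariate tracks are
driven by a rank-`r` latent Gaussian factor field plus independent
noise and rendered per-bin as bedGraph; the true per-bin mean is
`exp(beta . x'_i)` on the PCA scores of those tracks, so refitting the
pipeline on the emitted tracks targets exactly the stored
coefficients; per-sample rates are Gamma with shape `1/(sigma*s_d)` and
scale `mu*sigma`; counts are Poisson and variant positions are
scattered uniformly within bins. All randomness descends from one seed
through named substreams (tracks, rates, positions, permutation,
hotspots), so reruns are byte-identical and each component is
independently reproducible.

Default conditions: a 2 Gb two-chromosome genome gridded at 1 Mb
(n = 2000 training bins), three tracks from a rank-2 latent field
(noise SD 0.5), one disease of 50 genomes, beta = (1.0, 0.5, -0.3, 0.2)
and sigma = 0.2 — a sparsely mutated cohort of a few pooled variants
per Mb. The `cohort_config` preset raises the intercept to ~2000 pooled
mutations per Mb over 100 genomes (roughly 20 mutations/Mb/genome, the
scale of a heavily mutated carcinoma cohort), which is the condition
used for calibration, baseline-inflation and hotspot studies; burden
studies there use 10 kb tiling regions and 1 kb elements so that
region-level means are large enough for the discrete tail to resolve
the 0.05 level. What the generator does not emulate: mutational
signatures and trinucleotide context, sample-level clonality, covariate
measurement noise shaped like real assays, and inter-chromosomal
covariate structure. Passing tests therefore demonstrate correctness
and calibration of the statistical machinery under the stated model,
not robustness to every artefact of real sequencing data.

## Numerical choices

- All likelihood arithmetic is in log space via `gammaln`. Below
  `sigma = 1e-8` the pmf and tail switch to the exact Poisson limit:
  in double precision `gammaln(y + 1/sigma) - gammaln(1/sigma)` loses
  about `(1/sigma) log(1/sigma) * eps` of absolute accuracy, which is
  larger than the truncation error of the limit.
- The NB tail is `I_{1-p}(y, 1/sigma)` (regularised incomplete beta),
  stable far below machine epsilon; p-values are floored at 1e-300
  before any logarithm and floored values are counted in the output.
- Fitting alternates Fisher-scoring updates of `beta` (working weights
  `mu / (1 + sigma*mu)`) with a bounded Brent search on `log sigma`,
  initialised from a Poisson IRLS solution and the method-of-moments
  overdispersion `max(1e-4, (s^2 - ybar)/ybar^2)`. Convergence is a
  relative log-likelihood change below 1e-8 (default cap 200 outer
  iterations); non-convergence is flagged on the result, never silent.
- PCA loadings get a deterministic sign: the largest-magnitude element
  of each column is made positive, so rotations are reproducible across
  linear-algebra backends. Constant covariate columns are dropped with
  a warning before scaling.
- Ties in the nearest-training-bin search break toward the lower
  coordinate. Trailing sub-length bins at chromosome ends are
  discarded, and any bin overlapping a blacklist or gap interval by
  even one base is removed whole, keeping every training observation at
  identical exposure.
- Internal coordinates are 0-based half-open; 1-based inputs
  (GTF, VCF, tabular variants) are converted on read. Duplicate calls
  at one position in one sample count once; across samples they count
  per sample.

## Open design choices

- The aggregate relative prediction error `|y - mu_hat| / y` is
  reported as the mean over non-zero bins, with a median option —
  under an overdispersed model its floor is set by the per-bin
  coefficient of variation `sqrt(1/mu + sigma)`, not by fit quality
  alone.
- Observed-vs-predicted correlations are computed in-sample by
  default.
- Promoter windows (default 2500 nt) and TSS windows (default 100 nt)
  are strictly upstream of the first transcribed base, one window per
  transcript, deduplicated; both lengths are parameters, and the
  merged-exon union is the default coding test set with a CDS-only
  flag.
- Genes lacking a `gene_status` attribute (newer annotation dialects)
  skip the KNOWN filter with a warning instead of failing.
- The permutation window includes the original position, and permuted
  positions are not re-checked against the blacklist.
- Variants falling in blacklisted bins are excluded from training
  counts and from the global-rate MLE; the exclusion count is reported.

## Problem sizes

The test suite and the acceptance script run the studies at n = 2000
training bins (500 bins for the hotspot/permutation study), 10^4
tiling regions for calibration and baseline comparison, 2000 elements
with 50 injected hotspots, and 100 KS replicates — sizes chosen so the
Monte-Carlo error of each measured rate is well inside the asserted
bands while a full run stays in the tens of seconds.

## Known limitations

Constant-`sigma` mode shares one overdispersion across all bins per
disease; strongly varying cohort composition along the genome would
violate this. The approximation scheme assumes the nearest training
bin's covariates describe the region; regions in blacklisted territory
borrow the nearest usable bin, which can be distant. Fisher combination
is anti-conservative under positive dependence of per-disease tests.
The optimal scheme requires a covariate source for arbitrary windows
and falls back to the approximation with a warning when none is
supplied.
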