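# Methods

This note documents the statistical models, the generator that stands in
for field data, the numerical machinery, and the design choices made where
more than one reasonable implementation existed.

## Data model

Accessions are outbreeding populations, not inbred lines.  The genotype
signal per accession × marker is a pair of read depths from a pooled
sample; the pooled alternate-allele frequency is estimated with
pseudo-counts, `p = (AD_ALT + 1)/(AD_ALT + AD_REF + 2)`, which shrinks
low-depth cells toward 0.5 and keeps frequencies strictly inside (0, 1).
Cells below the per-cell depth threshold are explicitly missing; markers
are filtered on mean depth, site quality, pooled MAF and missing rate, and
remaining gaps are imputed with the marker mean.  Defaults: per-cell depth
≥ 10 reads, mean depth in [20, 100], quality ≥ 30, MAF ≥ 0.05, missing
rate < 20%.  The printed source for the mean-depth rule reads as a lower
bound on the maximum mean depth; we implement the plausible interval
reading (mean depth ∈ [20, 100]) and expose the literal reading behind
`FilterThresholds.mean_depth_max_is_lower_bound` rather than guessing
intent.  MAF is the across-accession mean pooled frequency folded to
`min(p̄, 1−p̄)`; a pooled read-count ratio would be an alternative estimator.

## Kernels

All relationship matrices share one construction,
`K = W W' / (tr(W W')/n)`, so that variance components are on the
phenotypic-variance scale.  For **G_A**, W is the column-centered frequency
matrix (centered, not per-marker standardized — the trace normalization is
the only scaling in the formula).  For **G_D**, W holds dominance codes:
per-marker OLS residuals of expected heterozygosity `H = 2pq` on
(intercept, p) across accessions.  Regressing per marker (rather than one
global regression, available via `scope="global"`) is what makes the codes
orthogonal to the additive regressor marker-wise, which is the stated
purpose of the decorrelation.  For **E**, W is the environment × feature
table; because weather covariates carry incommensurate units, feature
columns are standardized to unit variance by default (`scale=False`
restores strict centering; both behaviors exist because the source
pipeline's scaling is not documented).

Environmental features come in two flavors.  Reaction-norm features are
arithmetic means of each daily covariate within each 30-day window of the
trait's extraction range (1 Sep of the year before harvest to 31 Aug for
seasonal yield; to 31 May for traits scored in spring).  365 days are not
divisible by 30: the final short window is kept as its own window (13
windows for the full year, 10 for the spring range); truncation is
available.  Envirotype features bin daily values at the (0.05, 0.25, 0.50,
0.95) quantiles, computed per covariate-window on values **pooled across
environments** — pooling is what makes bin frequencies comparable between
environments, which is their purpose; per-environment cut-points are
available behind `pool_environments=False`.  Thermal covariates use a
piecewise-linear trapezoid response between the crop's cardinal
temperatures (base 3.2 °C, optimum 10–30 °C, upper limit 52 °C), scaled to
[0, 1] per day.  The identity of a canonical covariate list is
configuration, not code; the generator's default set (min/mean/max
temperature, precipitation, humidity, radiation, wind, plus derived
thermal indices) is a labeled stand-in.

## Stage 1: spatial analysis

Per trial site, plot values are regressed on accession (fixed), year
(random iid), accession×year (random iid), iid trial/replicate blocks, and
random row- and column-effect vectors with AR1(ρ) correlation over the
field indices, nested in year, trial or replicate per the site's design
(configuration, not code branches).  Row and column effects are separate
AR1 vectors, not a separable AR1⊗AR1 plot field.  Accession
identifiability uses a sum-to-zero contrast; reported effects add the
intercept back so means are on the observed scale.  ρ_row and ρ_col are
profiled: a coordinate-wise grid (default step 0.15 over ±0.9, two sweeps)
followed by a Nelder–Mead polish.  A finer grid changes nothing on the
smooth profiles we observe and multiplies the number of inner REML fits;
the grid is configurable (`SpatialSpec.rho_grid`).  Accession-year means
are fixed accession effect + accession×year BLUP — the year main effect is
deliberately excluded; it is absorbed anyway by the z-scaling that
follows.  Z-scaling centers and scales all accessions per country-year on
the core collection's mean and SD (n−1 denominator), which removes
management/scale differences and with them scale-type GxE.

## Stage 2: the REML engine

The engine fits `y = Xβ + Σ_k u_k + ε` with `u_k ~ N(0, σ²_k K_k)` for
arbitrary observation-level kernels; stage-2 models M1–M3 supply Kronecker
terms (`G ⊗ J`, `J ⊗ E`, `G ⊗ E` restricted to observed cells), stage 1
and GWAS supply dense terms.  The restricted log-likelihood is
`-½[(n−p)ln2π + ln|V| + ln|X'V⁻¹X| + y'Py]`.

Numerics: components are maximized by average-information REML — Newton
steps with the AI matrix, step-halving, and freezing of components pinned
at the floor with negative gradients — with an L-BFGS-B fallback on log
variances when AI stalls.  Convergence: relative log-likelihood change
< 1e-8.  Components live in `[1e-8·Var(y), 1e3·Var(y)]`; the floor keeps V
invertible in exact-fit limits (condition number bounded by ~cap/floor)
and floor-level estimates are reported as 0.  Initialization splits Var(y)
equally across components; multi-start (`n_starts`) jitters it.  The
intercept is the only stage-2 fixed effect; environment enters through its
kernel.

When the observations form a complete accession × environment rectangle
and the environment-side matrices commute — always true for kernels built
from column-centered features, whose row sums are zero, so J and E share
an eigenbasis — the covariance block-diagonalizes in that eigenbasis and
the engine works with m blocks of size n instead of one nm × nm matrix.
The rotation is detected automatically (numerical commutation check) and
verified in tests to reproduce the dense likelihood to machine precision.
This brings a full-scale M3 fit (264 × 12 = 3168 observations) to about a
second; unbalanced designs use the dense path.

BLUPs are conditional means `σ²_k K_k Z' V⁻¹(y − Xβ̂)` over each term's
full label set, so accessions or environments absent from training get
genomic/enviromic extrapolations; held-out cells are predicted by the
joint-Gaussian conditional mean, with a leakage guard that rejects cells
present in training.  Likelihood-ratio tests report the raw LR (slightly
negative values can occur at convergence tolerance and are clipped only
for the p-value) against the plain chi-square with df = added variance
components — conservative for components on the boundary, as the null
calibration study shows (rejection rate ~0.02 at nominal 0.05).

## GWAS

The null model's fixed design is intercept + first three genomic PCs +
country (sum-to-zero); random terms are additive and dominance effects,
their interactions with country (`G ⊗ I` over countries), an iid
country-year environment effect included only when some country is scored
in more than one year, and the residual.  Variance components are
estimated once under this null and held fixed across markers; each
marker's effects come from generalized least squares under the null
covariance (the fixed-components approximation is verified against full
per-marker REML refits in tests).  The marginal scan tests the single
fixed effect `s_i α` (Wald, df 1) with `s_i` the unstandardized pooled
frequency, so effects are per unit allele frequency.  The conditional scan
adds `s_i × country` deviations under a sum-to-zero constraint — α remains
the across-country average effect — and jointly tests the deviation vector
(df = C − 1), targeting effect heterogeneity; a joint test of all SNP
terms (df = C) is the alternative reading and can be assembled from the
returned GLS pieces.  Multiple testing uses Benjamini–Hochberg q-values
with calls at 0.05 and 0.10; genomic-control λ is reported, never applied.

Calibration note: the conditional Wald test is exactly calibrated when the
polygenic genotype×country variances are interior, and mildly conservative
when they are truly zero — boundary REML estimates adaptively absorb
country-contrast noise into AxC/DxC, inflating δ standard errors precisely
when δ̂ is large.  The calibration study therefore draws from the null
model with all components positive: the conditional null hypothesis is the
fixed deviation of one marker, not the absence of polygenic interaction.

## The generator

The synthetic-data module emulates the statistical structure the analysis
assumes: ancestral frequencies uniform on a MAF band, Balding–Nichols
subpopulation perturbation (divergence F, default 0.02 — the weak
structure of a diverse panel, leading PC < 5% of variance),
Beta-distributed within-accession drift (concentration 30), Poisson read
depths (mean 40) with binomial allele sampling; markers independent by
default (downstream methods treat them exchangeably) with an AR-over-
position mode (`ld_decay_length`) whose inter-marker correlation decays as
exp(−d/L), for LD-decay testing.  Weather is a site sinusoid (annual mean
and amplitude linear in latitude — a labeled stand-in, not meteorology)
plus AR(1) noise (φ = 0.7), with tmin ≤ tmean ≤ tmax by construction.
The default trial design reproduces the emulated study: 264 accessions,
6 countries × 2 years, per-country counts 213/144/108/118/142/262 nested
around a 108-accession core, two trials per environment, trait scoring
patterns including a winter-stress trait scored only in three 2016
environments.  Phenotypes are drawn from the M3 covariance (default
fractions 0.35/0.02/0.18/0.15/0.17/0.15, echoing an additive-dominated
decomposition with both interaction channels active), with embedded QTL
`s_i(α + δ_country)` and plot-level expansion adding year, trial, AR1
row/column and iid plot effects.  The truth record stores every component
so recomposition and recovery are testable to machine precision.

What the generator does not emulate: linkage disequilibrium with realistic
haplotype structure, allele-frequency spectra from real demography, actual
site meteorology, spatially heterogeneous residual variances, phenotype
measurement artifacts (scoring scales, censoring).  Passing tests
therefore certify the statistical machinery under the assumed covariance
structure, not robustness to violations of it.

## Problem sizes and runtimes

Parameter recovery runs at the study scale (264 accessions × 12
environments, complete grid, 20 seeds; ~25 s via the rotated path).  Null
calibration of the LRT uses 200 instances of 30 accessions × 6
environments — the chi-square reference, not scale, is the question
there.  GWAS calibration pools 4 draws × 250 markers at 60 accessions ×
8 environments.  The cross-validation direction study runs at 120
accessions × 8 environments with 10 genetic-cluster folds × 5 seeds,
enough paired folds for the Monte-Carlo standard error to resolve the
M2−M1 gain.  The whole test suite runs in about a minute on one CPU; the
reproduction script in well under two.

## Known limitations

- The A/D variance split is weakly identified on single small panels
  (G_A and G_D remain ~0.3 correlated off-diagonal even after
  decorrelation); estimates are unbiased over seeds but wobble per seed.
- The interaction component AxEnv is weakly separated from the residual
  on small complete designs (rank of G ⊗ E approaches the observation
  count), which is visible in null fits as occasional nonzero AxEnv.
- Stage-1 AR1 correlations are informative only with enough rows/columns
  per nesting group; small trials give noisy single-fit estimates.
- The engine is dense (Cholesky of V): fine to a few thousand
  observations, not intended for sparse large-scale problems.
- REML has no finite optimum on exactly noise-free data; the variance
  floor and cap make the engine return the boundary solution gracefully.
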