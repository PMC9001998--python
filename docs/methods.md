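# Methods

## Model

`gridlong` fits a Bayesian mixed model for a quantitative trait measured
repeatedly, at irregular times, on genotyped individuals.  For subject
*i* with *n<sub>i</sub>* observations,

    y_i = mu 1 + x_i Gamma beta + p_i Delta Psi b_i + e_i,
    b_i ~ N(0, I_k),   e_i ~ N(0, sigma^2 I),

where the candidate fixed effects are the always-included covariate block
(standardized observation time first, plus any user covariates) and the
*d = p + p(p−1)/2 + pq* genetic effect terms: one main effect per SNP
(additive 0/1/2 coding), one product column per unordered SNP pair
(epistasis), and one SNP-by-covariate product per (SNP, covariate) pair
(gene–time / gene–environment interaction).  `Gamma` carries latent binary
inclusion indicators; the sampler explores which terms are active and at
which SNP positions.

Within-subject dependence is modelled through a *k*-vector of random effects
defined at pre-specified grid time points.  Each observation loads on its two
bracketing grid points with linear-interpolation weights (`p_i`), so a single
fixed-dimension covariance describes arbitrarily unbalanced designs.  The
grid covariance is parameterised by its modified Cholesky decomposition
`D = Delta Psi Psi' Delta` (`Delta` nonnegative diagonal, `Psi` unit lower
triangular), which admits half-normal priors on `delta` and normal priors on
`psi` and keeps every continuous update conjugate.

### Assumptions

- Additive genotype coding, raw (uncentered); interaction columns are
  elementwise products of raw codes.  Time enters twice: raw time drives the
  interpolation weights, standardized time (mean 0, variance 1) is the
  covariate column.
- Linear interpolation only, no extrapolation: the grid must cover the
  observed time range (the default grid is equally spaced over it).  A time
  exactly on a grid point maps to that point's unit vector.
- Residuals are homoscedastic and independent given the random effects.

## Identifiability

The marginal covariance `P D P' + sigma^2 I` may fail to identify
`(D, sigma^2)` — canonically when every subject is observed exactly on the
grid, where `sigma^2` is confounded with `diag(D)`.  The package builds the
linear system whose unknowns are the free elements of a covariance
perturbation plus a residual-variance perturbation; the model is identifiable
iff that coefficient matrix has full column rank `k(k+1)/2 + 1`.  Rank is
computed from singular values with numpy's default tolerance
(`max(shape)·eps·sigma_max`) — the matrix entries are simple rationals of the
interpolation weights, so this is far below any genuine spectral gap.
`fit()` refuses non-identifiable designs unless `fix_sigma2=True`, which
freezes `sigma^2 = 0` and models `D` directly.

## Priors and defaults

| Parameter | Prior | Default |
| --- | --- | --- |
| inclusion `gamma_a` | Bernoulli(`w_a`) per type | expected 3 main / 1 epistatic / 1 SNP-covariate active |
| position `lambda_a` | uniform over SNPs | — |
| `beta_a` | N(0, `sigma_beta_a`²) | — |
| `sigma_beta_a`² | scaled-inv-chi²(`nu_beta`, `s_beta_a`²) | `nu_beta` = 6, `s²` from E(h_a) = 0.1 |
| `mu` | N(`eta_0`, `tau_0`²) | empirical mean / variance of y |
| `sigma²` | scaled-inv-chi²(`nu_sigma`, `s_sigma`²) | (2, var(y)) — weakly informative |
| `delta_l` | half-normal N⁺(0, 30) | — |
| `psi` | N(0, 0.5·I) | — |
| covariate effects | N(0, 100·var(y)) | weakly informative (always included) |

`s_beta_a² = (nu_beta − 2)·E(h_a)·V / (nu_beta·V_a)` ties the prior effect
variance to an expected per-effect heritability of 10%, with `V` the trait
variance and `V_a` the sample variance of the effect's design column
(monomorphic columns fall back to `V_a = 1` and are flagged).  The
per-type inclusion probabilities are user-overridable; the defaults make the
prior expected model size 5 terms regardless of `p`.

## MCMC

Metropolis–Hastings within Gibbs.  Per sweep, the model space receives one
(configurable) move drawn from {add, delete, move-position, beta-refresh}
with probabilities (0.3, 0.3, 0.2, 0.2):

- **add** picks an effect type proportional to its prior mass, a term
  uniformly within type, and proposes `(sigma_beta², beta)` from their
  priors, so those densities cancel in the acceptance ratio, which reduces to
  the conditional-likelihood ratio times the prior inclusion odds times the
  add/delete proposal ratio;
- **delete** is the exact reverse move;
- **move-position** relocates one SNP slot of an active term to a uniform
  SNP (symmetric; the term-dependent `sigma_beta²` prior scale is accounted
  for in the ratio);
- **refresh** is a Gibbs draw of one active `beta_a`.

The number of simultaneously active effects is capped (default 3× the prior
expected count), giving a fixed-dimensional composite model space.  All other
parameters are conjugate Gibbs draws (derived in `sampler.py`'s docstring);
truncated-normal draws use the inverse CDF with an exponential-rejection
fallback deep in the tail, and a single seeded `numpy` generator makes chains
bit-reproducible.

The default schedule is 4×10⁵ iterations after 1,000 burn-in sweeps, thinned
every 40 (10⁴ retained samples).  The cold-start transient (finding the
active effects and adapting `delta`, `psi`) lasts a roughly fixed number of
sweeps, not a fixed fraction of the chain, so short chains need
proportionally much longer burn-ins: the scaled-down schedules used in the
test suite pair 10⁴-iteration chains with 2,000–5,000 burn-in sweeps.
Under-burned chains inflate the mean deviance and hence DIC and P_D, which
biases grid-size selection toward larger k.  Each scaled experiment's
problem sizes are stated inline in its test.

**sigma² = 0 mode.**  With the residual variance frozen at zero the
explicit-`b` sweep degenerates (every conditional divides by `sigma²`), so the
sampler switches to a collapsed variant: `b` is integrated out analytically,
the singular marginal likelihood is evaluated through the pseudo-determinant
(residual mass outside the column space of `p_i Delta Psi` scores −inf), and
`mu`, covariate effects, `delta` (reflected at 0), `psi`, `beta` and the model
space are updated by random-walk / prior-proposal Metropolis steps.  This
mode trades conjugacy for well-definedness and is intended for the
all-on-grid designs where it is needed.

## Posterior analysis

Per-SNP evidence uses the per-sample indicator "any active effect involves
this SNP", so inclusion probabilities are bounded by 1 even when a SNP enters
through several terms.  The matching prior is computed by the complement rule
over the 1 + (p−1) + q terms touching a SNP (a user-specified scalar prior is
also accepted).  Bayes factors are posterior over prior odds; zero posterior
counts are floored at 1/(2T) before taking logs (flagged in the output).
Support categories: weak 3–10, moderate 10–30, strong > 30.  HPD intervals
use the sorted-window shortest-interval method; Geweke Z compares the first
10% and last 50% of a trace with ESS-corrected standard errors; the PSRF is
arviz's rank-normalized R-hat; ROC curves come from scikit-learn, with the
power comparisons scored by the best TPR at FPR ≤ 0.2.

## Grid-size selection

`DIC = −2·E[log P(y|gamma, theta)] + P_D` with
`P_D = −2·E[log P] + 2·log P(y|posterior means)`, and the simplified
`BPIC = DIC + P_D` (double penalty).  Expectations use the stored per-sample
marginal likelihoods (`b` integrated out).  Because the posterior mean of the
inclusion vector is non-binary, the plug-in deviance is evaluated at the
posterior mean of the per-observation *linear predictor* together with the
posterior means of `delta`, `psi`, `sigma²` — the well-defined reading of
"posterior means of gamma and theta".  `scan_k` refits each candidate *k*
with a shared seed (paired comparison) and reports the argmin per criterion.

## Synthetic data

The generator emulates the validation designs: HWE genotypes
(column *j* ~ Binomial(2, maf_j), maf ~ U[0.05, 0.5], near-monomorphic
columns redrawn) replace real haplotype panels — deliberately **without
linkage disequilibrium**, population structure or missingness, so passing
tests demonstrate the method's behaviour under independent common variants,
not its robustness to LD; per-subject measurement counts are uniform on
{3..7} nudged to hit the total N exactly, times are U[0,1]; random effects
come from the true `(delta, psi)` (defaults (1, 1.2, 0.8) / (0.6, 0.4, 0.6)
at k = 3, with k = 2 and k = 4 variants); residual `sigma² = 1`.  Six effect
templates cover main-only through ten SNP-time interactions.  The whole
genetic bracket (including its standalone time term where the template has
one) is scaled by `c_g = sqrt(h²(V_re + sigma²)/((1−h²)·Var S))`, so the
realized trait heritability — Var(scaled signal) over total variance, with
`V_re` the average per-observation random-effect variance — hits the target
(40% default) to within ±0.02.  The truth record carries causal indices,
terms, `c_g`, the random-effect realizations and the realized heritability.

## Numerical choices

- Subject-level linear algebra is batched over a padded (n × max n_i)
  layout; padded slots carry zero weights and residuals and are corrected for
  in the marginal log-likelihood.
- Row interpolation uses `searchsorted` with exact on-grid hits resolved to
  the left point's unit vector.
- The `sigma² = 0` marginal uses SVD with tolerance 1e−8·max(1, s_max) for
  the pseudo-determinant and a relative 1e−6 residual-column-space check.
- Degenerate inputs: zero-variance phenotypes, empty subjects, genotype
  values outside [0, 2], duplicate (subject, time) rows, infeasible (n, N)
  schedules, and wide phenotype layouts are all rejected with specific
  errors; missing genotype dosages are mean-imputed per SNP.

## Validation strategy

Every conjugate conditional is certified against a grid-integration oracle
built only from the likelihood interface and explicit prior densities
(Kolmogorov–Smirnov distance < 0.01 at 10⁵ draws); the model-space sampler is
certified against exhaustive enumeration of all inclusion patterns on a
2-SNP toy (total variation < 0.02); and a successive-conditional simulation
(alternately drawing data given parameters and parameters given data)
verifies that the full sweep leaves the prior invariant.  Scaled-down
simulation studies check HPD coverage of the covariance parameters,
DIC/BPIC grid-size selection, power orderings across sample size, SNP count
and heritability, and calibration under the null; the problem sizes for each
are stated in the test docstrings.

## Known limitations

- No LD-aware simulation; no dominance/recessive codings; no three-way
  interactions; no kinship random effects.
- The collapsed `sigma² = 0` sampler mixes more slowly than the conjugate
  path and is only intended for small all-on-grid designs.
- `P(kappa) = p/h`-style scalar position priors are supported but the
  complement-rule prior is the default; with very small p the two differ
  noticeably.
- Spline/polynomial interpolation between grid points is not implemented.
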