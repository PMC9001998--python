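# gridlong

Grid-based Bayesian mixed models for longitudinal genetic association.

Cohort studies measure traits such as body weight or cholesterol repeatedly
per individual, at times that differ from subject to subject.  Single-variant,
single-time-point analyses discard most of that information and cannot see
variants whose effects act through other variants (epistasis) or change over
time.  `gridlong` is for statistical geneticists who want to analyse such
data jointly: it fits a Bayesian variable-selection mixed model over all
candidate SNP main effects, SNP–SNP interactions and SNP–time/environment
interactions at once, while modelling the within-subject correlation of the
repeated measurements.

## Model

For subject *i* with *n<sub>i</sub>* measurements,

    y_i = mu 1 + x_i Gamma beta + p_i Delta Psi b_i + e_i,
    b_i ~ N(0, I_k),  e_i ~ N(0, sigma^2 I),

* `x_i` stacks the covariate block (standardized time, always included) and
  the d = p + p(p−1)/2 + pq candidate genetic effect columns; the diagonal
  indicator matrix `Gamma` selects which genetic terms are active, and a
  Metropolis–Hastings-within-Gibbs sampler explores the model space.
* Within-subject dependence runs through random effects at *k* grid time
  points: `p_i` maps each observation onto its two bracketing grid points by
  linear interpolation, so one fixed-dimension covariance
  `D = Delta Psi Psi' Delta` (modified Cholesky: `Delta` nonnegative
  diagonal, `Psi` unit lower triangular) serves arbitrarily unbalanced
  designs.
* Evidence per SNP is reported as a Bayes factor
  `BF(kappa) = posterior odds / prior odds` that any active effect involves
  that SNP, plotted as 2·log BF (weak 3–10, moderate 10–30, strong > 30).
* The number of grid points is chosen by DIC or the simplified BPIC
  (`BPIC = DIC + P_D`), and a rank criterion decides whether `(D, sigma^2)`
  is identifiable for a given design before any fitting starts.

See `docs/methods.md` for priors, the sampler, and the synthetic-data engine.

## Worked example

```python
import gridlong as gl

design = gl.SimulationDesign(setup=1, n=150, N=750, p=80, n_causal=8, h2=0.4)
data = gl.simulate(design, seed=11)

model = gl.LongitudinalGridModel(data.phenotypes, data.genotypes, grid=3)
print(model.check_identifiability())
# k=3: rank(A) = 7, required = 7 (2400 equations) -> identifiable

res = model.fit(n_iter=4000, burn_in=500, thin=5, seed=1, mh_moves_per_sweep=5)
print(res.summary().round(2))
```

```
               mean  median    sd  hpd_95%_low  hpd_95%_high
parameter
mu             1.08    1.00  0.46         0.14          2.20
sigma2         1.06    1.05  0.07         0.92          1.20
delta1         0.82    0.81  0.16         0.52          1.14
delta2         1.19    1.20  0.20         0.83          1.60
delta3         0.92    0.92  0.19         0.55          1.30
psi21          0.68    0.63  0.34         0.08          1.36
psi31          0.24    0.25  0.33        -0.48          0.85
psi32          0.66    0.62  0.35         0.10          1.46
beta_time_std  0.68    0.67  0.06         0.55          0.78
```

The generating values (`sigma2 = 1`, `delta = (1, 1.2, 0.8)`,
`psi = (0.6, 0.4, 0.6)`) all fall inside their 95% HPD intervals even at this
reduced scale.  The genome profile flags the signal:

```python
prof = res.genome_profile()
print(prof[prof.bf > 10].round(2))
#     snp  posterior      bf  two_log_bf category
# snp0009       0.92  136.69        9.84   strong
# snp0024       1.00     inf         inf   strong
# snp0028       1.00     inf         inf   strong
# snp0070       0.90  108.24        9.37   strong
```

All four strong hits are true causal SNPs (causal set: 3, 9, 10, 11, 24, 28,
37, 70 — a 4,000-iteration chain finds half of them; the default 4×10⁵
schedule is used for real analyses).  Model scores for grid-size selection:

```python
res.dic()    # (2537.6, 23.5)  -> DIC, effective parameter count P_D
res.bpic()   # 2561.1          == DIC + P_D
```

The same workflows are scriptable from the shell:

```bash
gridlong simulate --setup 1 --n 150 --n-obs 750 --p 80 --out sim/
gridlong identifiability --phenotypes sim/phenotypes.tsv --genotypes sim/genotypes.tsv --grid 3
gridlong fit --phenotypes sim/phenotypes.tsv --genotypes sim/genotypes.tsv --grid 3 --out run/
gridlong select-k --phenotypes sim/phenotypes.tsv --genotypes sim/genotypes.tsv --k-candidates 2,3,4 --out sel/
gridlong summarize --run-dir run/
```

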