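# Methods

This note records the statistical model, the estimation machinery, the
defaults and the numerical choices implemented in `pedigreml`.

## The model

For a trait `y` recorded on pedigreed animals:

```
y = X b + Z_a a + Z_m m + Z_pe pe + e
```

- `b`: fixed effects (intercept, generation, hatch, optionally their
  interaction), screened beforehand by least-squares ANOVA;
- `a`: direct additive genetic effects, `Var(a) = A σ²_a` with `A` the
  numerator relationship matrix over the full pedigree;
- `m`: maternal additive genetic effects of the dam, `Var(m) = A σ²_m`,
  `Cov(a, m) = A σ_am`;
- `pe`: maternal permanent environmental effects, IID per dam,
  `Var(pe) = I σ²_c`;
- `e`: residual, `Var(e) = I σ²_e`.

Six nested single-trait models differ in which maternal components they
fit (Willham's maternal-effects hierarchy):

| model | random part |
|-------|-------------|
| 1 | a |
| 2 | a + m (σ_am = 0) |
| 3 | a + m + σ_am |
| 4 | a + pe |
| 5 | a + m + pe (σ_am = 0) |
| 6 | a + m + pe + σ_am |

Records whose animal has an unknown dam are dropped under maternal models
(the maternal effect has no carrier); the count is logged.  For model
comparison, `fit_all_models` fits every model to that common record set
by default so AIC values are comparable.

## Pedigree algebra

- `A` by the tabular recursion; `A⁻¹` directly by Henderson's rules with
  inbreeding (Quaas), using Mendelian-sampling variances
  `d_i = 0.5 − 0.25(F_s + F_d)` (one parent: `0.75 − 0.25 F_p`;
  none: 1).
- Inbreeding coefficients by the Meuwissen–Luo algorithm (O(n)·path
  tracing), exact for arbitrary inbred pedigrees.
- `log|A| = Σ log d_i` from the `A = T D T'` factorization;
  `A`-vector products in O(n) through the same factorization.
- Rate of inbreeding per generation:
  `ΔF_t = (F̄_t − F̄_{t−1}) / (1 − F̄_{t−1})`, reported for all animals
  and for parents only.

## REML

The restricted log-likelihood is computed exactly from the mixed-model
equations:

```
-2 logL = (n − p) log 2π + log|R| + log|G| + log|C| + y'P y
```

with `C` the MME coefficient matrix (sparse LU via SuperLU,
`MMD_AT_PLUS_A` ordering), `y'Py = y'R⁻¹y − sol'rhs`, and
`log|G| = Σ_t (q_t log|Σ_t| + s_t log|A|)`.  Fixed-effect rank
deficiencies are removed up front by column-pivoted QR.

Maximization is Newton-type:

- gradient: central finite differences of the exact logL (each evaluation
  is one sparse factorization; no traces of matrix inverses are needed);
- curvature: the exact average-information matrix
  `AI_ij = 0.5 f_i' P f_j`, `f_i = (∂V/∂θ_i) P y`, evaluated with the
  stored LU factor;
- step control: step-halving with monotone acceptance (drop ≤ 1e−8
  tolerated), variance floor `1e−6 · var(y)`, covariance blocks clamped
  to keep |correlation| ≤ 0.9999;
- active set: a variance pinned at the floor with a downhill gradient is
  frozen and the Newton step is taken in the free subspace; if no uphill
  Newton step exists, a gradient-ascent step in the free subspace is
  tried before declaring convergence at the boundary.

Convergence: `|ΔlogL| < 5e−4` **and** max relative parameter change
`< 1e−4`; cap 200 iterations.  Standard errors come from the inverse AI
matrix restricted to parameters away from the boundary; boundary-pinned
parameters report `NaN` SE.

Model choice: `AIC = −2 logL + 2q` with `q` the number of free
(co)variance parameters (the fixed part is identical across models);
ties within 1e−6 go to the model with fewer parameters.

## Derived parameters

With `σ²_p = σ²_a + σ²_m + σ_am + σ²_c + σ²_e`:

- `h² = σ²_a/σ²_p`, `m² = σ²_m/σ²_p`, `c² = σ²_c/σ²_p`;
- `r_am = σ_am/(σ_a σ_m)` (the correlation; the proportion `σ_am/σ²_p`
  is reported separately as `cov_am_proportion`);
- total heritability (Willham):
  `h²_T = h² + 0.5 m² + 1.5 m r_am h`, with `h = √h²`, `m = √m²`;
  reduces to `h² + 0.5 m²` when `σ_am = 0` and to `h²` without `m`.

Ratios of unfitted components are `NaN`, never zero-filled.  SEs by the
first-order delta method: numerical Jacobian of each ratio propagated
through the inverse AI matrix.

## Bivariate REML

The two traits' records are stacked; every random term present in both
traits' (best univariate) models receives an unstructured 2×2 cross-trait
block; terms present in only one model stay univariate; no cross-effect
covariances are fitted.  The residual 2×2 block applies to animals
recorded on both traits (implemented with five sparse pattern matrices so
`W'R⁻¹W` is a cached linear combination).  Correlations `r_a, r_m, r_c,
r_e` and `r_p = Σcov/√(σ²_p1 σ²_p2)` with delta-method SEs; LRTs set one
covariance to zero (χ² with 1 df); the phenotypic correlation is also
tested with the exact `t = r√((n−2)/(1−r²))` transform.  Models with a
fitted σ_am are not supported in the bivariate stage (no best model in
the validation tables uses one).

## EBVs and trends

BLUP solutions for all pedigree animals (including unrecorded parents)
come from the converged MME.  The genetic trend is the weighted
least-squares regression of per-generation mean EBV on generation
(weights = generation counts), by default over females that appear as
dams of a later-generation animal; the phenotypic trend applies the same
regression to raw generation means.

## Synthetic data

The generator emulates a closed pedigreed nucleus: discrete generations,
`n_sires × n_dams` parents per generation (default 7 generations × 50
sires × 250 dams × 15 progeny/dam, up to 8 hatches; `tiny()` preset
3×5×20×4), random or sib-avoiding mating, optional truncation selection
on phenotype or true breeding value with a chosen selected proportion.

Phenotypes follow the model exactly: founder `(a, m)` vectors are drawn
from the true (co)variance block, non-founders are parent averages plus a
Mendelian-sampling deviation whose variance uses the parents' *exact*
pedigree inbreeding (`0.5 − 0.25(F_s + F_d)` times the founder block), so
relationship-matrix-based REML is correctly specified; dams carry IID
permanent environmental effects; records add generation/hatch fixed
effects and residual noise.  Cross-trait blocks (`cov_a`, `cov_m`,
`cov_c`, `cov_e`) support bivariate validation.  Every latent value is
retained in a truth table.  Same seed → byte-identical output.

The default and test problem sizes (number of generations, parents and
progeny) are this package's own validation choices.

## Limitations

- Single- and two-trait analyses only; no random regression, no genomic
  information, no overlapping generations.
- Bivariate models with a fitted direct-maternal covariance are not
  supported.
- SEs at variance boundaries are undefined (reported `NaN`) rather than
  profile-likelihood based.
- Gaussian traits only; count-like traits are treated as Gaussian, as the
  analysis model assumes.
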