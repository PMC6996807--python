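# Methods

`rrgp` implements single- and multi-trait random regression models (RRM) for
genomic inference and prediction of longitudinal traits, exercised end to end
on a synthetic two-trait greenhouse study: daily water use (WU) and projected
shoot area (PSA) recorded for a panel of related rice-like accessions over 20
days of imaging.

## Two-stage workflow

Stage one collapses raw plot-level records to one adjusted mean (BLUE) per
accession and day. Water use is derived from pot weights as
`WU_t = Potwt_{t-1} − Potwt_t` (after-watering weight of the previous day
minus today's pre-watering weight); the per-day model

```
y = mu + accession (fixed) + experiment/replicate + smarthouse block
      + accession x experiment + error
```

treats all terms except accession as random with scalar variances (conjugate
Gibbs estimates by default), and reports `mu + accession effect` under a
sum-to-zero constraint. Stage two fits the RRM to the per-day BLUEs. The
synthetic generator produces BLUE-level data directly, so stage one is
exercised by its own analysis script and tests rather than being on the
critical path.

## The random regression model

For accession *j*, trait *q* and day *t*,

```
y_qjt = sum_k phi_k(t) b_qk + sum_k phi_k(t) u_qjk + sum_k phi_k(t) p_qjk + e_qjt
```

with a quadratic (k = 0, 1, 2) Legendre basis for the fixed mean trajectory,
the additive genetic regression `u`, and the permanent-environment regression
`p`. In matrix form `y = Xb + Zu + Qp + e` with

- `Var(u) = C ⊗ G` — `C` the (n_traits·3)² genetic coefficient covariance,
  `G` the genomic relationship matrix,
- `Var(p) = D ⊗ I` — permanent environment, independent across accessions,
- `Var(e)` block diagonal with one `R(t)` block per day (2×2 for two traits:
  heterogeneous variances plus a within-day residual covariance).

The Kronecker ordering is fixed globally as coefficient-outer/accession-inner
(internally the coefficients are held accession-major, in which layout the
same covariance reads `G ⊗ C`); `realized_covariance` reconstructs the full
phenotypic covariance from any component set and is tested against a
brute-force Monte-Carlo oracle precisely to pin this ordering down.

### Basis convention

Time is standardized linearly onto [−1, 1]; the basis columns are
`phi_k(x) = sqrt(2k+1) · P_k(x)`, i.e. the orthonormal Legendre polynomials
scaled so the intercept column is identically 1. `Phi = M Λ` (monomials times
coefficient matrix) and the three-term recurrence are both implemented and
agree to machine precision. All coefficient covariances are
convention-dependent; day-level summaries (genetic variance, heritability,
genomic correlation) are invariant to the column scaling.

Standardization bounds default to the observed design range. For forecasting
(CV2) the bounds remain those of the **full** design even though training
uses only the first 10 days, so that the basis evaluated at days 11–20 lives
on the same polynomial as the training rows. This is the single most
consequential convention choice in the forecasting scenario; the alternative
(standardizing over the training window) is available by constructing a
`TimeGrid` with explicit bounds.

### Genomic relationship matrix

`G = W W' / m` from centered, column-scaled dosages. The default scales each
column by its population standard deviation (divide by n), which makes
`mean(diag(G)) = 1` exactly on complete data — a convenient, testable
identity. The classical frequency-based denominator `2 Σ p(1−p)` is available
(`scaling="allele_freq"`). Markers with call rate or minor allele frequency
at or below the thresholds (defaults 0.95 and 0.05) are removed before the
GRM; a configurable ridge (default 1e−6) is added to the diagonal before any
inversion, because a finite marker panel leaves `G` singular (centering alone
removes one rank).

## Per-day genetic summaries

With `t_i = phi(t)` the basis row of day *t*:

- genomic correlation `rg(t) = t_i C12 t_i' / sqrt(t_i C1 t_i' · t_i C2 t_i')`,
- narrow-sense heritability `h2(t) = g(t) / (g(t) + pe(t) + ve(t))` with
  `g(t) = t_i C_q t_i'` and `pe(t) = t_i D_q t_i'`.

Whether the permanent-environment variance belongs in the `h2` denominator is
a convention; both choices ship (`include_pe`), and the choice moves the level
of the trajectory but not its shape.

## Estimation: blocked Gibbs sampler

The sampler targets the joint posterior of `(b, u, p, C, D, R(t))` with flat
priors on `b` and inverse-Wishart priors on the covariance blocks. One
iteration consists of:

1. **Locations.** For every accession, the stacked vector `(u_j, p_j)` is
   drawn from its joint multivariate-normal full conditional — jointly,
   because the two blocks share the same within-accession design and are
   strongly negatively correlated given data; sampling them separately mixes
   very slowly. The fixed coefficients follow from their own normal
   conditional. The sweep is compiled with numba; all randomness enters
   through pre-generated standard-normal draws from a single numpy
   `Generator`, so runs are exactly reproducible given the seed.
2. **Covariances.** `C | u ~ IW(ν0 + n, S0_C + U' G⁻¹ U)` and
   `D | p ~ IW(ν0 + n, S0_D + P'P)`; each day's residual block is a 2×2
   inverse-Wishart where both traits are recorded that day and a scaled
   inverse chi-square per observed trait otherwise (days with a single
   recorded trait update only that trait's variance; the cross-covariance of
   such days is unused by the likelihood, which applies the marginal
   precision to lone records).

Three algorithmic choices beyond the textbook sampler matter in practice:

- **Eigenbasis rotation.** When every accession carries the same
  (day, trait) record pattern — true of all variance-estimation fits here —
  the model is rotated into the eigenbasis of `G + ridge·I`. The rotated
  model has identical structure (the overall-mean covariates pick up a
  scalar `(V'1)_k` per eigen-row) but a *diagonal* genetic prior across
  eigen-accessions. This removes the near-degenerate sum constraint that a
  centered (singular) `G` imposes on the coefficients, which otherwise makes
  the per-accession sweep mix pathologically slowly. Unbalanced designs fall
  back to the untransformed sweep.
- **Partially collapsed rescaling of C and D.** The conjugate updates
  condition on the current split of each accession's total effect
  `t_j = u_j + p_j`, but the data identify that split only through the
  eigenvalue dependence `t*_k ~ N(0, λ_k C + D)`, so the genetic vs
  permanent-environment partition is metastable — chains can stall with all
  variance assigned to one side even when the collapsed posterior prefers
  the truth by hundreds of log-units. After the conjugate draws, a
  Metropolis step rescales the per-trait blocks of `C` and `D` against the
  collapsed density `p(C, D | t)` (split integrated out), and the split is
  then redrawn exactly from its Gaussian conditional. This is a valid
  partially collapsed Gibbs move and traverses the trade-off in a few steps.
- **Method-of-moments initialization and data-scaled priors.** Starting
  values come from per-accession least squares on the shared design:
  cross-accession products give `C` without any noise correction
  (`E[t_i t_j'] = G_ij C` for i ≠ j), noise-corrected self products give
  `D`, and the per-day residual blocks come from df-corrected fit residuals.
  Estimates are clipped to positive definiteness **on the correlation
  scale** — the two traits' coefficients live on scales that differ by two
  orders of magnitude, and flooring eigenvalues of the raw matrix would
  inflate the small trait's variances. The inverse-Wishart priors are then
  centered on these starting estimates at the minimal proper degrees of
  freedom (`ν0 = dim + 2`, prior mean = the estimate, weight comparable to
  one observation). A fixed small-scale prior (`scale·I` with tiny scale) is
  configurable but *not* the default: its marginal on each variance is
  InvGamma(1.5, scale/2), a spike at zero that can absorb a weakly
  identified component entirely.

Chain defaults are 30,000 iterations, 10,000 burn-in, thinning 10. Posterior
means of the retained component draws are the reported estimates;
effective-sample-size diagnostics (initial positive sequence estimator) are
available from the draw container. Convergence is not auto-detected.

A fixed-variance mode disables all covariance updates (the draws echo the
input components and only locations are sampled); the deterministic
equivalent, `solve_mme`, builds and solves Henderson's mixed model equations
directly (dense Cholesky; the only large-dense block is `C⁻¹ ⊗ G⁻¹`) and is
what the cross-validation scenarios use for prediction.

## Prediction of unphenotyped accessions

At fixed variances, genetic values of accessions without records follow from
the genomic projection `a_test(t) = G_test,train G_train,train⁻¹ a_train(t)`
with `a_train(t) = Phi u_train`. This equals the joint-MME BLUP of
zero-record accessions exactly (same ridge on both paths), which is verified
to 1e−6 relative tolerance in the tests.

## Cross-validation scenarios

- **CV1** (prediction of new accessions): random disjoint splits, default
  245/112 per the emulated study design; variance components estimated on
  the training set per model family; at fixed variances, ST-RRM (WU only)
  and MT-RRM1 (bivariate) predict the test set by genomic projection, while
  MT-RRM2 adds the test accessions' PSA records to the MME and reads their
  WU genetic values directly off the BLUP solutions.
- **CV2** (forecasting): models train on the first 10 days (MT-RRM2's PSA
  records span all 20) and the basis rows of days 11–20 convert the genetic
  coefficients into forecasts for the same accessions.

Accuracy is the per-day Pearson correlation between predictions and the WU
BLUEs (plus, on synthetic data, the true genetic values as a diagnostic);
repeats are averaged at the accuracy level (pooling predictions across
repeats is a trivial variant but not what is reported). Every repeat derives
its split and chain seeds deterministically from one master seed
(`numpy.random.SeedSequence`), making the whole pipeline bit-for-bit
reproducible.

## Synthetic data generator

The generator mirrors the generative assumptions of the model itself:
`u ~ N(0, C ⊗ G)` and `p ~ N(0, D ⊗ I)` drawn through matrix square roots,
per-day residual pairs from `R(t)`, phenotype `Phi b + Phi u + Phi p + e`.
Defaults emulate the regime of a 357-accession, 20-day rice study:

- **Genetic covariance recipe.** Both traits load on one shared genetic
  factor whose loading curve rises concavely from 0.35 to 1.0 over the time
  course, plus a trait-specific constant factor (variance ratios 0.20 for WU
  and 0.30 for PSA relative to shared; overall scales 0.05 and 13 in
  squared trait units; a 1e−3 identity keeps `C` invertible). This yields a
  genomic correlation rising from ≈0.33 to ≈0.80 (mean ≈0.66) with the fast
  early rise and late plateau seen in such data.
- **Permanent environment** is a scaled copy of the genetic covariance,
  `D = 0.15 C` — repeated-measures resemblance at roughly one-sixth of the
  genetic scale.
- **Residual variances** are *solved per day* so the formula-implied
  heritability hits target curves exactly: WU rising linearly 0.28 → 0.69,
  PSA rising with an early-saturating quadratic 0.48 → 0.80. The residual
  correlation between traits within a day is 0.30 (same plant, same day,
  shared micro-environment).
- **Mean trajectories** are quadratic-basis projections of exponential
  growth curves (WU ≈ 0.15→1.5 kg/day, PSA 2→33 scaled pixel units), so the
  fitted fixed term is well specified; a deliberately misspecified
  true-exponential option exists for robustness checks.
- **Genotypes.** 2,000 independent biallelic markers, allele frequencies
  uniform on [0.05, 0.5]. By default the panel has *family structure*: 40
  founders drawn independently, every other accession a two-founder
  descendant via gamete sampling. This relatedness (top GRM eigenvalues ≈8
  at n = 300 versus ≈2 for an unrelated panel) is what makes the genetic vs
  permanent-environment partition statistically identifiable — with fully
  independent accessions the GRM is near-identity, the partition is almost
  unidentified, and no sampler can recover it. A real diversity panel plays
  the same role through its subpopulation structure. Plain independent
  accessions remain available (`n_founders=None`).

What the generator does **not** emulate: linkage disequilibrium,
allele-frequency differentiation between subpopulations, selection, genotype
x environment interaction, non-Gaussian residuals, residual autocorrelation
across days, and — importantly — genetic trajectories that deviate from the
quadratic basis (the truth is exactly `Phi u`). Passing tests therefore
demonstrate correctness of the machinery and recoverability of the
trajectories under the model's own assumptions, not performance on real
greenhouse data.

One consequence deserves emphasis. Under this well-specified generative
model, 10–20 daily records per accession plus strong relatedness let the
single-trait fit recover training genetic values almost completely, so the
*bivariate* models' advantage is small except where the second trait adds
genuinely new data: providing the test accessions' PSA records (MT-RRM2)
helps a lot, while MT-RRM1's oracle advantage over ST-RRM is on the order of
+0.01–0.03 accuracy and can be masked by variance-estimation noise on short
training windows. The large single- vs multi-trait gaps reported for real
experiments arise from real-data features listed above that the generative
model deliberately does not include.

## Numerical choices and problem sizes

- Ridge 1e−6 on `G` before every inversion (both MME and projection paths,
  kept identical so the joint-BLUP equivalence is exact).
- PSD clipping of moment estimates at 1e−3 of the largest eigenvalue on the
  correlation scale; residual variances floored at 1e−6.
- `rg` values beyond ±1 by more than 1e−10 raise (a PSD `C` cannot produce
  them); smaller overshoots are clipped.
- Days where a trait has zero genetic variance report `rg` as missing (NaN)
  rather than raising.
- Test and acceptance runs use reduced problem sizes chosen to keep the
  statistical properties intact: 300 accessions for trajectory recovery,
  220 accessions (150/70 splits) with shortened chains (2,000–2,500
  iterations) for the cross-validation scenarios, 2,000 markers throughout
  (GRM properties are insensitive to marker count beyond a few hundred).

## Known limitations

- Two traits maximum (the algebra generalizes; the scope does not).
- No REML/AI-REML alternative; estimates are posterior means under the
  documented priors and are convention- and prior-dependent in directions
  the data constrain weakly (e.g. high-order coefficients from short
  training windows).
- The unbalanced-design Gibbs path (accession-unbalanced record patterns)
  lacks the eigenbasis rotation and the collapsed rescaling move and can mix
  slowly; all estimation fits in the shipped workflows are balanced, and
  unbalanced *prediction* runs use the deterministic MME solver instead.
- Residual updates on days where some accessions carry both traits and
  others only one use the complete pairs only; such mixed days do not occur
  in the shipped estimation workflows.
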