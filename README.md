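# rrgp — random regression genomic prediction for longitudinal traits

`rrgp` is an analysis package for genomic inference and prediction of
time-valued traits with random regression models (RRM), built around a
synthetic re-creation of a greenhouse study in which a panel of related rice
accessions was imaged daily for 20 days, yielding two genetically correlated
longitudinal traits: daily water use (WU, from lagged pot weights) and
projected shoot area (PSA, an image-based shoot biomass proxy). WU is the
expensive, lower-heritability target trait; PSA is the cheap, highly
heritable secondary trait. The question the analyses answer is how much
jointly modeling PSA improves genomic prediction of WU — for accessions with
no WU records at all (CV1) and for forecasting future days from early
records (CV2).

## Model

For accession *j*, trait *q* and day *t*, phenotypes (per-day adjusted
means) follow

    y_qjt = Σ_k φ_k(t) b_qk + Σ_k φ_k(t) u_qjk + Σ_k φ_k(t) p_qjk + e_qjt

with quadratic Legendre polynomials φ_k of standardized time for the fixed
mean trajectory (b), additive genetic (u) and permanent-environment (p)
regressions, or in matrix form y = Xb + Zu + Qp + e with

    Var(u) = C ⊗ G,   Var(p) = D ⊗ I,   Var(e) = ⊕_t R(t)

where G = WW′/m is the genomic relationship matrix from centered, scaled SNP
dosages and R(t) is a per-day (2×2 for two traits) residual block. C and D
are estimated by a blocked Gibbs sampler (conjugate normal /
inverse-Wishart updates plus a partially collapsed move that keeps the
genetic vs permanent-environment partition mobile); predictions use
Henderson's mixed model equations at fixed variances. Per-day summaries are
the heritability h²(t) = g(t)/(g(t)+pe(t)+ve(t)) and the genomic correlation
rg(t) = t_i C₁₂ t_i′ / √(t_i C₁ t_i′ · t_i C₂ t_i′), with t_i = φ(t).

See `docs/methods.md` for conventions, the sampler, the synthetic-data
recipe, and what the synthetic study does and does not demonstrate.

## Worked example

```python
from rrgp import (SyntheticConfig, RRMSpec, GibbsConfig, build_design,
                  gibbs_sample, heritability, genomic_correlation,
                  simulate_dataset)

cfg = SyntheticConfig(n_accessions=300, seed=2024)
geno, grm, phenos, truth = simulate_dataset(cfg)   # 300 x 20 d x 2 traits
basis = cfg.basis()
model = build_design(phenos, basis, RRMSpec(traits=("WU", "PSA")), grm)
draws = gibbs_sample(model, GibbsConfig(n_iter=12_000, burn_in=4_000,
                                        thin=8, seed=1))
pm = draws.posterior_mean()
h2_wu = heritability(pm, basis, 0)
rg = genomic_correlation(pm, basis)
```

Running exactly this fit (`python analysis/03_fit_trajectories.py`) prints:

```
Gibbs: 12000 iterations in 63 s, 1000 retained draws
h2_wu: estimated range [0.23, 0.70], mean abs deviation from truth 0.032
h2_psa: estimated range [0.52, 0.86], mean abs deviation from truth 0.064
rg: estimated range [0.36, 0.80], mean abs deviation from truth 0.011
```

i.e. the estimated WU heritability rises from ≈0.23 on day 1 to ≈0.70 on day
20 (the generative truth rises 0.28 → 0.69), PSA's is higher throughout, and
the estimated genomic correlation between the traits climbs from ≈0.36 to a
≈0.80 plateau — recovering the generative trajectories to within a few
hundredths.

## The analyses

Numbered drivers under `analysis/` reproduce the study workflow; each writes
its tables under `results/` and prints what it found:

| script | what it does |
|---|---|
| `01_simulate_cohort.py` | generate the cohort; panel and truth summaries |
| `02_stage1_blues.py` | pot weights → WU → per-day BLUEs (stage one) |
| `03_fit_trajectories.py` | Gibbs fit; h²(t) and rg(t) vs truth |
| `04_cv1_prediction.py` | CV1: predict accessions with no WU records |
| `05_cv2_forecast.py` | CV2: forecast days 11–20 from days 1–10 |

A thin CLI mirrors the same steps for file-based use:
`rrgp simulate | qc | grm | blue | fit | summaries | cv1 | cv2`
(see `rrgp --help`).

## Layout

```
src/rrgp/        geno, basis, model, inference, summaries, pipeline,
                 synthdata, cli  — the library every script and test imports
analysis/        numbered narrative drivers (see above)
scripts/         acceptance.py
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  model conventions, sampler details, generator recipe
```
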