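# ecoeff — agricultural eco-efficiency measurement and inference

`ecoeff` is a tested re-implementation of a complete measurement-and-inference
chain used in agro-environmental economics to ask whether digital
infrastructure improves **agricultural eco-efficiency (AEE)** — a score that
credits a region for agricultural output and crop carbon sequestration while
debiting it for carbon emissions and non-point-source pollution. The package
is aimed at researchers who want the full chain — accounting, efficiency
scoring, index construction, panel econometrics — as composable, unit-tested
Python components, exercised end-to-end on synthetic province-year panels
with known ground truth.

## The chain

1. **Carbon accounting.** Crop carbon sequestration
   `CSA = Σᵢ (1−rᵢ)·csᵢ·yᵢ/HIᵢ` (economic yield `yᵢ`, water content `rᵢ`,
   uptake rate `csᵢ`, economic coefficient `HIᵢ`; 15 crops) and carbon
   emission `CE = Σᵢ βᵢAᵢ` over six activity sources (pesticides, fertilizer,
   diesel, film in kg; irrigation and tillage in hm²), with the coefficient
   tables shipped as editable CSV resources.
2. **Efficiency scoring.** A super-efficiency slacks-based-measure (SBM) DEA
   model with undesirable outputs: interior units get the standard SBM score

   `ρ = [1 − (1/m)Σ s⁻ᵢ/xᵢₖ] / [1 + (1/(r₁+r₂))(Σ s^d_s/y^d_sk + Σ s^u_q/y^u_qk)] ≤ 1`,

   and frontier units are re-scored against the frontier built **without**
   them, allowing scores above 1. Both fractional programs are solved as
   linear programs after the Charnes–Cooper substitution (HiGHS via SciPy),
   under constant or variable returns to scale.
3. **Index construction.** An entropy-weight method (weights proportional to
   `1−eⱼ`, `eⱼ` the cross-unit Shannon entropy of indicator `j`) builds the
   information and innovation sub-indices; a coupled-coordination degree
   `D = √(C·T)`, `C = 2√(u₁u₂)/(u₁+u₂)`, couples traditional infrastructure
   with the informatization degree into the convergence sub-index; the
   composite index is the expert-weighted sum `NDI = 0.4·INFI + 0.3·CI +
   0.3·INNI`.
4. **Econometrics.** Pooled ("mixed") OLS with 1% winsorization, a
   grid-search threshold regression in the innovation sub-index with a
   residual-bootstrap F test (sequential single/double decision), an
   urbanization-interaction moderation model with year fixed effects, a
   lag-1 robustness fit, a censored-normal (Tobit) MLE, 2SLS with a
   first-stage excluded-instrument F, and period/region subsample splits.

All estimators run against a synthetic-data module whose panels carry their
generating truth, so every stage is testable without any external data.

## Worked example

Simulate a panel that hides a two-regime effect of the innovation sub-index
(slope 15 below the cut 0.28, −4 above it, noise s.d. 0.5) and let the
threshold machinery find it:

```sh
printf 'beta_low: 15.0\nbeta_high: -4.0\ntheta_true: 0.28\nsigma_eps: 0.5\n' > dgp.yaml
ecoeff simulate --config dgp.yaml --out panel.csv --seed 0
ecoeff fit --panel panel.csv --model threshold --seed 0
```

```
theta = 0.2780  F = 2866.65  boot p = 0.0000  thresholds = 1
[threshold]  N = 300
       const   2.9847*** ( 3.51)
    inni_low   14.1524*** ( 31.09)
   inni_high  -4.1724*** (-19.10)
...
```

i.e. the estimated cut lands one grid point from 0.28, the bootstrap
confidently detects exactly one threshold, and both regime slopes are
recovered within two standard errors. The numbered drivers under `analysis/`
run the whole study: `01_simulate` writes the raw tables,
`02_carbon_accounts` the CSA/CE accounts, `03_dea_scores` the CRS and VRS
efficiency scores (e.g. 53 of 300 unit-years super-efficient under CRS),
`04_ndi_index` the composite index, and `05_regressions` the full estimator
battery against the known truth. A single `ecoeff run --config study.yaml`
executes the same pipeline with a hash-stamped manifest.

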