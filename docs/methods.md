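# Methods

This note records the models implemented in `ecoeff`, the defaults and the
reasoning behind the genuinely open design choices, and what the synthetic
experiments do and do not demonstrate.

## Carbon accounting

Sequestration sums over crops: dry matter `(1−r)·y` is converted to carbon
with the crop's uptake rate `cs`, and the economic coefficient `HI`
translates economic into biological yield. The applied literature is split
on whether `HI` divides (biological = economic / harvest index) or
multiplies; the printed formula is a plain product but no worked value
discriminates. We default to **divide** — the standard
biomass-from-economic-yield conversion — and expose `hi_mode="multiply"` as
a switch.

Emission factors (kg per kg of pesticide 4.9341, fertilizer 0.8956, diesel
0.5927, film 5.18; kg per hm² of irrigation 266.48, tillage 312.6) ship as a
CSV resource; user tables with the same columns extend both vocabularies.
Activities are validated per unit class (mass vs. area); the aggregate is
reported in tons. "Fertilizer" is taken in pure-nutrient (discounted) tons
as given — no gross-weight conversion is attempted. Livestock methane is
out of scope; the four pollution components (COD, NH, TN, TP) are accepted
as inputs and summed.

## Super-efficiency SBM with undesirable outputs

Scoring is two-stage, which is what the applied efficiency literature means
by a "super-SBM" model:

1. the standard SBM with undesirable outputs (inputs contract, desired
   outputs expand, undesired outputs contract, all as slack ratios) gives
   `ρ ≤ 1`, with `ρ = 1` exactly on the frontier;
2. frontier units are re-scored against the technology built without them:
   the projected point must weakly worsen the unit
   (`x̄ ≥ x_k, ȳᵈ ≤ yᵈ_k, ȳᵘ ≤ yᵘ_k`) while remaining dominated by the
   remaining reference set, giving a super-efficiency score `δ ≥ 1`.

A single-stage program cannot deliver both behaviours: the exclusion
program's constraints force its optimum to 1 or above for every unit, so
interior units must be scored by the standard model. Both stages are
Charnes–Cooper linearizations solved with HiGHS; scores are exposed at full
precision and rounded to 4 decimals only in CSV output.

Numerical/degenerate-case policy:

* data must be strictly positive (SBM ratios are undefined at zero); zeros
  are rejected, not epsilon-shifted;
* VRS super-efficiency can be genuinely infeasible (a known pathology for
  extreme units). `sbm_super_efficiency` reports `status="infeasible_super"`
  with no score; `score_panel` substitutes the standard inclusive score
  (1.0) with a logged warning so regression panels stay balanced;
* the frontier is **pooled** across all unit-years by default, making score
  levels comparable over time; `frontier="by_year"` scores each
  cross-section separately. With pooled super-efficiency, a unit replicated
  in another year pins its score at exactly 1.

## Index construction

Min-max normalization is direction-aware and shifts by ε = 1e-4
(`v → (v+ε)/(1+ε)`) so entropy logarithms are defined; constant columns are
flagged degenerate and zero-weighted rather than dropped, keeping the panel
balanced. Entropy weights are computed on the pooled unit-year panel (one
weight vector for all years) so index levels are comparable over time;
per-year weighting is possible by slicing the matrix.

The convergence sub-index couples two subsystem scores — traditional
infrastructure and informatization degree, each an entropy-weighted block
composite — through the canonical two-system coupled-coordination model
`C = 2√(u₁u₂)/(u₁+u₂)`, `T = αu₁+βu₂` with α = β = 0.5, `D = √(CT)`. The
composite uses fixed expert weights (0.4, 0.3, 0.3); the elicitation behind
them is out of scope and the weights are configurable inputs.

## Econometrics

* **Baseline.** Pooled OLS of AEE on one index plus five controls, with
  symmetric order-statistic winsorization (default 1%, pooled across the
  panel) and both conventional and HC1 standard errors (the variance
  estimator is not dictated by the design; conventional SEs are reported by
  default, robust ones carried alongside). Unit fixed effects are
  deliberately not the default — the baseline is a pooled ("mixed")
  regression.
* **Threshold model.** Grid = distinct observed values of the threshold
  variable inside the 1%/99% quantiles; θ̂ minimizes the two-regime SSR;
  `F = n(SSR₀−SSR₁)/SSR₁` with a 300-draw i.i.d. residual bootstrap for its
  null distribution, sequential testing up to two thresholds at the 5%
  level. Implementation detail: the candidate regime columns are
  residualized once on the non-threshold regressors, after which every SSR
  and every bootstrap replication is a single matrix product — an exact
  Frisch–Waugh reformulation that makes the bootstrap cost negligible.
  *Limitation:* the bootstrap resamples residuals independently; if the
  error term hides a persistent omitted component (e.g. the non-innovation
  parts of the composite index when only the innovation term enters the
  model), the test over-rejects (~10% at nominal 5% in our experiments).
  The calibration test therefore uses a null DGP whose errors are i.i.d.
* **Moderation.** AEE on NDI, urbanization, their interaction, controls and
  (optionally) year dummies; `marginal_effect(fit, lu)` returns α₁ + α₃·LU.
* **Tobit.** Censored-normal MLE (configurable lower/upper bounds),
  parameterized in (β, log σ), BFGS from OLS start values, standard errors
  from the numerical Hessian. With no censored rows the MLE equals OLS.
* **2SLS.** One excluded instrument; the first stage reports the excluded
  instrument's F (squared t) with a weak-instrument warning below 10;
  second-stage standard errors use structural residuals computed with the
  original regressor. Controls enter both stages.
* **Subsamples and lags.** Splits re-run the baseline per side; the lag-1
  fit replaces the index by its within-unit lag (the first year drops, so a
  30×10 panel yields N = 270).

## Synthetic data

The generator emulates the study conditions: a balanced 30-unit × 10-year
panel. Physical quantities are log-normal around a persistent unit scale
factor (larger units have proportionally larger inputs *and* outputs, which
keeps DEA scores non-degenerate). Bounded sub-indices have Beta marginals
matched to the reference descriptive moments (INFI mean 0.26 sd 0.18, CI
0.41/0.23, INNI 0.21/0.15) and a Gaussian-copula unit random effect carrying
85% of the latent variance — infrastructure endowments move slowly, which is
also what makes the lag-1 regression informative. The composite identity
`NDI = 0.4·INFI + 0.3·CI + 0.3·INNI` holds inside every generated panel.
Urbanization is a persistent unit level on [35, 90]% with a slow upward
trend; controls are independent Gaussians with the reference moments, and
their true outcome coefficients default to the reference baseline estimates.

The outcome is `AEE = α₀ + β·NDI + β_low·INNI·1[INNI≤θ] +
β_high·INNI·1[INNI>θ] + γ·NDI·LU + α₂'Controls + ε`, ε i.i.d. Gaussian. By
default the threshold and interaction terms are off (β_low = β_high = γ = 0,
β = 1, σ = 0.3), so the default DGP is exactly the baseline equation;
recovery experiments switch individual features on (threshold experiments
use β_low = 15, β_high = −4, θ = 0.28, σ = 0.5). Left-censoring for Tobit
experiments uses the empirical `censor_frac` quantile of the latent outcome
as the bound, stored on the returned object. All randomness flows through
one seeded generator; identical configuration is bit-identical. Truth
travels with the panel object so recovery tests cannot desynchronize.

What the generator does **not** emulate: spatial dependence between units,
measurement error in the indicator blocks, trends in the outcome, or any
link between the DEA-scored activity panel and the regression DGP's outcome
(the pipeline regresses DEA scores on constructed indices as an integration
exercise; only the DGP panels carry known truth). Passing tests therefore
demonstrate correctness of the estimators under the stated conditions, not
empirical conclusions about any real panel.

## Problem sizes and verification

The test suite verifies, among others: the hand-computed accounting
examples; exact reproduction of the shipped coefficient tables; DEA
equivalence with a closed-form best-ratio oracle on 200 single-input/output
instances (≤1e-6) and with an independent direct solve of the fractional
programs on small multi-dimensional instances with undesirable outputs
(≤1e-6); threshold-location recovery within one grid step in ≥90% of 50
replications; 95% CI coverage for the baseline slope, the interaction and
the Tobit slope within ±5 points of nominal over 200 panels; and the
degenerate-limit identities (Tobit=OLS uncensored, 2SLS=OLS under a perfect
instrument, duplicate-unit super-efficiency = 1). Panel-scoring unit tests
run at 10 units × 3 years; the full 300-unit-year scoring runs in
`analysis/03_dea_scores.py` and the pipeline.
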