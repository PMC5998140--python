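# Methods

This note records the statistical conventions, numerical choices and
known limitations behind `fertresp`. Empirical figures quoted here are
the ones the test suite and `scripts/acceptance.py` themselves compute.

## Data model

A "3414" trial tests N, P₂O₅ and K₂O at four levels — 0, 0.5, 1 and 1.5
times a locally recommended level-2 rate — in the 14 standard treatment
combinations. `TrialRecord` validates completeness (exactly the 14
codes, no duplicates) and rate consistency (each observed rate must
match multiplier × level-2 rate within 0.5 kg/hm², absorbing rounding in
published tables). All model fitting operates on the 14 treatment yield
*means*. This follows from the degrees of freedom of the significance
tests (below): with n = 14 and 10 quadratic coefficients the residual df
is 4, which is how published F tests for such trials are computed.
Standard deviations and replicate counts are carried for simulation and
display only.

The six built-in trials (Pinghe and Xianyou counties, low/medium/high
soil fertility) use per-site designs: 165-75-105 kg/hm² in Pinghe,
165-56-109 for Xianyou low/medium and 165-53-112 for Xianyou high.

## Estimation

**Quadratic surface (TPFM).** OLS on the design matrix
(1, N, P, K, N², P², K², NP, NK, PK) via the numpy least-squares solver;
a rank check names collinear columns (pivoted QR) before fitting. The
tests cross-check coefficients and statistics against an independent OLS
implementation.

**Non-structural surface (TNFM).** Nonlinear least squares
min Σᵢ (Yᵢ − f(Xᵢ, θ))², θ = (A, N₀, P₀, K₀, c₁, c₂, c₃), with
Levenberg–Marquardt and an analytic Jacobian. Estimation is
*unconstrained*: negative estimates must be reachable because the
typicality screen, not the optimizer, judges sign plausibility.

- *Initialization.* N₀, P₀, K₀ start at the level-2 design rates; each
  cᵢ at 1/(2 × level-2 rate), which places the implied optimum near the
  level-2 dose; A is chosen so the surface reproduces the control
  (zero-fertilizer) yield at the origin exactly.
- *Multi-start.* The objective is multimodal in principle, so the
  default fit runs 20 starts: the initializer plus 19 seeded log-normal
  multiplicative perturbations (log-sd 0.5) of it; the lowest SSE wins.
  A fixed seed gives bit-identical results across runs.
- *Tolerances.* xtol = ftol = gtol = 1e-12, at most 2000 residual
  evaluations per start. On the built-in trials every start converges in
  well under 100 evaluations.
- *Degenerate ridges.* On noisy data the unconstrained SSE infimum can
  lie on a ridge with no finite minimizer — e.g. P₀ → ∞ with A → 0 and
  c₂ < 0, the P factor degenerating towards a non-saturating profile. A
  start stopped by the evaluation cap on such a ridge is kept as a
  candidate and the result is flagged `converged=False`; these fits fail
  the sign screen downstream, which is the correct scientific verdict.
  `FittingError` is reserved for runs that produce no finite iterate at
  all.
- *Overflow guard.* `tnfm_predict` raises rather than overflow when
  |c₁N + c₂P + c₃K| > 700; inside the optimizer the exponent is clipped
  at ±500 so wild intermediate iterates produce large finite residuals
  instead (the clip cannot bind near any optimum of interest).

**Goodness of fit.** SST is taken about the observed mean; R² = 1 −
SSE/SST (negative for fits worse than the mean); F = ((SST−SSE)/df_reg)
/ (SSE/df_res) with df_reg = 9 (TPFM) or 6 (TNFM) and df_res = n −
df_reg − 1; P is the upper F tail. Significance for the NRSS gate uses
α = 0.05 (p < α), reproducing the published significant/nonsignificant
split of the built-in trials (site-5 quadratic p ≈ 0.038 significant,
site-6 p ≈ 0.079 not).

## Typicality screen

Gates run in order and the verdict is the first failure:

1. **NRSS** — regression not significant at α.
2. **PS** — signs: TPFM requires b₁..b₃ > 0 and b₄..b₆ < 0 (interaction
   coefficients b₇..b₉ are deliberately unconstrained — they vary in
   sign across perfectly reasonable fits); TNFM requires all seven
   parameters > 0.
3. **Max** — TPFM: a unique critical point (3×3 solve; treated as
   singular when |det| < 1e-12 × the Hessian's scale cubed, separating
   structural singularity from round-off) with principal minors G₁ < 0,
   G₂ > 0, G₃ < 0, i.e. negative-definite curvature. TNFM: all-positive
   parameters guarantee an interior global maximum, so this gate cannot
   fail once PS passes.
4. **RF** — the recommended rates must lie in [0, 1.5 × level-2 rate]
   per nutrient, boundary inclusive, using each trial's own design.
   With prices both the maximum and the economic rates are checked;
   without prices only the maximum rates are, and the verdict is marked
   `price_free`.

On the built-in trials the quadratic family gives 3 TYPICAL, 2 Max
failures and 1 NRSS. The non-structural family gives 5 TYPICAL and 1 RF:
the Xianyou-medium fit puts its P₂O₅ maximum at ≈88 kg/hm², just outside
that design's 84 kg/hm² bound. The reference table published with these
trials marks that site typical; the rule as stated, applied to the very
parameters printed beside it, says otherwise, and this package follows
the rule.

## Recommendations

Maximum rates: closed form 1/cᵢ − (soil supply) for the TNFM; the
critical point of the quadratic for the TPFM (refusing, with the failed
minor named, when the curvature is not negative-definite). Economic
rates equate each marginal product with the price ratio (α, β, γ) =
(P_N, P_P, P_K)/P_Y. For the TPFM that is one linear solve. For the TNFM,

    N_eco = 1/(c₁ + α/Y_eco) − N₀  (etc.),

a fixed point in Y_eco solved by seeding Y_eco with the maximum yield
and iterating; the stopping rule is a componentwise rate change below
0.1 kg/hm² (well under agronomic relevance), capped at 5 iterations by
default. The mapping contracts by roughly a factor of 10 per iteration;
across the six built-in parameter sets and integer price ratios 1–10 the
5th iterate is always within 0.8 kg/hm² of the exact fixed point — i.e.
within the 1 kg/hm² precision at which rates are reported — while the
strict 0.1 kg/hm² successive-change criterion needs 6–7 iterations in
the slowest ~10% of price combinations, which the `converged` flag then
honestly reports. The economic yield sequence decreases monotonically
after the seed, and economic rates never exceed maximum rates for
positive prices. Displayed rates and yields are rounded to whole
kg/hm²; full precision is kept internally. Negative economic components
(possible under steep prices) are returned un-clipped — range judgement
belongs to the typicality screen.

## Quadratic reduction

`tnfm_to_quadratic` truncates each exponential factor to first order
(e^x ≈ 1 + x) and drops pairwise/triple products of the c's and the
three-way interaction, yielding the printed ten-coefficient quadratic
with B = 1 − N₀c₁, C = 1 − P₀c₂, D = 1 − K₀c₃. No higher-order
correction is applied. Note the truncation is *qualitative*, not
numerically tight at field rates: at a level-2 dose c·x ≈ 0.5, where
e^x differs from 1 + x by ~18%, and across the built-in parameter sets
the reduction deviates from the full surface by 27–41% at the outer
design points. The reduction explains the structural kinship of the two
families; it is not an accurate surrogate for prediction.

## Synthetic trials and the success-rate experiment

`generate_trial` draws, for each of the 14 treatments, `reps` replicate
yields = surface value + Gaussian(0, noise_sd), then records their mean
and sample sd — the shape a field report publishes. Defaults are 3
replicates and noise_sd = 300 kg/hm², matching the replicate scatter of
the built-in trials (their per-treatment sds centre around 300–600
kg/hm²; a mean of 3 draws at sd 300 has sd ≈ 173). Negative replicates
are truncated at zero and counted (`return_info=True`); a treatment
whose replicates are all truncated aborts generation. Gaussian noise is
an idealisation: real trials add block effects, spatial trend and
season-by-site interaction, none of which are modelled, so passing
recovery tests demonstrate estimator correctness under the stated noise
model, not field-scale guarantees.

`recovery_experiment` simulates trials per condition (seeds spawned per
replicate, so conditions are independent and the whole experiment is
reproducible), fits both families, screens both, and reports per-family
typical percentages plus bias/RMSE of the recovered non-structural
parameters. At the default conditions (site-1 truth, 165-75-105 design,
sd 300, 200 replicates) the non-structural family attains a higher
typical rate than the quadratic family (≈69% vs ≈56% at seed 1) — a
desk-scale analogue of multi-site success-rate surveys. Parameter
identifiability is uneven: the effect coefficients c₁ and c₃ recover
with ~10–14% median relative error at these conditions, while c₂ is
markedly weaker (~27%) because the P design range (0–112.5 kg/hm²) is
the narrowest relative to its soil supply equivalent; pooled across the
three coefficients the median error is ~15%.

## Known limitations

- Fitting uses treatment means, so replicate-level variance information
  is ignored (no weighting); trials reporting only means remain fully
  supported.
- The significance test treats the 14 means as independent
  observations, inheriting the convention of the published tables.
- The economic optimum ignores fixed application costs and price
  uncertainty.
- The typicality classes are a screen, not a model-selection criterion;
  a non-typical fit can still describe the data well (high R²) while
  being unusable for dose recommendation.
- The six built-in trials are early rice from one province; nothing in
  the code is rice-specific, but defaults (noise, designs) reflect that
  provenance.
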