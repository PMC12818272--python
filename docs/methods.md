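# Methods

## Model and assumptions

Outcomes are modelled as independent Bernoulli random variables
`Y_i ~ Bern(q_i)` with true individual risks `q_i ∈ [0, 1]`; predictions
`p_i ∈ [0, 1]` are evaluated by the Brier score
`BS = (1/n) Σ (p_i − y_i)²`. All expectation formulas follow from this
model alone:

- `E[BS] = (1/n) Σ [(p_i − q_i)² + q_i(1 − q_i)]`, since
  `E[(p − Y)²] = (p − q)² + Var(Y)`. The first term is `l2(p, q)²/n`
  (Euclidean distance squared), the second the perfect-prediction floor.
- Strict properness and the distance-ordering property are immediate
  consequences; they are nevertheless *verified by enumeration* in the
  tests (exhaustive 0.01-step grid search over predictions at n ≤ 3)
  rather than assumed.
- Shifting every prediction by ±ε raises the expectation by exactly ε²,
  whatever the sign pattern.
- Jensen: `(1/n) Σ q_i(1−q_i) ≤ q̄ − q̄²`, with equality iff all `q_i`
  coincide; the difference is the population variance of `q`.

Independence across subjects is assumed throughout; no clustering,
covariate shift or informative missingness is modelled.

## Calibration-in-the-large

CIL is the difference form `mean(p) − mean(y)` (expectation
`mean(p) − mean(q)`). The logistic-intercept recalibration variant is not
implemented; the difference form is the one whose closed-form values the
analytic examples reproduce (0 for the calibrated pair, ≈ 0.2224745 for
the overestimating pair `p′ = (0.444949, 1)` on `q′ = (0.2, 0.8)`).

A note on that overestimating example: computing its expected Brier score
through the decomposition gives
`((0.244949² + 0.16) + (0.2² + 0.16))/2 = 0.21`, not the 0.2 sometimes
quoted alongside it. The package always computes through the
decomposition and never hard-codes a headline value.

Similarly, the Unif(0,1) perfect-prediction expectation is
`E[q(1−q)] = 1/6 ≈ 0.1667`; a two-decimal rendering of 0.16 appears in
some summaries of this setting but is a truncation, and is not used as a
numeric reference anywhere.

## Perturbation families

`p = f(q)` with three miscalibration families besides the identity:

| kind | rule | magnitude meaning | default |
|---|---|---|---|
| `additive_bias` | `p_i = q_i + ε` | bias ε ≥ 0 | — |
| `uniform_noise` | `p_i = q_i + U_i`, `U_i ~ Unif(−m, m)` | half-width m | m = 0.1 in the shipped suite |
| `logit_noise` | `p_i = expit(logit(q_i) + δ_i)`, `δ_i ~ N(0, m)` | logit-scale SD | — |

The logit-scale error law is taken Normal — the natural symmetric choice
on that scale; `q_i ∈ {0, 1}` are fixed points (logit undefined there).
Out-of-range values are clamped to [0, 1] by default (`clip_to_unit`);
the `reject` policy aborts the replicate instead. For Unif(0,1) truth and
m = 0.1, clamping lowers the exact expectation `1/6 + m²/3 = 0.17` by
about 1.7 × 10⁻⁴, i.e. it is invisible at two decimals; the per-replicate
analytic expectation recorded by the engine uses the *actual* (possibly
clamped) predictions, so consistency checks are exact either way.

## Truth distributions and the model-based scenario

Families: `constant(c)`, `uniform(a, b)`, `beta(α, β)`,
`two_point(v0, v1, w)` (the degenerate 0/1 mixture makes perfect
predictions score exactly zero), and `logistic_model`. The logistic family
emulates risks produced by a fitted logistic regression on population
survey data: covariates `x_i ~ N(0, I_k)` i.i.d.,
`q_i = expit(β0 + x_iᵀβ)`, optionally generated as a large pool and
subsampled without replacement. Because the linear predictor is
`N(β0, ‖β‖²)`, the intercept achieving a target mean risk is solved
deterministically by adaptive quadrature plus Brent root finding (the
solve is exact to ~1e−10, far inside the 0.01 tolerance it is checked
against). Defaults: k = 3 covariates with β = (0.5, 0.5, 0.5) — a
moderate risk spread — at 20% target prevalence, a typical event rate for
the epidemiological settings this emulates. No real survey data are
touched; the emulation reproduces the *mechanism* (regression-derived
risks, subsampling), not any particular fitted model's risk values, which
is why the model-based panels are checked structurally rather than
numerically.

## Simulation design

A scenario fixes truth distribution, perturbation, sample size n,
replicate count R and a master seed. The shipped suite uses
n ∈ {300, 1000} and R = 5000 (the `--smoke` flag scales R to 200 for
quick passes; the test suite uses a few hundred replicates so the whole
run stays in seconds — replicate means are then compared within 4
standard errors, which adapts to the size used). Per replicate the engine
redraws `q` i.i.d. by default; `redraw_truth=False` fixes one `q` vector
across replicates, matching designs where risks are fixed model outputs.

Seeding: the master seed spawns one `numpy.random.SeedSequence` child per
replicate (plus one reserved for a fixed truth draw), so replicates are
independent streams, bit-reproducible, and independent of execution
order.

Summaries: medians and 5%/95% percentiles use numpy's
linear-interpolation quantile convention. Proportions of the events
`ȳ − ȳ² > BS` and `BS > ȳ − ȳ²` carry 95% percentile-bootstrap intervals
(1000 resamples of whole replicates, seeded). `evaluate_predictions`
bootstraps `(p_i, y_i)` pairs instead, since there a single dataset is
the resampling unit.

## Numerical conventions and degenerate inputs

- Closed-form identities are asserted at absolute tolerance 1e−12;
  Monte-Carlo agreement at 4 standard errors.
- Strict event inequalities use an absolute margin of 1e−12 so quantities
  that tie in exact arithmetic (e.g. `ȳ − ȳ²` vs `BS` under constant
  truth with `ȳ = q`, where the difference is exactly `−(ȳ − q)²`) are
  never flipped by float round-off; genuine differences are at least
  `1/n²` for the sample sizes used. The same convention would misclassify
  true differences only for n ≳ 10⁶.
- n = 1 is allowed everywhere. The scaled Brier score raises a dedicated
  error when `ȳ ∈ {0, 1}` (zero reference variance) instead of returning
  infinity; `evaluate_predictions` marks it unavailable and reports the
  rest.
- A constant-truth identity scenario at q = ½ has a *deterministic* score
  (`(½ − y)² = ¼` regardless of y): the reference `ȳ − ȳ²` then never
  strictly exceeds the score — the exact binomial enumeration in the
  tests confirms probability 0 — while the score exceeds the reference
  with probability `1 − P(ȳ = ½)`. Both orderings are therefore recorded
  per replicate.
- The ε-sweep refuses values that push any prediction outside [0, 1]
  rather than clipping silently, because its ε² claim holds only
  unclipped.

## What the synthetic generator does and does not show

The generator reproduces the stochastic structure the analysis needs —
i.i.d. risks from known families, Bernoulli outcomes, controlled
miscalibration — and therefore demonstrates *properties of the score*,
not properties of any real clinical model. Real data add correlated
covariates, non-logistic risk surfaces, finite-population and sampling-
design effects, and model-fitting noise in `p`; none of these are
emulated, so passing tests certify the score's behaviour under the stated
data-generating processes only. In particular, absolute levels of the
model-based (logistic) panels depend on coefficients no synthetic choice
can pin down, which is why only their qualitative structure (score below
the `q̄ − q̄²` bar, noise shifting the distribution upward, nonzero
probability of overshooting the reference at n = 300) is claimed.

## Known limitations

- Binary outcomes only: no survival/censoring-weighted scores, no
  multi-category extension.
- CIL is the only calibration measure; calibration slopes/curves,
  discrimination (c-index) and decision-analytic measures are out of
  scope.
- Slope-type miscalibration (`p = expit(a + b·logit(q))`, b ≠ 1) is not
  among the perturbation families.
- Plotting is limited to the numeric summaries needed to draw the usual
  violin/percentile figures; no publication graphics are produced.
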