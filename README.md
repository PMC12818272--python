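# brierlab

Tools for understanding — and correctly reporting — the Brier score of
binary risk-prediction models, aimed at biostatisticians and
epidemiologists who evaluate clinical or public-health prediction models.

The Brier score of predictions `p = (p_1, …, p_n)` against binary outcomes
`y = (y_1, …, y_n)` is

```
BS(p, y) = (1/n) Σ (p_i − y_i)²
```

When outcomes arise as independent Bernoulli draws `Y_i ~ Bern(q_i)` from
true individual risks `q_i`, its expectation decomposes exactly:

```
E[BS] = (1/n) Σ (p_i − q_i)²   +   (1/n) Σ q_i (1 − q_i)
        └── distance to truth ──┘   └── irreducible Bernoulli noise ──┘
```

The second term means a *perfect* model (`p = q`) does not score zero; the
first means a uniform ±ε miscalibration raises the expectation by exactly
ε². The score is strictly proper (uniquely minimised at `p = q`) and
preserves the Euclidean-distance ordering of models, but only *in
expectation*: the realised score is a random variable, and at modest sample
sizes it can exceed the naive prevalence reference `ȳ − ȳ²` or rank a
worse model ahead by chance. `brierlab` makes all of this computable:

- **metrics** — observed and expected Brier score, the perfect-prediction
  floor `(1/n) Σ q_i(1−q_i)`, the prevalence reference `ȳ − ȳ²` and its
  truth analogue `q̄ − q̄²`, calibration-in-the-large `mean(p) − mean(y)`,
  the scaled Brier score `1 − BS/(ȳ(1−ȳ))`, and the Euclidean distance
  underlying the ordering property.
- **perturbations** — identity, additive bias, Unif(−m, m) noise, and
  symmetric Normal logit-scale error, with explicit clipping policy.
- **synthetic_truth** — truth distributions (constant, uniform, beta,
  two-point, and a logistic risk model with standard-normal covariates and
  a numerically solved intercept hitting a target prevalence) plus
  Bernoulli outcome generation, all seeded and bit-reproducible.
- **simulation** — a Monte-Carlo scenario engine recording per-replicate
  Brier score, perfect-prediction score, CIL, the reference gap
  `ȳ − ȳ² − BS_perf`, and both strict orderings of score vs reference,
  summarised by medians, 5%/95% percentiles and bootstrap CIs.
- **pipeline / CLI** — a configuration-driven suite runner and a one-shot
  evaluator implementing the recommended reporting defaults (prevalence
  baseline, bootstrap uncertainty).

## Worked example

Evaluate a CSV of predictions and outcomes (header `p,y`):

```bash
$ cat example.csv
p,y
0.2,0
0.8,1
0.5,1
0.5,0
$ brierlab evaluate --input example.csv --bootstrap 1000 --seed 1
{
  "n": 4,
  "brier": 0.145,
  "prevalence_reference": 0.25,
  "cil": 0.0,
  "scaled_brier": 0.42000000000000004,
  "brier_ci95": [
    0.039999999999999994,
    0.25
  ],
  "bootstrap_reps": 1000
}
```

The Brier score 0.145 beats the prevalence baseline `ȳ − ȳ² = 0.25`
(scaled Brier 0.42, i.e. a 42% improvement over predicting the constant
incidence), the model is calibrated in the large (CIL 0), and the wide
bootstrap interval [0.04, 0.25] shows how noisy a 4-observation score is.

The same machinery runs from Python:

```python
import brierlab as bl

# a perfectly calibrated pair of risks still scores 0.21 in expectation
bl.expected_brier([0.3, 0.7], [0.3, 0.7]).value   # 0.21
bl.perfect_expected_brier([0.3, 0.7]).value       # 0.21 (floor; p = q)

# a ±0.1 miscalibration of every prediction adds exactly 0.1² = 0.01
bl.expected_brier([0.4, 0.6], [0.3, 0.7]).value   # 0.22
```

Run the full simulation suite (all misconception demonstrations; use
`--smoke` for a 200-replicate quick pass):

```bash
brierlab simulate --smoke --out results/ --seed 1
```

which writes per-scenario `*_replicates.csv` / `*_summary.csv` files and a
`suite_report.json` pairing every empirical summary with its analytic
expectation. In that report, for example, the Unif(0,1)-truth scenario
with Unif(−0.1, 0.1) prediction noise at n = 1000 has median Brier score
0.1704 against the analytic expectation 1/6 + 0.01/3 = 0.17, while the
constant-½ truth scenario sits at exactly 0.25 even though its predictions
are perfect.

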