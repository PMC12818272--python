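"""Data-generating mechanisms for true risks q and Bernoulli outcomes y.

Families of truth distributions:

* ``constant`` — every subject shares one risk c;
* ``uniform`` — q_i ~ Unif(a, b) i.i.d.;
* ``beta`` — q_i ~ Beta(α, β) i.i.d. (right-skewed risks for α < β);
* ``two_point`` — q_i = v1 with probability w, else v0 (the degenerate
  0/1 mixture makes perfect predictions score exactly zero);
* ``logistic_model`` — q_i = expit(β0 + x_iᵀβ) with covariates x_i drawn
  i.i.d. standard normal.  This emulates a survey-fitted logistic
  risk model (probabilities produced by a regression on population
  covariates, optionally generated as a large pool and subsampled without
  replacement) with a fully synthetic covariate law.

Outcomes are always independent Bernoulli draws, Y_i ~ Bern(q_i).  All
sampling is driven by an explicit seed/generator, so a fixed seed yields
bit-identical q and y across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .metrics import TruthModel, ValidationError

__all__ = [
    "TRUTH_FAMILIES",
    "TruthDistributionSpec",
    "ConvergenceError",
    "sample_true_probabilities",
    "sample_outcomes",
    "subsample_without_replacement",
    "nhanes_like_spec",
]

TRUTH_FAMILIES = ("constant", "uniform", "beta", "two_point", "logistic_model")

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


class ConvergenceError(RuntimeError):
    """The numeric intercept solve failed to reach the target prevalence."""


def _validate_params(family: str, params: Mapping) -> dict:
    p = dict(params)
    if family == "constant":
        c = float(p.get("value", 0.5))
        if not 0.0 <= c <= 1.0:
            raise ValidationError("constant value must lie in [0, 1]")
        return {"value": c}
    if family == "uniform":
        a, b = float(p.get("low", 0.0)), float(p.get("high", 1.0))
        if not (0.0 <= a < b <= 1.0):
            raise ValidationError("uniform bounds must satisfy 0 ≤ low < high ≤ 1")
        return {"low": a, "high": b}
    if family == "beta":
        alpha, beta = float(p.get("alpha", 1.0)), float(p.get("beta", 1.0))
        if alpha <= 0 or beta <= 0:
            raise ValidationError("beta shapes must be positive")
        return {"alpha": alpha, "beta": beta}
    if family == "two_point":
        v0, v1 = float(p.get("v0", 0.0)), float(p.get("v1", 1.0))
        w = float(p.get("weight", 0.5))
        if not (0.0 <= v0 <= 1.0 and 0.0 <= v1 <= 1.0 and 0.0 <= w <= 1.0):
            raise ValidationError("two_point values and weight must lie in [0, 1]")
        return {"v0": v0, "v1": v1, "weight": w}
    if family == "logistic_model":
        beta = np.asarray(p.get("beta", ()), dtype=float).ravel()
        k = int(p.get("k", beta.size))
        if k < 1 or beta.size != k or not np.all(np.isfinite(beta)):
            raise ValidationError(
                "logistic_model needs k ≥ 1 finite coefficients matching k"
            )
        intercept = float(p.get("intercept", 0.0))
        pool_size = p.get("pool_size")
        if pool_size is not None:
            pool_size = int(pool_size)
            if pool_size < 1:
                raise ValidationError("pool_size must be ≥ 1")
        return {
            "k": k,
            "beta": [float(b) for b in beta],
            "intercept": intercept,
            "covariates": p.get("covariates", "standard_normal"),
            "pool_size": pool_size,
        }
    raise ValidationError(f"unknown truth family {family!r}; choose from {TRUTH_FAMILIES}")


@dataclass(frozen=True)
class TruthDistributionSpec:
    """One truth distribution: family, family-specific params, sample size n."""

    family: str
    params: Mapping = field(default_factory=dict)
    n: int = 1000

    def __post_init__(self):
        object.__setattr__(self, "params", _validate_params(self.family, self.params))
        if int(self.n) < 1:
            raise ValidationError("n must be ≥ 1")
        object.__setattr__(self, "n", int(self.n))

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self.params.items() if v is not None)
        return f"{self.family}({inner})"

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params), "n": self.n}

    @classmethod
    def from_dict(cls, data: Mapping) -> "TruthDistributionSpec":
        return cls(
            family=data["family"],
            params=data.get("params", {}),
            n=int(data.get("n", 1000)),
        )


def sample_true_probabilities(
    spec: TruthDistributionSpec,
    seed: SeedLike = None,
    n: Optional[int] = None,
) -> TruthModel:
    """Draw a vector of true probabilities q according to ``spec``.

    ``n`` overrides ``spec.n`` when given (scenario specs carry their own
    sample size).  For ``logistic_model`` with a ``pool_size`` larger than
    n, a covariate pool of that size is generated first and n probabilities
    are subsampled without replacement, mirroring how risks fitted on a
    survey cohort are carried into a smaller evaluation sample.
    """
    rng = np.random.default_rng(seed)
    size = int(n) if n is not None else spec.n
    if size < 1:
        raise ValidationError("n must be ≥ 1")
    params = spec.params
    fam = spec.family
    if fam == "constant":
        q = np.full(size, params["value"])
    elif fam == "uniform":
        q = rng.uniform(params["low"], params["high"], size)
    elif fam == "beta":
        q = rng.beta(params["alpha"], params["beta"], size)
    elif fam == "two_point":
        pick = rng.random(size) < params["weight"]
        q = np.where(pick, params["v1"], params["v0"])
    else:  # logistic_model
        beta = np.asarray(params["beta"], dtype=float)
        pool_size = params["pool_size"] or size
        if pool_size < size:
            raise ValidationError("pool_size must be ≥ the requested sample size")
        x = rng.standard_normal((pool_size, beta.size))
        q_pool = expit(params["intercept"] + x @ beta)
        q = (
            subsample_without_replacement(q_pool, size, rng)
            if pool_size > size
            else q_pool
        )
    return TruthModel(q=np.clip(q, 0.0, 1.0), source=spec.describe())


def sample_outcomes(q, seed: SeedLike = None) -> np.ndarray:
    """Independent Bernoulli outcomes Y_i ~ Bern(q_i), returned as 0/1 ints."""
    qarr = q.q if isinstance(q, TruthModel) else np.asarray(q, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    return (rng.random(qarr.size) < qarr).astype(np.int64)


def subsample_without_replacement(q, n: int, seed: SeedLike = None) -> np.ndarray:
    """Uniform without-replacement subsample of n values from the pool ``q``."""
    qarr = q.q if isinstance(q, TruthModel) else np.asarray(q, dtype=float).ravel()
    if not 1 <= n <= qarr.size:
        raise ValidationError("subsample size must be in [1, len(pool)]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(qarr.size, size=n, replace=False)
    return qarr[idx]


def _mean_expit_normal(intercept: float, sigma: float) -> float:
    """E[expit(intercept + sigma·Z)] for Z ~ N(0, 1), by adaptive quadrature."""
    if sigma == 0.0:
        return float(expit(intercept))
    val, _ = quad(
        lambda z: expit(intercept + sigma * z) * norm.pdf(z), -12.0, 12.0, limit=200
    )
    return float(val)


def nhanes_like_spec(
    prevalence_target: float,
    k: int = 3,
    seed: SeedLike = None,
    *,
    beta: Optional[np.ndarray] = None,
    n: int = 1000,
    pool_size: Optional[int] = None,
) -> TruthDistributionSpec:
    """Build a logistic-model truth spec hitting a target mean risk.

    Covariates are i.i.d. standard normal, so the linear predictor is
    N(β0, ‖β‖²); the intercept β0 is solved numerically (quadrature +
    Brent root find — a deterministic computation, so ``seed`` is accepted
    for interface symmetry but not consumed) such that E[q] matches
    ``prevalence_target`` to well within 0.01.

    ``beta`` defaults to 0.5 for each of the k covariates, giving
    moderately dispersed individual risks around the target prevalence.
    """
    if not 0.0 < prevalence_target < 1.0:
        raise ValidationError("prevalence_target must lie strictly in (0, 1)")
    if k < 1:
        raise ValidationError("k must be ≥ 1")
    coef = (
        np.full(k, 0.5) if beta is None else np.asarray(beta, dtype=float).ravel()
    )
    if coef.size != k:
        raise ValidationError("beta must have length k")
    sigma = float(np.linalg.norm(coef))
    if sigma == 0.0:
        intercept = float(logit(prevalence_target))
    else:
        f = lambda b0: _mean_expit_normal(b0, sigma) - prevalence_target
        try:
            intercept = float(brentq(f, -40.0, 40.0, xtol=1e-10))
        except ValueError as exc:  # pragma: no cover - unreachable for expit
            raise ConvergenceError(
                f"could not solve intercept for prevalence {prevalence_target}"
            ) from exc
    achieved = _mean_expit_normal(intercept, sigma)
    if abs(achieved - prevalence_target) > 0.01:
        raise ConvergenceError(
            f"intercept solve off target: achieved {achieved:.4f} "
            f"vs requested {prevalence_target:.4f}"
        )
    return TruthDistributionSpec(
        family="logistic_model",
        params={
            "k": k,
            "beta": coef,
            "intercept": intercept,
            "pool_size": pool_size,
        },
        n=n,
    )
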