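"""Rules mapping true probabilities q to predictions p.

Three miscalibration families plus the identity:

* ``additive_bias`` — p_i = q_i + ε (systematic over/under-prediction);
* ``uniform_noise`` — p_i = q_i + U_i with U_i ~ Unif(−m, m) i.i.d.;
* ``logit_noise``  — p_i = expit(logit(q_i) + δ_i), δ_i ~ Normal(0, m),
  a symmetric error on the log-odds scale (q_i ∈ {0, 1} are fixed points,
  the logit being undefined there).

Perturbed values can leave [0, 1]; the ``clip_policy`` decides whether they
are clamped (``clip_to_unit``, the default) or abort the replicate
(``reject``).  Every stochastic rule consumes an explicitly passed seed or
generator — no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
from scipy.special import expit, logit

from .metrics import TruthModel, ValidationError, _as_probabilities

__all__ = [
    "PERTURBATION_KINDS",
    "CLIP_POLICIES",
    "PerturbationSpec",
    "RejectedReplicateError",
    "apply_perturbation",
]

PERTURBATION_KINDS = ("identity", "additive_bias", "uniform_noise", "logit_noise")
CLIP_POLICIES = ("clip_to_unit", "reject")

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


class RejectedReplicateError(ValidationError):
    """A perturbed prediction left [0, 1] under the ``reject`` clip policy."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Specification of one perturbation rule.

    ``magnitude`` is the bias ε, the half-width m of the uniform noise, or
    the standard deviation of the logit-scale error, depending on ``kind``.
    """

    kind: str
    magnitude: float = 0.0
    clip_policy: str = "clip_to_unit"

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValidationError(
                f"unknown perturbation kind {self.kind!r}; choose from {PERTURBATION_KINDS}"
            )
        if self.clip_policy not in CLIP_POLICIES:
            raise ValidationError(
                f"unknown clip policy {self.clip_policy!r}; choose from {CLIP_POLICIES}"
            )
        if not np.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValidationError("magnitude must be a finite number ≥ 0")
        if self.kind == "identity" and self.magnitude != 0.0:
            raise ValidationError("identity perturbation requires magnitude 0")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "magnitude": self.magnitude,
            "clip_policy": self.clip_policy,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PerturbationSpec":
        return cls(
            kind=data["kind"],
            magnitude=float(data.get("magnitude", 0.0)),
            clip_policy=data.get("clip_policy", "clip_to_unit"),
        )


def apply_perturbation(
    q,
    spec: PerturbationSpec,
    seed: SeedLike = None,
) -> np.ndarray:
    """Map true probabilities to predictions under ``spec``.

    Parameters
    ----------
    q
        A :class:`~brierlab.metrics.TruthModel` or probability vector.
    spec
        The perturbation rule.
    seed
        Seed, SeedSequence or Generator for the stochastic kinds; ignored
        by deterministic kinds.

    Returns
    -------
    numpy.ndarray
        Predictions of the same length, guaranteed in [0, 1] (under the
        ``reject`` policy an out-of-range value raises
        :class:`RejectedReplicateError` instead of being clamped).
    """
    qarr = q.q if isinstance(q, TruthModel) else _as_probabilities(q, "q")
    m = float(spec.magnitude)

    if spec.kind == "identity" or m == 0.0:
        return qarr.copy()

    rng = np.random.default_rng(seed)
    if spec.kind == "additive_bias":
        raw = qarr + m
    elif spec.kind == "uniform_noise":
        raw = qarr + rng.uniform(-m, m, size=qarr.size)
    else:  # logit_noise: boundary probabilities are fixed points
        raw = qarr.copy()
        interior = (qarr > 0.0) & (qarr < 1.0)
        delta = rng.normal(0.0, m, size=int(interior.sum()))
        raw[interior] = expit(logit(qarr[interior]) + delta)

    if spec.clip_policy == "reject":
        if raw.min() < 0.0 or raw.max() > 1.0:
            raise RejectedReplicateError(
                "perturbed prediction left [0, 1] under the reject policy"
            )
        return raw
    return np.clip(raw, 0.0, 1.0)
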