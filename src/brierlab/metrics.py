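"""Closed-form Brier-score metrics for binary risk predictions.

The Brier score of predicted probabilities ``p`` against binary outcomes
``y`` is the mean squared difference ``BS = (1/n) Σ (p_i − y_i)²``.  When the
outcomes arise as independent Bernoulli draws ``Y_i ~ Bern(q_i)`` with true
event probabilities ``q_i``, the score's expectation decomposes as

    E[BS] = (1/n) Σ [ (p_i − q_i)² + q_i (1 − q_i) ]

— a squared-distance term measuring how far the predictions sit from the
truth, plus an irreducible Bernoulli-variance floor that even perfect
predictions (``p = q``) cannot remove.  Everything in this module is an
exact, deterministic function of its inputs; Monte-Carlo behaviour lives in
:mod:`brierlab.simulation`.

Companion quantities implemented here:

* ``prevalence_reference`` — ``ȳ − ȳ²``, the Brier score (and expected
  Brier score) of the constant prediction equal to the observed incidence;
  the standard non-informative baseline.
* ``truth_reference`` — ``q̄ − q̄²``, the analogous quantity for the true
  risks; by Jensen's inequality it upper-bounds the perfect-prediction
  expectation ``(1/n) Σ q_i(1−q_i)``.
* ``calibration_in_the_large`` — ``mean(p) − mean(y)``, the aggregate
  miscalibration the Brier score alone cannot reveal.
* ``scaled_brier`` — ``1 − BS / (ȳ(1−ȳ))``, the prevalence-scaled score
  (0 = no better than the baseline, 1 = perfect extreme fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "UndefinedReferenceError",
    "MetricValue",
    "PredictionSet",
    "TruthModel",
    "brier_score",
    "expected_brier",
    "perfect_expected_brier",
    "prevalence_reference",
    "truth_reference",
    "calibration_in_the_large",
    "expected_cil",
    "scaled_brier",
    "l2_distance",
    "read_prediction_set",
    "write_metric_values",
]


class ValidationError(ValueError):
    """Raised when inputs violate the domain invariants (range, length)."""


class UndefinedReferenceError(ValidationError):
    """Raised when a prevalence-based reference is undefined (ȳ ∈ {0, 1})."""


def _as_probabilities(x, name: str = "p") -> np.ndarray:
    """Coerce to a 1-d float array of probabilities in [0, 1]."""
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} must contain at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError(f"{name} values must lie in [0, 1]")
    return arr


def _as_binary(y, name: str = "y") -> np.ndarray:
    arr = np.asarray(y, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} must contain at least one value")
    if not np.all((arr == 0.0) | (arr == 1.0)):
        raise ValidationError(f"{name} values must all be 0 or 1")
    return arr


def _truth_array(q) -> np.ndarray:
    if isinstance(q, TruthModel):
        return q.q
    return _as_probabilities(q, "q")


@dataclass(frozen=True)
class MetricValue:
    """A named scalar metric together with the sample size it was computed on."""

    name: str
    value: float
    n: int

    def __float__(self) -> float:  # convenience for arithmetic in callers
        return float(self.value)


@dataclass(frozen=True)
class PredictionSet:
    """Paired predicted probabilities ``p`` and binary outcomes ``y``.

    Both vectors must have equal length ``n ≥ 1``; ``p`` lies in [0, 1] and
    ``y`` in {0, 1}.  Validation happens on construction.
    """

    p: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        p = _as_probabilities(self.p, "p")
        y = _as_binary(self.y, "y")
        if p.shape != y.shape:
            raise ValidationError(
                f"p and y must have equal length (got {p.size} and {y.size})"
            )
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.p.size)


@dataclass(frozen=True)
class TruthModel:
    """True event probabilities ``q`` plus a descriptor of their origin."""

    q: np.ndarray
    source: str = "unspecified"

    def __post_init__(self):
        object.__setattr__(self, "q", _as_probabilities(self.q, "q"))

    def __len__(self) -> int:
        return int(self.q.size)


# ---------------------------------------------------------------------------
# Observed metrics (functions of (p, y))
# ---------------------------------------------------------------------------


def brier_score(ps: PredictionSet) -> MetricValue:
    """Observed Brier score ``(1/n) Σ (p_i − y_i)²``; lies in [0, 1]."""
    value = float(np.mean((ps.p - ps.y) ** 2))
    return MetricValue("brier", value, len(ps))


def calibration_in_the_large(ps: PredictionSet) -> MetricValue:
    """Calibration-in-the-large, ``mean(p) − mean(y)``.

    Positive values mean the model over-predicts risk on average.  This is
    the difference form; no logistic-intercept recalibration is involved.
    """
    value = float(np.mean(ps.p) - np.mean(ps.y))
    return MetricValue("cil", value, len(ps))


def prevalence_reference(y) -> MetricValue:
    """``ȳ − ȳ²`` — the Brier score of the constant prediction ``p_i = ȳ``.

    Accepts a raw binary vector or a :class:`PredictionSet` (whose outcomes
    are then used).
    """
    arr = y.y if isinstance(y, PredictionSet) else _as_binary(y)
    ybar = float(np.mean(arr))
    return MetricValue("prevalence_reference", ybar - ybar**2, int(arr.size))


def scaled_brier(ps: PredictionSet) -> MetricValue:
    """Scaled Brier score ``1 − BS / (ȳ(1−ȳ))``.

    Positive values mean better than the prevalence baseline; 1 is a perfect
    extreme fit.  Undefined when ``ȳ ∈ {0, 1}`` (zero baseline variance) —
    raises :class:`UndefinedReferenceError` rather than returning infinity.
    """
    ref = prevalence_reference(ps.y)
    if ref.value == 0.0:
        raise UndefinedReferenceError(
            "scaled Brier score is undefined when the observed incidence is 0 or 1"
        )
    bs = brier_score(ps)
    return MetricValue("scaled_brier", 1.0 - bs.value / ref.value, len(ps))


# ---------------------------------------------------------------------------
# Expectations under Y_i ~ Bern(q_i)
# ---------------------------------------------------------------------------


def expected_brier(p, q) -> MetricValue:
    """Expected Brier score ``(1/n) Σ [(p_i − q_i)² + q_i(1 − q_i)]``.

    ``q`` may be a :class:`TruthModel` or a plain probability vector.
    """
    parr = _as_probabilities(p, "p")
    qarr = _truth_array(q)
    if parr.shape != qarr.shape:
        raise ValidationError(
            f"p and q must have equal length (got {parr.size} and {qarr.size})"
        )
    value = float(np.mean((parr - qarr) ** 2 + qarr * (1.0 - qarr)))
    return MetricValue("expected_brier", value, int(parr.size))


def perfect_expected_brier(q) -> MetricValue:
    """Expected Brier score of the perfect prediction ``p = q``.

    Equals ``(1/n) Σ q_i(1 − q_i)`` — the irreducible Bernoulli-noise floor.
    """
    qarr = _truth_array(q)
    value = float(np.mean(qarr * (1.0 - qarr)))
    return MetricValue("perfect_expected_brier", value, int(qarr.size))


def truth_reference(q) -> MetricValue:
    """``q̄ − q̄²`` for the true mean incidence ``q̄``.

    Upper-bounds :func:`perfect_expected_brier` (Jensen), with equality iff
    all ``q_i`` are equal.  This is the theoretical bar annotated alongside
    simulated Brier-score distributions.
    """
    qarr = _truth_array(q)
    qbar = float(np.mean(qarr))
    return MetricValue("truth_reference", qbar - qbar**2, int(qarr.size))


def expected_cil(p, q) -> MetricValue:
    """Expectation of calibration-in-the-large: ``mean(p) − mean(q)``."""
    parr = _as_probabilities(p, "p")
    qarr = _truth_array(q)
    if parr.shape != qarr.shape:
        raise ValidationError(
            f"p and q must have equal length (got {parr.size} and {qarr.size})"
        )
    value = float(np.mean(parr) - np.mean(qarr))
    return MetricValue("expected_cil", value, int(parr.size))


def l2_distance(p, q) -> float:
    """Euclidean distance ``‖p − q‖₂`` between two probability vectors.

    The expected Brier score preserves the ordering this distance induces:
    E[BS] = perfect floor + l2²/n.
    """
    parr = _as_probabilities(p, "p")
    qarr = _as_probabilities(q, "q")
    if parr.shape != qarr.shape:
        raise ValidationError(
            f"p and q must have equal length (got {parr.size} and {qarr.size})"
        )
    return float(np.sqrt(np.sum((parr - qarr) ** 2)))


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def read_prediction_set(path: Union[str, Path]) -> PredictionSet:
    """Read a CSV with header columns ``p`` and ``y`` into a PredictionSet.

    Malformed (non-numeric or out-of-range) rows raise a
    :class:`ValidationError` naming the offending line of the file.
    """
    frame = pd.read_csv(path)
    for col in ("p", "y"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    numeric = frame[["p", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | ~np.isfinite(numeric).all(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValidationError(f"{path}: malformed row at line {line}")
    p = numeric["p"].to_numpy()
    y = numeric["y"].to_numpy()
    out_of_range = (p < 0) | (p > 1) | ~np.isin(y, (0.0, 1.0))
    if out_of_range.any():
        line = int(np.flatnonzero(out_of_range)[0]) + 2
        raise ValidationError(
            f"{path}: value out of range at line {line} (p must be in [0,1], y in {{0,1}})"
        )
    return PredictionSet(p=p, y=y)


def write_metric_values(metrics: Iterable[MetricValue], path: Union[str, Path]) -> None:
    """Write metrics as CSV rows with columns ``metric,value,n``."""
    rows = [{"metric": m.name, "value": m.value, "n": m.n} for m in metrics]
    pd.DataFrame(rows, columns=["metric", "value", "n"]).to_csv(path, index=False)
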