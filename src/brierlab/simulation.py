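"""Monte-Carlo engine for Brier-score simulation scenarios.

One *scenario* fixes a truth distribution, a perturbation rule, a sample
size n, a replicate count and a master seed.  Each replicate draws true
risks q, Bernoulli outcomes y and predictions p, and records:

``brier``                observed Brier score of the perturbed predictions
``brier_perfect``        Brier score of the perfect prediction p = q on the
                         same outcomes
``cil``                  calibration-in-the-large of the perturbed predictions
``prevalence_reference`` ȳ − ȳ²
``gap``                  ȳ − ȳ² − brier_perfect (how far the naive baseline
                         sits above the perfect model's realised score)
``exceed``               the event ȳ − ȳ² > brier (strict)
``brier_exceeds_reference``  the reverse event brier > ȳ − ȳ² (strict) —
                         the score overshooting its naive upper "bound"
``expected_brier``       the analytic expectation given the drawn (p, q)
``truth_reference``      q̄ − q̄² for the drawn q

Reproducibility: the master seed spawns one child ``SeedSequence`` per
replicate (plus one reserved for a fixed truth draw), so replicates are
independent streams and any execution order yields the sequential result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .metrics import (
    MetricValue,
    PredictionSet,
    TruthModel,
    ValidationError,
    brier_score,
    calibration_in_the_large,
    expected_brier,
    perfect_expected_brier,
    prevalence_reference,
    truth_reference,
)
from .perturbations import PerturbationSpec, RejectedReplicateError, apply_perturbation
from .synthetic_truth import (
    TruthDistributionSpec,
    sample_outcomes,
    sample_true_probabilities,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioSummary",
    "run_scenario",
    "summarize_scenario",
    "epsilon_sweep",
    "compare_models",
    "REPLICATE_COLUMNS",
]

REPLICATE_COLUMNS = (
    "replicate",
    "brier",
    "brier_perfect",
    "cil",
    "prevalence_reference",
    "gap",
    "exceed",
    "brier_exceeds_reference",
    "expected_brier",
    "truth_reference",
)

SUMMARY_METRICS = ("brier", "brier_perfect", "cil", "prevalence_reference", "gap")

# Strict-inequality events are decided with this absolute margin so that
# quantities equal in exact arithmetic (e.g. ȳ−ȳ² vs BS for constant truth
# with ȳ = q) are never misclassified by float round-off; genuine
# differences are O(1/n²) or larger, far above it.
TIE_TOLERANCE = 1e-12


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell: truth × perturbation × n × replicates × seed.

    ``redraw_truth`` selects the truth-sampling policy: True draws a fresh
    q each replicate (fully i.i.d. pipeline, the default); False draws one
    q vector up front and reuses it across replicates, matching designs
    where risks are fixed model outputs subsampled once.
    """

    label: str
    truth: TruthDistributionSpec
    perturbation: PerturbationSpec
    n: int = 1000
    replicates: int = 5000
    master_seed: int = 0
    redraw_truth: bool = True

    def __post_init__(self):
        if int(self.replicates) < 1:
            raise ValidationError("replicates must be ≥ 1")
        if int(self.n) < 1:
            raise ValidationError("n must be ≥ 1")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "replicates", int(self.replicates))
        object.__setattr__(self, "master_seed", int(self.master_seed))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "truth": self.truth.to_dict(),
            "perturbation": self.perturbation.to_dict(),
            "n": self.n,
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "redraw_truth": self.redraw_truth,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioSpec":
        return cls(
            label=data["label"],
            truth=TruthDistributionSpec.from_dict(data["truth"]),
            perturbation=PerturbationSpec.from_dict(data["perturbation"]),
            n=int(data.get("n", 1000)),
            replicates=int(data.get("replicates", 5000)),
            master_seed=int(data.get("master_seed", 0)),
            redraw_truth=bool(data.get("redraw_truth", True)),
        )


def run_scenario(spec: ScenarioSpec) -> pd.DataFrame:
    """Execute every replicate of a scenario; deterministic given the spec.

    Returns the replicate table (one row per Monte-Carlo replicate) with
    the columns listed in :data:`REPLICATE_COLUMNS`.
    """
    children = np.random.SeedSequence(spec.master_seed).spawn(spec.replicates + 1)
    fixed_q: Optional[TruthModel] = None
    if not spec.redraw_truth:
        fixed_q = sample_true_probabilities(spec.truth, children[0], n=spec.n)

    rows = np.empty((spec.replicates, len(REPLICATE_COLUMNS)))
    for r in range(spec.replicates):
        rng = np.random.default_rng(children[r + 1])
        q = (
            fixed_q
            if fixed_q is not None
            else sample_true_probabilities(spec.truth, rng, n=spec.n)
        )
        try:
            p = apply_perturbation(q, spec.perturbation, rng)
        except RejectedReplicateError as exc:
            raise RejectedReplicateError(
                f"scenario {spec.label!r}, replicate {r}: {exc}"
            ) from exc
        y = sample_outcomes(q, rng)

        ps = PredictionSet(p=p, y=y)
        bs = brier_score(ps).value
        bs_perf = brier_score(PredictionSet(p=q.q, y=y)).value
        ref = prevalence_reference(y).value
        rows[r] = (
            r,
            bs,
            bs_perf,
            calibration_in_the_large(ps).value,
            ref,
            ref - bs_perf,
            ref - bs > TIE_TOLERANCE,
            bs - ref > TIE_TOLERANCE,
            expected_brier(p, q).value,
            truth_reference(q).value,
        )

    table = pd.DataFrame(rows, columns=list(REPLICATE_COLUMNS))
    table["replicate"] = table["replicate"].astype(np.int64)
    table["exceed"] = table["exceed"].astype(bool)
    table["brier_exceeds_reference"] = table["brier_exceeds_reference"].astype(bool)
    return table


@dataclass(frozen=True)
class ScenarioSummary:
    """Percentile summaries plus exceedance probabilities for one scenario.

    ``metrics`` maps each metric name to its median / 5% / 95% percentile /
    mean / sd across replicates (linear-interpolation sample quantiles).
    ``exceedance_probability`` is the fraction of replicates with
    ȳ − ȳ² > BS, with a percentile-bootstrap 95% CI (resampling replicates);
    ``brier_exceeds_reference_probability`` is the reverse event, the
    probability that the realised score overshoots the naive reference.
    ``truth_reference`` is the mean of q̄ − q̄² across replicates — the
    theoretical bar drawn next to simulated distributions.
    """

    label: str
    metrics: Mapping[str, Mapping[str, float]]
    exceedance_probability: float
    exceedance_ci: tuple
    brier_exceeds_reference_probability: float
    brier_exceeds_reference_ci: tuple
    truth_reference: float
    mean_expected_brier: float
    n: int
    replicates: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "metrics": {k: dict(v) for k, v in self.metrics.items()},
            "exceedance_probability": self.exceedance_probability,
            "exceedance_ci": list(self.exceedance_ci),
            "brier_exceeds_reference_probability": self.brier_exceeds_reference_probability,
            "brier_exceeds_reference_ci": list(self.brier_exceeds_reference_ci),
            "truth_reference": self.truth_reference,
            "mean_expected_brier": self.mean_expected_brier,
            "n": self.n,
            "replicates": self.replicates,
        }

    def to_frame(self) -> pd.DataFrame:
        """Flatten the per-metric summaries to a tidy frame for CSV export."""
        rows = [
            {"metric": name, **{k: float(v) for k, v in stats.items()}}
            for name, stats in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def _bootstrap_proportion_ci(
    flags: np.ndarray, bootstrap_reps: int, rng: np.random.Generator
) -> tuple:
    """Percentile-bootstrap 95% CI for a proportion, resampling replicates."""
    m = flags.size
    draws = rng.integers(0, m, size=(bootstrap_reps, m))
    props = flags[draws].mean(axis=1)
    lo, hi = np.quantile(props, (0.025, 0.975))
    return (float(lo), float(hi))


def summarize_scenario(
    table: pd.DataFrame,
    label: str = "scenario",
    n: Optional[int] = None,
    bootstrap_reps: int = 1000,
    seed: Union[None, int, np.random.SeedSequence, np.random.Generator] = 0,
) -> ScenarioSummary:
    """Summarise a replicate table: medians, 5%/95% percentiles, exceedance.

    Quantiles use numpy's linear-interpolation convention.  The bootstrap
    resamples whole replicates with replacement.
    """
    if len(table) == 0:
        raise ValidationError("replicate table is empty")
    if bootstrap_reps < 1:
        raise ValidationError("bootstrap_reps must be ≥ 1")
    rng = np.random.default_rng(seed)

    metrics = {}
    for name in SUMMARY_METRICS:
        col = table[name].to_numpy(dtype=float)
        p5, med, p95 = np.quantile(col, (0.05, 0.5, 0.95))
        metrics[name] = {
            "median": float(med),
            "p5": float(p5),
            "p95": float(p95),
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if col.size > 1 else 0.0,
        }

    exceed = table["exceed"].to_numpy(dtype=float)
    reverse = table["brier_exceeds_reference"].to_numpy(dtype=float)
    return ScenarioSummary(
        label=label,
        metrics=metrics,
        exceedance_probability=float(exceed.mean()),
        exceedance_ci=_bootstrap_proportion_ci(exceed, bootstrap_reps, rng),
        brier_exceeds_reference_probability=float(reverse.mean()),
        brier_exceeds_reference_ci=_bootstrap_proportion_ci(
            reverse, bootstrap_reps, rng
        ),
        truth_reference=float(table["truth_reference"].mean()),
        mean_expected_brier=float(table["expected_brier"].mean()),
        n=int(n) if n is not None else -1,
        replicates=len(table),
    )


def epsilon_sweep(
    q,
    epsilons: Sequence[float],
    signs: Union[str, Sequence[int]] = "positive",
) -> pd.DataFrame:
    """Expected-Brier increase from perturbing predictions ε away from q.

    For each ε the prediction is q + s·ε with the chosen sign pattern
    (``"positive"``, ``"negative"``, ``"alternating"`` or an explicit ±1
    vector); the recorded increase over the perfect expectation equals ε²
    exactly, whatever the signs.  An ε that pushes any component outside
    [0, 1] raises — the sweep never clips silently.
    """
    qarr = q.q if isinstance(q, TruthModel) else np.asarray(q, dtype=float).ravel()
    if isinstance(signs, str):
        if signs == "positive":
            s = np.ones(qarr.size)
        elif signs == "negative":
            s = -np.ones(qarr.size)
        elif signs == "alternating":
            s = np.where(np.arange(qarr.size) % 2 == 0, 1.0, -1.0)
        else:
            raise ValidationError(f"unknown sign policy {signs!r}")
    else:
        s = np.asarray(signs, dtype=float).ravel()
        if s.shape != qarr.shape or not np.all(np.abs(s) == 1.0):
            raise ValidationError("signs must be a ±1 vector matching q")

    floor = perfect_expected_brier(qarr).value
    records = []
    for eps in epsilons:
        eps = float(eps)
        if eps < 0:
            raise ValidationError("epsilons must be ≥ 0")
        p = qarr + s * eps
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValidationError(
                f"epsilon {eps} pushes predictions outside [0, 1]; no silent clipping"
            )
        records.append(
            {"epsilon": eps, "expected_increase": expected_brier(p, qarr).value - floor}
        )
    return pd.DataFrame.from_records(records, columns=["epsilon", "expected_increase"])


def compare_models(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Paired per-replicate Brier comparison of two scenarios.

    Both tables must come from scenarios sharing truth spec and n (same
    replicate count); the engine cannot verify the sharing, only the pairing.
    Reports the fraction of replicates each model wins (strictly lower
    Brier score), quantifying how often chance inverts the expected order.
    """
    if len(table_a) != len(table_b):
        raise ValidationError(
            f"replicate counts differ ({len(table_a)} vs {len(table_b)})"
        )
    diff = table_a["brier"].to_numpy() - table_b["brier"].to_numpy()
    m = diff.size
    return {
        "replicates": int(m),
        "mean_diff": float(diff.mean()),
        "sd_diff": float(diff.std(ddof=1)) if m > 1 else 0.0,
        "a_wins": float(np.mean(diff < 0)),
        "b_wins": float(np.mean(diff > 0)),
        "ties": float(np.mean(diff == 0)),
    }
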