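"""Configuration-driven pipeline: the full misconception suite end-to-end.

``run_suite`` executes a list of scenarios (grouped into the five
misconception demonstrations plus two analytic worked examples), writes
per-scenario replicate and summary CSVs, and emits one structured JSON
report.  ``evaluate_predictions`` applies the recommended reporting
defaults — Brier score against a prevalence baseline, scaled Brier, CIL,
and a percentile-bootstrap 95% CI — to a user-supplied (p, y) CSV.

Configs are human-editable YAML (JSON parses identically, YAML being a
superset) mirroring the scenario dataclasses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .metrics import (
    PredictionSet,
    UndefinedReferenceError,
    ValidationError,
    brier_score,
    calibration_in_the_large,
    expected_brier,
    expected_cil,
    l2_distance,
    perfect_expected_brier,
    prevalence_reference,
    read_prediction_set,
    scaled_brier,
)
from .perturbations import PerturbationSpec
from .simulation import ScenarioSpec, epsilon_sweep, run_scenario, summarize_scenario
from .synthetic_truth import TruthDistributionSpec, nhanes_like_spec

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "default_config",
    "run_suite",
    "evaluate_predictions",
    "analytic_examples",
    "analytic_checks",
]

logger = logging.getLogger("brierlab")

SMOKE_REPLICATES = 200


@dataclass
class RunConfig:
    """The whole suite: scenarios, output directory, bootstrap and seed."""

    scenarios: List[ScenarioSpec] = field(default_factory=list)
    out_dir: Path = Path("results")
    bootstrap_reps: int = 1000
    master_seed: int = 0
    groups: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        labels = [s.label for s in self.scenarios]
        if len(labels) != len(set(labels)):
            raise ValidationError("scenario labels must be unique")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "bootstrap_reps": self.bootstrap_reps,
            "master_seed": self.master_seed,
            "groups": {k: list(v) for k, v in self.groups.items()},
            "scenarios": [s.to_dict() for s in self.scenarios],
        }


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse a YAML (or JSON) suite configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    scenarios = [ScenarioSpec.from_dict(s) for s in data.get("scenarios", [])]
    return RunConfig(
        scenarios=scenarios,
        out_dir=Path(data.get("out_dir", "results")),
        bootstrap_reps=int(data.get("bootstrap_reps", 1000)),
        master_seed=int(data.get("master_seed", 0)),
        groups=data.get("groups", {}),
    )


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Default scenario grid — the shipped misconception suite
# ---------------------------------------------------------------------------


def _truth(family: str, n: int, **params) -> TruthDistributionSpec:
    return TruthDistributionSpec(family=family, params=params, n=n)


def default_config(
    master_seed: int = 0,
    replicates: int = 5000,
    out_dir: Union[str, Path] = "results",
    bootstrap_reps: int = 1000,
) -> RunConfig:
    """The shipped suite covering all five misconception demonstrations.

    Truth distributions span constant 1/2, Unif(0,1), Beta(1,3), the
    degenerate 0/1 two-point mixture, and a logistic-model emulation of a
    survey-fitted risk model at 20% prevalence; perturbations cover perfect
    predictions, additive bias 0.1 and Unif(−0.1, 0.1) noise.  Sample sizes
    follow the study design: n = 1000 for the distribution panels, n = 300
    for the small-sample randomness panels.
    """
    identity = PerturbationSpec("identity")
    noise = PerturbationSpec("uniform_noise", 0.1)
    bias = PerturbationSpec("additive_bias", 0.1)
    nhanes_1000 = nhanes_like_spec(0.2, k=3, n=1000)
    nhanes_300 = nhanes_like_spec(0.2, k=3, n=300)

    # Seeds: deterministic offsets from the master seed, one per scenario.
    seed_iter = iter(range(10_000))

    def sc(label, truth, pert, n, **kw):
        return ScenarioSpec(
            label=label,
            truth=truth,
            perturbation=pert,
            n=n,
            replicates=replicates,
            master_seed=(master_seed * 10_000 + next(seed_iter)) % (2**31 - 1),
            **kw,
        )

    scenarios = [
        # #1: perfect predictions are not score-zero predictions (n=1000)
        sc("m1_uniform_perfect", _truth("uniform", 1000, low=0.0, high=1.0), identity, 1000),
        sc("m1_uniform_noise", _truth("uniform", 1000, low=0.0, high=1.0), noise, 1000),
        sc("m1_beta_perfect", _truth("beta", 1000, alpha=1.0, beta=3.0), identity, 1000),
        sc("m1_beta_noise", _truth("beta", 1000, alpha=1.0, beta=3.0), noise, 1000),
        sc("m1_logistic_perfect", nhanes_1000, identity, 1000),
        sc("m1_logistic_noise", nhanes_1000, noise, 1000),
        # #2: cross-dataset comparisons mislead
        sc("m2_constant_half_perfect", _truth("constant", 1000, value=0.5), identity, 1000),
        sc("m2_two_point_perfect", _truth("two_point", 1000, v0=0.0, v1=1.0, weight=0.5), identity, 1000),
        sc("m2_beta_noise", _truth("beta", 1000, alpha=1.0, beta=3.0), noise, 1000),
        # #3: Brier score is not calibration (n=300, CIL contrast)
        sc("m3_uniform_perfect", _truth("uniform", 300, low=0.0, high=1.0), identity, 300),
        sc("m3_uniform_bias", _truth("uniform", 300, low=0.0, high=1.0), bias, 300),
        sc("m3_uniform_noise", _truth("uniform", 300, low=0.0, high=1.0), noise, 300),
        # #4/#5: small-sample randomness around the prevalence reference
        sc("m4_uniform_perfect", _truth("uniform", 300, low=0.0, high=1.0), identity, 300),
        sc("m4_beta_perfect", _truth("beta", 300, alpha=1.0, beta=3.0), identity, 300),
        sc("m4_constant_half_perfect", _truth("constant", 300, value=0.5), identity, 300),
        sc("m4_logistic_perfect", nhanes_300, identity, 300),
    ]
    groups = {
        "misconception1": [s.label for s in scenarios if s.label.startswith("m1_")],
        "misconception2": [s.label for s in scenarios if s.label.startswith("m2_")],
        "misconception3": [s.label for s in scenarios if s.label.startswith("m3_")],
        "misconception4": [s.label for s in scenarios if s.label.startswith("m4_")],
        # #5 reuses the #4 perfect-prediction scenarios via their exceedance columns
        "misconception5": [s.label for s in scenarios if s.label.startswith("m4_")],
        "example1": ["analytic"],
        "worked_example_m2": ["analytic"],
    }
    return RunConfig(
        scenarios=scenarios,
        out_dir=Path(out_dir),
        bootstrap_reps=bootstrap_reps,
        master_seed=master_seed,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Analytic worked examples and self-checks
# ---------------------------------------------------------------------------


def analytic_examples() -> dict:
    """The two closed-form demonstrations, recomputed from the formulas.

    * ``worked_example_m2`` — one observation with true risk 0.1; the model
      predicting 0 has lower expected Brier score (0.1) than the model
      predicting 0.25 (0.1125), although a human would usually prefer the
      latter.
    * ``example1`` — two settings with n = 2: perfectly calibrated
      predictions (expected CIL 0) versus systematically overestimating
      ones whose expected CIL is ≈ 0.2224745 despite a comparable expected
      Brier score.  Both expected Brier values are computed through the
      decomposition, never transcribed.
    """
    q_m2 = [0.1]
    setting_a_q = [0.3, 0.7]
    setting_b_q = [0.2, 0.8]
    setting_b_p = [0.444949, 1.0]
    return {
        "worked_example_m2": {
            "true_probability": 0.1,
            "model1_prediction": 0.0,
            "model2_prediction": 0.25,
            "model1_expected_brier": expected_brier([0.0], q_m2).value,
            "model2_expected_brier": expected_brier([0.25], q_m2).value,
        },
        "example1": {
            "setting_a": {
                "q": setting_a_q,
                "p": setting_a_q,
                "expected_brier": expected_brier(setting_a_q, setting_a_q).value,
                "expected_cil": expected_cil(setting_a_q, setting_a_q).value,
            },
            "setting_b": {
                "q": setting_b_q,
                "p": setting_b_p,
                "expected_brier": expected_brier(setting_b_p, setting_b_q).value,
                "expected_cil": expected_cil(setting_b_p, setting_b_q).value,
            },
        },
    }


def analytic_checks(atol: float = 1e-12) -> List[dict]:
    """Closed-form identities of the metrics layer, evaluated at run time.

    Each entry carries the computed values and a pass flag at ``atol``, so
    a suite report is auditable without rerunning anything.
    """
    rng = np.random.default_rng(12345)
    q = rng.uniform(0.05, 0.95, 25)
    p = np.clip(q + rng.normal(0, 0.05, 25), 0, 1)
    checks = []

    lhs = expected_brier(p, q).value
    rhs = perfect_expected_brier(q).value + l2_distance(p, q) ** 2 / q.size
    checks.append(
        {"name": "decomposition_identity", "lhs": lhs, "rhs": rhs, "pass": abs(lhs - rhs) <= atol}
    )

    sweep = epsilon_sweep(q, [0.05], signs="alternating")
    inc = float(sweep["expected_increase"].iloc[0])
    checks.append(
        {"name": "epsilon_squared_increase", "lhs": inc, "rhs": 0.05**2, "pass": abs(inc - 0.05**2) <= atol}
    )

    perfect = perfect_expected_brier(q).value
    from .metrics import truth_reference as _truth_ref

    bar = _truth_ref(q).value
    checks.append(
        {"name": "jensen_bound", "lhs": perfect, "rhs": bar, "pass": perfect <= bar + atol}
    )

    const_half = perfect_expected_brier([0.5] * 8).value
    checks.append(
        {"name": "constant_half_floor", "lhs": const_half, "rhs": 0.25, "pass": abs(const_half - 0.25) <= atol}
    )
    return checks


# ---------------------------------------------------------------------------
# Suite execution
# ---------------------------------------------------------------------------


def run_suite(config: RunConfig) -> dict:
    """Run every scenario, write CSVs and the JSON suite report.

    Per scenario: ``<label>_replicates.csv`` and ``<label>_summary.csv``.
    The report pairs each empirical summary with its analytic expectation
    (mean of per-replicate expected Brier) so the consistency gap is
    auditable.  Scenario failures are logged and collected; the report's
    ``failures`` list is empty on full success.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "master_seed": config.master_seed,
        "bootstrap_reps": config.bootstrap_reps,
        "groups": {k: list(v) for k, v in config.groups.items()},
        "scenarios": {},
        "analytic_examples": analytic_examples(),
        "analytic_checks": analytic_checks(),
        "failures": [],
    }
    for spec in config.scenarios:
        logger.info(
            "scenario %s: truth=%s perturbation=%s n=%d replicates=%d master_seed=%d",
            spec.label,
            spec.truth.describe(),
            spec.perturbation.kind,
            spec.n,
            spec.replicates,
            spec.master_seed,
        )
        try:
            table = run_scenario(spec)
            summary = summarize_scenario(
                table,
                label=spec.label,
                n=spec.n,
                bootstrap_reps=config.bootstrap_reps,
                seed=spec.master_seed + 1,
            )
        except Exception as exc:  # noqa: BLE001 — suite must report, not die
            logger.error("scenario %s failed: %s", spec.label, exc)
            report["failures"].append({"label": spec.label, "error": str(exc)})
            continue
        table.to_csv(out / f"{spec.label}_replicates.csv", index=False)
        summary.to_frame().to_csv(out / f"{spec.label}_summary.csv", index=False)
        entry = summary.to_dict()
        entry["spec"] = spec.to_dict()
        report["scenarios"][spec.label] = entry

    with open(out / "suite_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


# ---------------------------------------------------------------------------
# Single-dataset evaluation (the recommended reporting defaults)
# ---------------------------------------------------------------------------


def evaluate_predictions(
    source: Union[str, Path, PredictionSet],
    bootstrap_reps: int = 1000,
    seed: Union[None, int] = 0,
) -> dict:
    """Evaluate one (p, y) dataset with baseline and uncertainty included.

    Reports the Brier score, the prevalence reference ȳ − ȳ², the scaled
    Brier score (marked unavailable when ȳ ∈ {0, 1}), CIL, and a
    percentile-bootstrap 95% CI for the Brier score obtained by resampling
    (p_i, y_i) pairs.
    """
    if bootstrap_reps < 1:
        raise ValidationError("bootstrap_reps must be ≥ 1")
    ps = source if isinstance(source, PredictionSet) else read_prediction_set(source)
    result = {
        "n": len(ps),
        "brier": brier_score(ps).value,
        "prevalence_reference": prevalence_reference(ps.y).value,
        "cil": calibration_in_the_large(ps).value,
    }
    try:
        result["scaled_brier"] = scaled_brier(ps).value
    except UndefinedReferenceError:
        result["scaled_brier"] = None
        result["scaled_brier_note"] = (
            "unavailable: observed incidence is 0 or 1, so the prevalence "
            "reference score is zero"
        )

    rng = np.random.default_rng(seed)
    m = len(ps)
    idx = rng.integers(0, m, size=(bootstrap_reps, m))
    boot = ((ps.p[idx] - ps.y[idx]) ** 2).mean(axis=1)
    lo, hi = np.quantile(boot, (0.025, 0.975))
    result["brier_ci95"] = [float(lo), float(hi)]
    result["bootstrap_reps"] = int(bootstrap_reps)
    return result
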