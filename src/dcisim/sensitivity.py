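"""Univariate and probabilistic sensitivity analysis.

Parameters are addressed by dotted paths.  Scalars are set directly
(``regression.value``, ``clinical.value``, ``screening.participation``,
``screening.sensitivity``); table-valued inputs (onset, progression,
mortality) vary through a single table-wide multiplier with base value 1.0
(``onset.scale``, ``progression.scale``, ``mortality.scale``), preserving
the age/grade shape of the table.

The univariate analysis (USA) re-runs the scenario at each interval bound
with common random numbers — the same master seed as the base run — so two
runs differ only through the varied parameter.  The probabilistic analysis
(PSA) samples all parameters jointly and uniformly within their intervals
(the sampler is pluggable) and simulates each of the ``n_scenarios``
resulting scenarios.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .engine import CohortResult, Fate, simulate_cohort
from .parameters import (
    LifeTable,
    ParameterInterval,
    ScenarioConfig,
    ValidationError,
)

__all__ = [
    "apply_parameter",
    "base_value",
    "univariate",
    "probabilistic",
    "fate_long_format",
]


def _scale_life_table(table: LifeTable, factor: float) -> LifeTable:
    v = np.clip(table.values * factor, 0.0, 1.0)
    v[-1] = 1.0  # the terminal age remains certain death
    return LifeTable(v)


def apply_parameter(
    config: ScenarioConfig, path: str, value: float
) -> ScenarioConfig:
    """Return a copy of ``config`` with one parameter set/scaled."""
    if path == "onset.scale":
        return config.replace(
            onset=type(config.onset)(
                bands=config.onset.bands,
                values=config.onset.values * value,
                max_age=config.onset.max_age,
            )
        )
    if path == "progression.scale":
        return config.replace(
            progression=type(config.progression)(
                bands=config.progression.bands,
                values=config.progression.values * value,
                max_age=config.progression.max_age,
            )
        )
    if path == "mortality.scale":
        return config.replace(life_table=_scale_life_table(config.life_table, value))
    if path == "regression.value":
        return config.replace(
            regression=type(config.regression)(np.full(3, float(value)))
        )
    if path == "clinical.value":
        return config.replace(clinical=type(config.clinical)(float(value)))
    if path in ("screening.participation", "screening.sensitivity"):
        if config.screening is None:
            raise ValidationError(f"{path}: scenario has no screening policy")
        field = path.split(".", 1)[1]
        return config.replace(
            screening=type(config.screening)(
                **{
                    **{
                        "start_age": config.screening.start_age,
                        "end_age": config.screening.end_age,
                        "interval": config.screening.interval,
                        "participation": config.screening.participation,
                        "sensitivity": config.screening.sensitivity,
                    },
                    field: float(value),
                }
            )
        )
    raise ValidationError(f"unknown parameter path {path!r}")


def base_value(config: ScenarioConfig, path: str) -> float:
    """Base value of a parameter path (1.0 for table-wide multipliers)."""
    if path.endswith(".scale"):
        return 1.0
    if path == "regression.value":
        return float(config.regression.values[0])
    if path == "clinical.value":
        return float(config.clinical.value)
    if path == "screening.participation":
        return float(config.screening.participation)
    if path == "screening.sensitivity":
        return float(config.screening.sensitivity)
    raise ValidationError(f"unknown parameter path {path!r}")


def _default_outcomes(results: Sequence[CohortResult]) -> dict[str, float]:
    screens = sum(r.mammograms for r in results)
    screen_det = sum(int(r.detections_by_age_grade.sum()) for r in results)
    clin_det = sum(r.fate_counts()["clin_detected"] for r in results)
    out = {
        "screen_detection_rate": screen_det / screens * 1000 if screens else np.nan,
        "all_detection_rate": (screen_det + clin_det) / screens * 1000
        if screens
        else np.nan,
    }
    return out


def univariate(
    base: ScenarioConfig,
    intervals: Sequence[ParameterInterval],
    outcome: Callable[[Sequence[CohortResult]], dict[str, float]] | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity: tornado-ordered outcome deltas.

    Each parameter is set to its lower and upper bound in turn, all else at
    base, and the scenario re-simulated with the base master seed (common
    random numbers).  Rows are ordered by the largest absolute change in
    screen-detection rate (the tornado order).
    """
    outcome = outcome or _default_outcomes
    base_out = outcome(simulate_cohort(base))
    rows = []
    for iv in intervals:
        b = base_value(base, iv.parameter_path)
        if not (iv.low <= b <= iv.high):
            raise ValidationError(
                f"interval for {iv.parameter_path} [{iv.low}, {iv.high}] "
                f"does not bracket the base value {b}"
            )
        lo_out = outcome(simulate_cohort(apply_parameter(base, iv.parameter_path, iv.low)))
        hi_out = outcome(simulate_cohort(apply_parameter(base, iv.parameter_path, iv.high)))
        row = {"parameter": iv.parameter_path, "low": iv.low, "high": iv.high}
        for key in base_out:
            row[f"{key}_base"] = base_out[key]
            row[f"{key}_low"] = lo_out[key]
            row[f"{key}_high"] = hi_out[key]
            row[f"{key}_delta_low"] = lo_out[key] - base_out[key]
            row[f"{key}_delta_high"] = hi_out[key] - base_out[key]
        rows.append(row)
    df = pd.DataFrame(rows)
    span = (
        df[["screen_detection_rate_delta_low", "screen_detection_rate_delta_high"]]
        .abs()
        .max(axis=1)
    )
    return df.assign(max_abs_delta=span).sort_values(
        "max_abs_delta", ascending=False, ignore_index=True
    )


def probabilistic(
    base: ScenarioConfig,
    intervals: Sequence[ParameterInterval],
    n_scenarios: int = 100,
    seed: int | None = None,
    sampler: Callable[[np.random.Generator, ParameterInterval], float] | None = None,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis over ``n_scenarios`` random scenarios.

    Each scenario draws every parameter independently within its interval
    (uniformly, unless a custom ``sampler(rng, interval)`` is given), then
    simulates the full scenario with a deterministically spawned child seed.
    Returns one row per scenario with the sampled values, the total
    screen-detection rate, episode-fate fractions, and the screen-detected
    grade distribution.  ``(seed, intervals)`` fully determine the design.
    """
    master = base.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 9001]))
    draw = sampler or (lambda r, iv: float(r.uniform(iv.low, iv.high)))
    child_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_scenarios)]

    rows = []
    for k in range(n_scenarios):
        cfg = base
        sampled: dict[str, float] = {}
        for iv in intervals:
            v = draw(rng, iv)
            sampled[iv.parameter_path] = v
            cfg = apply_parameter(cfg, iv.parameter_path, v)
        cfg = cfg.replace(seed=child_seeds[k])
        results = simulate_cohort(cfg)
        row: dict = {"scenario": k, "seed": cfg.seed, **sampled}
        row.update(_default_outcomes(results))
        fates = metrics.fate_distribution(results)
        for name, frac in zip(fates["fate"], fates["fraction"]):
            row[f"fate_{name}"] = frac
        try:
            grades = metrics.grade_distribution(results)
        except ValueError:
            grades = {1: np.nan, 2: np.nan, 3: np.nan}
        for g, frac in grades.items():
            row[f"grade_{g}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


def fate_long_format(psa: pd.DataFrame) -> pd.DataFrame:
    """Box-plot-ready long table (scenario, fate, fraction) from a PSA run."""
    fate_cols = [c for c in psa.columns if c.startswith("fate_")]
    long = psa.melt(
        id_vars=["scenario"],
        value_vars=fate_cols,
        var_name="fate",
        value_name="fraction",
    )
    long["fate"] = long["fate"].str.removeprefix("fate_")
    return long
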