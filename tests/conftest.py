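"""Shared fixtures: shipped scenarios and programmatic toy configurations."""

from __future__ import annotations

import numpy as np
import pytest

from dcisim.parameters import (
    AgeBand,
    ClinicalDetectionModel,
    LifeTable,
    OnsetTable,
    ProgressionTable,
    RegressionModel,
    ScenarioConfig,
    ScreeningPolicy,
    fixture_path,
    load_scenario,
)

MAX_AGE = 100


class UncappedOnset(OnsetTable):
    """Onset table without the plausibility cap, for forced-path tests."""

    _max_value = 1.0


def flat_life_table(p: float = 0.0, max_age: int = MAX_AGE) -> LifeTable:
    v = np.full(max_age + 1, p, dtype=float)
    v[-1] = 1.0
    return LifeTable(v)


def onset_table(
    rows: dict[tuple[int, int], tuple[float, float, float]],
    max_age: int = MAX_AGE,
    cls=OnsetTable,
) -> OnsetTable:
    """Build an onset table from {(lo, hi): (g1, g2, g3)} plain probabilities;
    uncovered ages are zero-filled."""
    bands, values = [], []
    covered = sorted(rows)
    cursor = 0
    for lo, hi in covered:
        if lo > cursor:
            bands.append(AgeBand(cursor, lo - 1))
            values.append((0.0, 0.0, 0.0))
        bands.append(AgeBand(lo, hi))
        values.append(rows[(lo, hi)])
        cursor = hi + 1
    if cursor <= max_age:
        bands.append(AgeBand(cursor, max_age))
        values.append((0.0, 0.0, 0.0))
    return cls(bands=tuple(bands), values=np.array(values), max_age=max_age)


def flat_progression(p: float, max_age: int = MAX_AGE) -> ProgressionTable:
    bands = (AgeBand(0, 19), AgeBand(20, max_age))
    values = np.array([[0.0, 0.0, 0.0], [p, p, p]])
    return ProgressionTable(bands=bands, values=values, max_age=max_age)


def make_config(
    *,
    onset: OnsetTable | None = None,
    death: LifeTable | None = None,
    regression: float = 0.0,
    progression: float = 0.0,
    clinical: float = 0.0,
    screening: ScreeningPolicy | None = None,
    cohort_size: int = 1000,
    iterations: int = 1,
    seed: int = 7,
    label: str = "toy",
) -> ScenarioConfig:
    return ScenarioConfig(
        label=label,
        cohort_size=cohort_size,
        iterations=iterations,
        seed=seed,
        max_age=MAX_AGE,
        life_table=death if death is not None else flat_life_table(),
        onset=onset if onset is not None else onset_table({}),
        regression=RegressionModel(np.full(3, regression)),
        progression=flat_progression(progression),
        clinical=ClinicalDetectionModel(clinical),
        screening=screening,
    )


@pytest.fixture(scope="session")
def nl_config():
    """Dutch base scenario exactly as shipped (10 x 100,000, seed 1)."""
    return load_scenario(fixture_path("nl_base.yaml"))


@pytest.fixture(scope="session")
def nl_small(nl_config):
    """Dutch base scenario at reduced scale for module-level checks."""
    return nl_config.replace(cohort_size=20000, iterations=3)


@pytest.fixture(scope="session")
def constant_hazard_config():
    """No death before the horizon, no screening, constant competing hazards
    P3=0.05, P4=0.15, P6=0.05: closed-form fate fractions are available."""
    return make_config(
        onset=onset_table({(20, 94): (0.002, 0.003, 0.005)}),
        regression=0.05,
        progression=0.15,
        clinical=0.05,
        cohort_size=20000,
        iterations=2,
        seed=11,
    )
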