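"""Shared yearly transition kernel.

Both the stochastic engine and the deterministic expectation oracle iterate
the same ordered update, once per model year at integer age ``a``:

1. **Screening** — if ``a`` is a scheduled round and the woman is still in
   the model, she attends with probability ``participation`` (independent
   per round); an attended examination is counted as a mammogram, and a
   present DCIS is detected with probability ``sensitivity`` (absorbing).
2. **Death** — all-cause death with probability P1(a), identical in the
   healthy and DCIS states (absorbing; an open DCIS episode ends as
   died-of-other-cause).
3. **Disease transition** —
   healthy: DCIS of grade g arises with probability P2(a, g), the three
   grades mutually exclusive within the year;
   DCIS(g): one competing-risk draw among regression P3(g), progression to
   IBC P4(a, g), clinical detection P6, and remaining, using the yearly
   probabilities as printed (no rate conversion).

Screening precedes the year's transitions so that a lesion present at the
round cannot be pre-empted by a same-year transition; a lesion arising in
step 3 is first detectable at the next round.  The per-age probabilities are
precomputed here into dense arrays; every consumer reads the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ScenarioConfig, ScreeningPolicy

__all__ = ["AgeProbabilityGrid", "build_grid", "schedule_screens", "FATES", "EXITS"]

# Episode fates, in reporting order.
FATES = (
    "regressed",
    "progressed_ibc",
    "screen_detected",
    "clin_detected",
    "died_other",
    "censored",
)

# Whole-woman exit states.
EXITS = ("died_other", "ibc", "screen_detected", "clin_detected")


def schedule_screens(policy: ScreeningPolicy) -> list[int]:
    """Ordered screening ages: start, start+interval, ..., <= end."""
    return policy.schedule()


@dataclass(frozen=True)
class AgeProbabilityGrid:
    """Dense per-age annual probabilities driving the yearly update.

    Shapes: ``death`` is (max_age+1,); ``onset`` and ``progression`` are
    (max_age+1, 3) over grades; ``regression`` is (3,); ``clinical`` is a
    scalar.  ``screen_ages`` is a boolean mask over ages.
    """

    max_age: int
    death: np.ndarray
    onset: np.ndarray
    regression: np.ndarray
    progression: np.ndarray
    clinical: float
    screen_ages: np.ndarray  # bool mask, all False when no screening policy
    participation: float
    sensitivity: float


def build_grid(config: ScenarioConfig) -> AgeProbabilityGrid:
    """Resolve a scenario's tables into the dense per-age grid."""
    mask = np.zeros(config.max_age + 1, dtype=bool)
    participation = sensitivity = 0.0
    if config.screening is not None:
        mask[schedule_screens(config.screening)] = True
        participation = config.screening.participation
        sensitivity = config.screening.sensitivity
    return AgeProbabilityGrid(
        max_age=config.max_age,
        death=config.life_table.values,
        onset=config.onset.per_age(),
        regression=config.regression.values,
        progression=config.progression.per_age(),
        clinical=config.clinical.value,
        screen_ages=mask,
        participation=participation,
        sensitivity=sensitivity,
    )
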