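"""Deterministic expectation oracle.

Propagates the exact probability mass of a single woman over
age x state x grade under the same ordered yearly update as the stochastic
engine (see :mod:`dcisim.kernel`).  Because every update is linear in the
state masses, the result equals the engine's expectation at infinite cohort
size: it serves as an analytic oracle for the Monte Carlo engine and as a
fast noise-free estimator of detection rates and episode-fate fractions.

No variance information is produced here; intervals come from engine
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ExitState, Fate
from .kernel import build_grid
from .parameters import ScenarioConfig, ScreeningPolicy

__all__ = [
    "StateDistribution",
    "propagate",
    "expected_detection_rates",
    "expected_fate_distribution",
    "expected_grade_distribution",
]

MASS_TOL = 1e-12


@dataclass(frozen=True)
class StateDistribution:
    """Exact per-age state masses and accumulated event masses.

    ``healthy`` and ``dcis`` hold the mass at the *start* of each age-year,
    before that year's events.  ``onset``, ``screens`` and ``detections``
    are per-age event masses; ``fates`` accumulates episode-fate mass per
    (fate, grade); ``exits`` the absorbed whole-woman mass per exit state.
    """

    healthy: np.ndarray  # (max_age+1,)
    dcis: np.ndarray  # (max_age+1, 3)
    onset: np.ndarray  # (max_age+1, 3)
    screens: np.ndarray  # (max_age+1,) expected examinations
    detections: np.ndarray  # (max_age+1, 3) expected screen-detections
    fates: np.ndarray  # (len(Fate), 3)
    exits: np.ndarray  # (len(ExitState),)

    @property
    def total_onset_mass(self) -> float:
        """Expected number of DCIS episodes per woman."""
        return float(self.onset.sum())

    def trajectory(self) -> pd.DataFrame:
        """Age-indexed table of the full state-mass trajectory."""
        return pd.DataFrame(
            {
                "age": np.arange(self.healthy.size),
                "healthy": self.healthy,
                "dcis_g1": self.dcis[:, 0],
                "dcis_g2": self.dcis[:, 1],
                "dcis_g3": self.dcis[:, 2],
                "expected_screens": self.screens,
                "expected_detections": self.detections.sum(axis=1),
            }
        )


def propagate(config: ScenarioConfig) -> StateDistribution:
    """Propagate the exact state distribution from birth to ``max_age``.

    Raises ``RuntimeError`` if mass conservation is violated beyond 1e-12
    at any age (an internal-consistency failure, not a data error).
    """
    grid = build_grid(config)
    A = grid.max_age

    h = 1.0
    d = np.zeros(3)
    exits = np.zeros(len(ExitState))
    fates = np.zeros((len(Fate), 3))

    healthy = np.zeros(A + 1)
    dcis = np.zeros((A + 1, 3))
    onset = np.zeros((A + 1, 3))
    screens = np.zeros(A + 1)
    detections = np.zeros((A + 1, 3))

    for age in range(A + 1):
        healthy[age] = h
        dcis[age] = d

        # 1. screening round
        if grid.screen_ages[age]:
            screens[age] = (h + d.sum()) * grid.participation
            det = d * grid.participation * grid.sensitivity
            detections[age] = det
            d = d - det
            fates[Fate.SCREEN_DETECTED] += det
            exits[ExitState.SCREEN_DETECTED] += det.sum()

        # 2. death
        p1 = grid.death[age]
        dd = d * p1
        exits[ExitState.DEAD_OTHER] += h * p1 + dd.sum()
        fates[Fate.DIED_OTHER] += dd
        h -= h * p1
        d = d - dd

        # 3. disease transition (competing risks on pre-onset DCIS mass)
        new = h * grid.onset[age]
        onset[age] = new
        reg = d * grid.regression
        prog = d * grid.progression[age]
        clin = d * grid.clinical
        fates[Fate.REGRESSED] += reg
        fates[Fate.PROGRESSED_IBC] += prog
        fates[Fate.CLIN_DETECTED] += clin
        exits[ExitState.IBC] += prog.sum()
        exits[ExitState.CLIN_DETECTED] += clin.sum()
        h = h - new.sum() + reg.sum()
        d = d - reg - prog - clin + new

        total = h + d.sum() + exits.sum()
        if abs(total - 1.0) > MASS_TOL:
            raise RuntimeError(
                f"mass leak at age {age}: total probability {total!r}"
            )

    # P1(max_age) = 1 drives the remaining mass to zero; fold any residual
    # (possible only with a nonstandard life table) into censoring/death.
    if d.sum() > 0 or h > 0:
        fates[Fate.CENSORED] += d
        exits[ExitState.DEAD_OTHER] += h + d.sum()
        h, d = 0.0, np.zeros(3)

    return StateDistribution(
        healthy=healthy,
        dcis=dcis,
        onset=onset,
        screens=screens,
        detections=detections,
        fates=fates,
        exits=exits,
    )


def _age_groups(policy: ScreeningPolicy) -> list[tuple[int, int]]:
    """Five-year reporting bins spanning the screening schedule."""
    lo = 5 * (policy.start_age // 5)
    hi = 5 * (policy.end_age // 5) + 4
    return [(a, a + 4) for a in range(lo, hi + 1, 5)]


def expected_detection_rates(
    dist: StateDistribution, policy: ScreeningPolicy
) -> pd.DataFrame:
    """Expected screen-detection rates per 1,000 examinations.

    One row per stratum (5-year age group by age at the round, lesion grade,
    and total); strata with zero expected screens are omitted.
    """
    rows = []
    total_screens = dist.screens.sum()
    if total_screens == 0:
        return pd.DataFrame(columns=["stratum", "rate"])
    for lo, hi in _age_groups(policy):
        s = dist.screens[lo : hi + 1].sum()
        if s == 0:
            continue
        rows.append((f"age_{lo}-{hi}", dist.detections[lo : hi + 1].sum() / s * 1000))
    for g in (1, 2, 3):
        rows.append((f"grade_{g}", dist.detections[:, g - 1].sum() / total_screens * 1000))
    rows.append(("total", dist.detections.sum() / total_screens * 1000))
    return pd.DataFrame(rows, columns=["stratum", "rate"])


def expected_fate_distribution(dist: StateDistribution) -> dict[str, float]:
    """Fraction of expected DCIS episodes ending in each fate (sums to 1)."""
    total = dist.total_onset_mass
    if total == 0:
        raise ValueError("no DCIS onset mass: fate distribution undefined")
    return {f.name.lower(): float(dist.fates[f].sum() / total) for f in Fate}


def expected_grade_distribution(dist: StateDistribution) -> dict[int, float]:
    """Grade fractions among expected screen-detected episodes."""
    det = dist.fates[Fate.SCREEN_DETECTED]
    total = det.sum()
    if total == 0:
        raise ValueError("no screen-detected mass: grade distribution undefined")
    return {g: float(det[g - 1] / total) for g in (1, 2, 3)}
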