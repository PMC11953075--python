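"""Stochastic micro-simulation engine.

Simulates individual life histories from birth to exit under the ordered
yearly update defined in :mod:`dcisim.kernel`, vectorized over all women of
a cohort (one numpy pass per model year).  The scalar ``simulate_year`` and
per-woman ``simulate_woman`` entry points run the same vectorized step with
a single woman, so every code path shares one transition definition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .kernel import EXITS, FATES, AgeProbabilityGrid, build_grid, schedule_screens
from .parameters import ScenarioConfig

__all__ = [
    "Fate",
    "ExitState",
    "EpisodeRecord",
    "LifeHistory",
    "CohortResult",
    "simulate_year",
    "simulate_woman",
    "simulate_cohort",
    "schedule_screens",
]

HEALTHY = 0  # state codes: 0 healthy, 1..3 DCIS of that grade


class Fate(enum.IntEnum):
    """Terminal resolution of one DCIS episode."""

    REGRESSED = 0
    PROGRESSED_IBC = 1
    SCREEN_DETECTED = 2
    CLIN_DETECTED = 3
    DIED_OTHER = 4
    CENSORED = 5


class ExitState(enum.IntEnum):
    """Absorbing state through which a woman leaves the model."""

    DEAD_OTHER = 0
    IBC = 1
    SCREEN_DETECTED = 2
    CLIN_DETECTED = 3


assert tuple(f.name.lower() for f in Fate) == FATES
assert len(ExitState) == len(EXITS)


@dataclass(frozen=True)
class EpisodeRecord:
    """One DCIS episode: onset, grade, and eventual fate."""

    onset_age: int
    grade: int
    fate: Fate
    fate_age: int


@dataclass(frozen=True)
class LifeHistory:
    """Per-woman outcome: exit, DCIS episodes, screens attended."""

    exit_age: int
    exit_state: ExitState
    episodes: tuple[EpisodeRecord, ...]
    screens_attended: tuple[int, ...]


@dataclass
class CohortResult:
    """Sufficient aggregates of one simulated cohort.

    Episodes are stored as parallel arrays (onset_age, grade, fate,
    fate_age); every DCIS onset contributes exactly one row, closed with
    exactly one fate.  ``mammograms_by_age`` counts examinations performed
    (attended rounds of in-model women); ``detections_by_age_grade`` counts
    screen-detected DCIS by age at the round and lesion grade.
    """

    iteration: int
    seed: int
    cohort_size: int
    mammograms_by_age: np.ndarray  # (max_age+1,) int64
    detections_by_age_grade: np.ndarray  # (max_age+1, 3) int64
    exits_by_age_state: np.ndarray  # (max_age+1, 4) int64
    episode_onset_age: np.ndarray
    episode_grade: np.ndarray
    episode_fate: np.ndarray
    episode_fate_age: np.ndarray

    @property
    def mammograms(self) -> int:
        return int(self.mammograms_by_age.sum())

    @property
    def n_episodes(self) -> int:
        return int(self.episode_grade.size)

    def exit_counts(self) -> dict[str, int]:
        totals = self.exits_by_age_state.sum(axis=0)
        return {name: int(totals[i]) for i, name in enumerate(EXITS)}

    def fate_counts(self) -> dict[str, int]:
        counts = np.bincount(self.episode_fate, minlength=len(Fate))
        return {f.name.lower(): int(counts[f]) for f in Fate}


class _Cohort:
    """Mutable cohort state plus aggregate accumulators for one run."""

    def __init__(self, grid: AgeProbabilityGrid, n: int, trace: bool = False):
        self.grid = grid
        self.n = n
        self.trace = trace
        self.state = np.zeros(n, dtype=np.int8)
        self.onset_age_cur = np.full(n, -1, dtype=np.int16)
        self.active = np.ones(n, dtype=bool)
        A = grid.max_age
        self.mammograms_by_age = np.zeros(A + 1, dtype=np.int64)
        self.detections_by_age_grade = np.zeros((A + 1, 3), dtype=np.int64)
        self.exits_by_age_state = np.zeros((A + 1, len(EXITS)), dtype=np.int64)
        self.ep_onset: list[np.ndarray] = []
        self.ep_grade: list[np.ndarray] = []
        self.ep_fate: list[np.ndarray] = []
        self.ep_fate_age: list[np.ndarray] = []
        self.screens_attended: list[int] = []
        self.exit_info: dict = {}
        self.events: list[str] = []  # per-step event log, scalar use only

    def _close(self, idx: np.ndarray, fate: Fate, age: int) -> None:
        """Close the open episodes of women ``idx`` with the given fate."""
        if idx.size == 0:
            return
        self.ep_onset.append(self.onset_age_cur[idx].astype(np.int16))
        self.ep_grade.append(self.state[idx].astype(np.int8))
        self.ep_fate.append(np.full(idx.size, int(fate), dtype=np.int8))
        self.ep_fate_age.append(np.full(idx.size, age, dtype=np.int16))
        if self.trace:
            self.events.append(fate.name.lower())

    def _absorb(self, idx: np.ndarray, exit_state: ExitState, age: int) -> None:
        if idx.size == 0:
            return
        self.exits_by_age_state[age, int(exit_state)] += idx.size
        self.active[idx] = False
        if self.trace and not self.exit_info:
            self.exit_info.update(exit_age=age, exit_state=exit_state)

    def step(self, age: int, rng: np.random.Generator) -> None:
        """Advance every in-model woman through one year at ``age``:
        screening round, then death, then disease transition."""
        grid = self.grid
        state = self.state

        if grid.screen_ages[age]:
            idx = np.flatnonzero(self.active)
            att = idx[rng.random(idx.size) < grid.participation]
            self.mammograms_by_age[age] += att.size
            if self.trace and att.size:
                self.screens_attended.append(age)
                self.events.append("mammogram")
            with_dcis = att[state[att] > 0]
            det = with_dcis[rng.random(with_dcis.size) < grid.sensitivity]
            if det.size:
                np.add.at(self.detections_by_age_grade[age], state[det] - 1, 1)
                self._close(det, Fate.SCREEN_DETECTED, age)
                self._absorb(det, ExitState.SCREEN_DETECTED, age)

        # all-cause death, identical probability in healthy and DCIS states
        idx = np.flatnonzero(self.active)
        die = idx[rng.random(idx.size) < grid.death[age]]
        if die.size:
            self._close(die[state[die] > 0], Fate.DIED_OTHER, age)
            self._absorb(die, ExitState.DEAD_OTHER, age)
            if self.trace:
                self.events.append("death")

        idx = np.flatnonzero(self.active)
        healthy = idx[state[idx] == 0]
        dcis = idx[state[idx] > 0]

        if healthy.size:
            cum = np.cumsum(grid.onset[age])
            k = np.searchsorted(cum, rng.random(healthy.size), side="right")
            new = healthy[k < 3]
            if new.size:
                state[new] = (k[k < 3] + 1).astype(np.int8)
                self.onset_age_cur[new] = age
                if self.trace:
                    self.events.append(f"onset_g{int(state[new[0]])}")

        if dcis.size:
            g = state[dcis] - 1
            p_reg = grid.regression[g]
            p_prog = grid.progression[age, g]
            u = rng.random(dcis.size)
            regress = u < p_reg
            progress = ~regress & (u < p_reg + p_prog)
            clin = ~regress & ~progress & (u < p_reg + p_prog + grid.clinical)

            r = dcis[regress]
            if r.size:
                self._close(r, Fate.REGRESSED, age)
                state[r] = 0
                self.onset_age_cur[r] = -1
            self._close(dcis[progress], Fate.PROGRESSED_IBC, age)
            self._absorb(dcis[progress], ExitState.IBC, age)
            self._close(dcis[clin], Fate.CLIN_DETECTED, age)
            self._absorb(dcis[clin], ExitState.CLIN_DETECTED, age)

    def finalize(self) -> None:
        """Close out any woman still in the model after the final year.

        With a valid life table (death certain at max_age) this is a no-op;
        it exists so nonstandard tables cannot leak episodes or women."""
        leftover = np.flatnonzero(self.active)
        if leftover.size:
            self._close(
                leftover[self.state[leftover] > 0], Fate.CENSORED, self.grid.max_age
            )
            self._absorb(leftover, ExitState.DEAD_OTHER, self.grid.max_age)

    def episode_arrays(self):
        def cat(chunks, dtype):
            return np.concatenate(chunks) if chunks else np.empty(0, dtype=dtype)

        return (
            cat(self.ep_onset, np.int16),
            cat(self.ep_grade, np.int8),
            cat(self.ep_fate, np.int8),
            cat(self.ep_fate_age, np.int16),
        )


def simulate_year(
    state: int,
    age: int,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[int | ExitState, list[str]]:
    """Advance one woman through a single model year.

    ``state`` is 0 (healthy) or the DCIS grade 1..3; absorbing states cannot
    be advanced.  Returns the new state — an int code, or an
    :class:`ExitState` if the woman left the model — and the list of events
    that occurred (``mammogram``, ``screen_detected``, ``death``,
    ``onset_g2``, ``regressed``, ``progressed_ibc``, ``clin_detected``).
    """
    if state not in (0, 1, 2, 3):
        raise ValueError(f"state {state!r} is not a live state (0 or grade 1..3)")
    sim = _Cohort(build_grid(config), 1, trace=True)
    sim.state[0] = state
    if state > 0:
        sim.onset_age_cur[0] = age  # onset age unknown for a bare state
    sim.step(age, rng)
    if sim.active[0]:
        return int(sim.state[0]), sim.events
    return sim.exit_info["exit_state"], sim.events


def _run(
    grid: AgeProbabilityGrid, n: int, rng: np.random.Generator, trace: bool = False
) -> _Cohort:
    sim = _Cohort(grid, n, trace=trace)
    for age in range(grid.max_age + 1):
        sim.step(age, rng)
    sim.finalize()
    return sim


def simulate_woman(
    config: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> LifeHistory:
    """Simulate one woman from birth to exit; returns her life history."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sim = _run(build_grid(config), 1, rng, trace=True)
    onset, grade, fate, fate_age = sim.episode_arrays()
    records = tuple(
        EpisodeRecord(int(o), int(g), Fate(int(f)), int(a))
        for o, g, f, a in zip(onset, grade, fate, fate_age)
    )
    return LifeHistory(
        exit_age=int(sim.exit_info["exit_age"]),
        exit_state=sim.exit_info["exit_state"],
        episodes=records,
        screens_attended=tuple(sim.screens_attended),
    )


def simulate_cohort(config: ScenarioConfig) -> list[CohortResult]:
    """Simulate ``config.iterations`` independent cohorts of
    ``config.cohort_size`` women.

    Iteration ``i`` uses a child seed deterministically derived from
    ``(config.seed, i)`` via :class:`numpy.random.SeedSequence` spawning, so
    identical ``(config, seed)`` give bit-identical results and iterations
    are independent streams.
    """
    grid = build_grid(config)
    children = np.random.SeedSequence(config.seed).spawn(config.iterations)
    results: list[CohortResult] = []
    for i, child in enumerate(children):
        sim = _run(grid, config.cohort_size, np.random.default_rng(child))
        e_on, e_g, e_f, e_fa = sim.episode_arrays()
        results.append(
            CohortResult(
                iteration=i,
                seed=config.seed,
                cohort_size=config.cohort_size,
                mammograms_by_age=sim.mammograms_by_age,
                detections_by_age_grade=sim.detections_by_age_grade,
                exits_by_age_state=sim.exits_by_age_state,
                episode_onset_age=e_on,
                episode_grade=e_g,
                episode_fate=e_f,
                episode_fate_age=e_fa,
            )
        )
    return results
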