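"""Reporting metrics: summary tables, stratified detection rates with
across-iteration intervals, episode-fate and grade distributions, and
comparison against observed registry rates.

Conventions follow registry reporting: detection rates are screen-detected
DCIS per 1,000 screening examinations, attributed to 5-year age groups by
age at the round (not age at onset); intervals are 2.5/97.5 percentile
bounds across iterations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import CohortResult, Fate
from .kernel import EXITS
from .parameters import fixture_path

__all__ = [
    "summarize",
    "detection_rates",
    "fate_distribution",
    "grade_distribution",
    "compare_to_observed",
    "load_observed",
    "age_groups_for",
]

OBSERVED_REFERENCES = {
    "nl2019": "observed_nl2019.csv",
    "nhs2021": "observed_nhs2021.csv",
}


def age_groups_for(start_age: int, end_age: int) -> list[tuple[int, int]]:
    """Five-year reporting bins spanning [start_age, end_age]."""
    lo = 5 * (start_age // 5)
    hi = 5 * (end_age // 5) + 4
    return [(a, a + 4) for a in range(lo, hi + 1, 5)]


def _screening_span(results: Sequence[CohortResult]) -> tuple[int, int]:
    screened = np.flatnonzero(sum(r.mammograms_by_age for r in results))
    if screened.size == 0:
        raise ValueError("no screening examinations in these results")
    return int(screened[0]), int(screened[-1])


def summarize(results: Sequence[CohortResult]) -> pd.DataFrame:
    """Per-iteration summary: onsets per grade, fate counts, exits, mammograms,
    and mean ages of the main events.  A final ``pooled`` row sums counts and
    pools the averages."""
    if not results:
        raise ValueError("no cohort results to summarize")
    rows = []
    for r in results:
        row: dict = {"iteration": r.iteration, "women": r.cohort_size}
        onsets = np.bincount(r.episode_grade, minlength=4)[1:]
        for g in (1, 2, 3):
            row[f"onsets_g{g}"] = int(onsets[g - 1])
        row.update(r.fate_counts())
        for name, count in r.exit_counts().items():
            row[f"exit_{name}"] = count
        row["mammograms"] = r.mammograms
        row["mean_onset_age"] = (
            float(r.episode_onset_age.mean()) if r.n_episodes else np.nan
        )
        ages = np.arange(r.exits_by_age_state.shape[0])
        for i, name in enumerate(EXITS):
            n = r.exits_by_age_state[:, i].sum()
            row[f"mean_age_{name}"] = (
                float((ages * r.exits_by_age_state[:, i]).sum() / n) if n else np.nan
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    pooled = df.drop(columns="iteration").sum(numeric_only=True)
    for col in df.columns:
        if col.startswith("mean_"):
            pooled[col] = df[col].mean()
    pooled["iteration"] = "pooled"
    return pd.concat([df, pooled.to_frame().T], ignore_index=True)


def _per_iteration_rates(
    results: Sequence[CohortResult], groups: list[tuple[int, int]]
) -> pd.DataFrame:
    """Stratum x iteration matrix of rates per 1,000 examinations."""
    strata = [f"age_{lo}-{hi}" for lo, hi in groups] + [
        "grade_1",
        "grade_2",
        "grade_3",
        "total",
    ]
    mat = np.full((len(strata), len(results)), np.nan)
    for j, r in enumerate(results):
        total_screens = r.mammograms
        for i, (lo, hi) in enumerate(groups):
            s = r.mammograms_by_age[lo : hi + 1].sum()
            if s > 0:
                mat[i, j] = r.detections_by_age_grade[lo : hi + 1].sum() / s * 1000
        if total_screens > 0:
            det = r.detections_by_age_grade.sum(axis=0)
            for g in (1, 2, 3):
                mat[len(groups) + g - 1, j] = det[g - 1] / total_screens * 1000
            mat[-1, j] = det.sum() / total_screens * 1000
    return pd.DataFrame(mat, index=strata)


def detection_rates(
    results: Sequence[CohortResult],
    groups: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Screen-detection rates per 1,000 examinations with percentile intervals.

    One row per stratum: mean across iterations and 2.5/97.5 percentile
    bounds.  Strata with zero screens in every iteration are dropped.
    """
    if groups is None:
        groups = age_groups_for(*_screening_span(results))
    per_iter = _per_iteration_rates(results, groups)
    per_iter = per_iter.dropna(how="all")
    out = pd.DataFrame(
        {
            "stratum": per_iter.index,
            "rate": per_iter.mean(axis=1),
            "lower": per_iter.quantile(0.025, axis=1),
            "upper": per_iter.quantile(0.975, axis=1),
        }
    ).reset_index(drop=True)
    return out


def fate_distribution(results: Sequence[CohortResult]) -> pd.DataFrame:
    """Episode-fate fractions: pooled over iterations, with across-iteration
    percentile bounds.  Fractions over all six fates sum to 1."""
    total = sum(r.n_episodes for r in results)
    if total == 0:
        raise ValueError("no DCIS episodes: fate distribution undefined")
    counts = sum(
        np.bincount(r.episode_fate, minlength=len(Fate)) for r in results
    )
    per_iter = np.array(
        [
            np.bincount(r.episode_fate, minlength=len(Fate)) / max(r.n_episodes, 1)
            for r in results
        ]
    ).T
    return pd.DataFrame(
        {
            "fate": [f.name.lower() for f in Fate],
            "fraction": counts / total,
            "lower": np.quantile(per_iter, 0.025, axis=1),
            "upper": np.quantile(per_iter, 0.975, axis=1),
        }
    )


def grade_distribution(
    results: Sequence[CohortResult], among: Fate = Fate.SCREEN_DETECTED
) -> dict[int, float]:
    """Grade fractions among episodes with the given fate (default
    screen-detected); fractions sum to 1."""
    counts = np.zeros(3)
    for r in results:
        sel = r.episode_grade[r.episode_fate == int(among)]
        counts += np.bincount(sel - 1, minlength=3)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no episodes with fate {among.name}")
    return {g: float(counts[g - 1] / total) for g in (1, 2, 3)}


def load_observed(name_or_path: str | Path) -> pd.DataFrame:
    """Load an observed reference rate table (shipped name or CSV path)."""
    if str(name_or_path) in OBSERVED_REFERENCES:
        path = fixture_path(OBSERVED_REFERENCES[str(name_or_path)])
    else:
        path = Path(name_or_path)
    df = pd.read_csv(path, comment="#")
    if not {"stratum", "observed"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns ['stratum', 'observed']")
    return df


def compare_to_observed(
    simulated: pd.DataFrame, observed: pd.DataFrame
) -> pd.DataFrame:
    """Flag, per stratum, whether the observed rate lies inside the simulated
    across-iteration interval.

    Every observed stratum must be present in the simulated table; the
    simulated table may carry extra strata (they are ignored).
    """
    sim = simulated.set_index("stratum")
    missing = [s for s in observed["stratum"] if s not in sim.index]
    if missing:
        raise ValueError(f"observed strata absent from simulation: {missing}")
    rows = []
    for rec in observed.itertuples():
        s = sim.loc[rec.stratum]
        rows.append(
            {
                "stratum": rec.stratum,
                "simulated": s["rate"],
                "lower": s["lower"],
                "upper": s["upper"],
                "observed": rec.observed,
                "inside": bool(s["lower"] <= rec.observed <= s["upper"]),
            }
        )
    return pd.DataFrame(rows)
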