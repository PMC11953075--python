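"""Model input parameters: transition tables, screening policy, scenario config.

The natural-history model is driven by six annual probabilities:

* P1 — all-cause death, per integer age (a life table);
* P2 — DCIS onset, per age band and grade (grades 1..3);
* P3 — spontaneous regression of DCIS to healthy, per grade;
* P4 — progression of DCIS to invasive breast cancer (IBC), per age band
  and grade;
* P5 — mammographic sensitivity for DCIS (part of the screening policy);
* P6 — clinical (non-screen) detection of a present DCIS, age- and
  grade-independent.

All probabilities are stored internally as plain fractions per year.  Unit
conventions of the printed source tables (mortality x1e-2, onset x1e-3) are
applied at load time, never downstream.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AgeBand",
    "LifeTable",
    "OnsetTable",
    "ProgressionTable",
    "RegressionModel",
    "ClinicalDetectionModel",
    "ScreeningPolicy",
    "ScenarioConfig",
    "ParameterInterval",
    "ValidationError",
    "expand_life_table",
    "load_scenario",
    "fixture_path",
]

GRADES = (1, 2, 3)
DEFAULT_MAX_AGE = 100

_FIXTURE_DIR = Path(__file__).parent / "fixtures"


def fixture_path(name: str) -> Path:
    """Path of a shipped fixture (scenario config or parameter table)."""
    p = _FIXTURE_DIR / name
    if not p.exists():
        raise FileNotFoundError(f"no shipped fixture named {name!r}")
    return p


class ValidationError(ValueError):
    """A parameter table or scenario violates a model invariant."""


@dataclass(frozen=True, order=True)
class AgeBand:
    """Closed integer age interval [lower, upper]."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper):
            raise ValidationError(f"invalid age band {self.lower}-{self.upper}")

    def __contains__(self, age: int) -> bool:
        return self.lower <= age <= self.upper


def _check_band_partition(bands: Sequence[AgeBand], max_age: int, what: str) -> None:
    """Bands must be non-overlapping and jointly cover 0..max_age."""
    ordered = sorted(bands)
    expect = 0
    for b in ordered:
        if b.lower > expect:
            raise ValidationError(
                f"{what}: no band covers age {expect} (gap before {b.lower}-{b.upper})"
            )
        if b.lower < expect:
            raise ValidationError(
                f"{what}: band {b.lower}-{b.upper} overlaps the previous band"
            )
        expect = b.upper + 1
    if expect <= max_age:
        raise ValidationError(f"{what}: ages {expect}..{max_age} are not covered")


def _check_prob(value: float, what: str, hi: float = 1.0) -> None:
    if not (0.0 <= value <= hi):
        raise ValidationError(f"{what} = {value} outside [0, {hi}]")


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability for every integer age 0..max_age."""

    values: np.ndarray  # shape (max_age + 1,)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("life table must be a per-age vector")
        if np.any((v < 0) | (v > 1)):
            bad = int(np.argmax((v < 0) | (v > 1)))
            raise ValidationError(f"death probability at age {bad} = {v[bad]} outside [0,1]")
        if v[-1] != 1.0:
            raise ValidationError(
                f"death probability at max age must be 1.0, got {v[-1]}"
            )

    @property
    def max_age(self) -> int:
        return self.values.size - 1

    def __call__(self, age: int) -> float:
        return float(self.values[age])


def expand_life_table(
    band_endpoints: Sequence[tuple[int, int, float, float]],
    max_age: int = DEFAULT_MAX_AGE,
    scale: float = 1e-2,
) -> LifeTable:
    """Expand per-band endpoint ranges into a per-age life table.

    Printed mortality tables often give, per age band, the probability at the
    band's first and last age.  Within a band the endpoints are pinned to the
    first and last age and intermediate ages are log-linearly interpolated
    (mortality is approximately exponential in age).  Single-age bands take
    their single printed value.

    Parameters
    ----------
    band_endpoints
        Sequence of ``(lower, upper, first_value, last_value)``; values on the
        printed scale (``scale`` applied here, default 1e-2).
    """
    bands = [AgeBand(int(lo), int(hi)) for lo, hi, _, _ in band_endpoints]
    _check_band_partition(bands, max_age, "life table")
    out = np.empty(max_age + 1, dtype=float)
    for (lo, hi, v0, v1), band in zip(band_endpoints, bands):
        p0, p1 = v0 * scale, v1 * scale
        if band.lower == band.upper:
            out[band.lower] = p0
            continue
        if p0 <= 0 or p1 <= 0:
            raise ValidationError(
                f"life table band {lo}-{hi}: nonpositive endpoint with "
                "log-linear interpolation"
            )
        ages = np.arange(band.lower, min(band.upper, max_age) + 1)
        frac = (ages - band.lower) / (band.upper - band.lower)
        out[ages] = p0 * (p1 / p0) ** frac
        out[band.lower] = p0  # endpoints pinned exactly, no float drift
        if band.upper <= max_age:
            out[band.upper] = p1
    return LifeTable(out)


@dataclass(frozen=True)
class _BandedGradeTable:
    """Mapping (age band, grade) -> annual probability; shared machinery."""

    bands: tuple[AgeBand, ...]
    values: np.ndarray  # shape (n_bands, 3), plain probabilities
    max_age: int

    _what = "banded table"
    _max_value = 1.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "bands", tuple(self.bands))
        if vals.shape != (len(self.bands), 3):
            raise ValidationError(f"{self._what}: need one row of 3 grades per band")
        _check_band_partition(self.bands, self.max_age, self._what)
        for band, row in zip(self.bands, vals):
            for g, v in zip(GRADES, row):
                if not (0.0 <= v <= self._max_value):
                    raise ValidationError(
                        f"{self._what} band {band.lower}-{band.upper} grade {g}: "
                        f"{v} outside [0, {self._max_value}]"
                    )

    def lookup(self, age: int, grade: int) -> float:
        """Probability for the unique band containing ``age``."""
        return float(self.per_age()[self._age_index(age), grade - 1])

    def _age_index(self, age: int) -> int:
        if not (0 <= age <= self.max_age):
            raise ValidationError(f"{self._what}: age {age} outside 0..{self.max_age}")
        return int(age)

    def per_age(self) -> np.ndarray:
        """Dense (max_age+1, 3) per-age expansion; cached."""
        cached = getattr(self, "_per_age_cache", None)
        if cached is None:
            cached = np.zeros((self.max_age + 1, 3), dtype=float)
            for band, row in zip(self.bands, self.values):
                cached[band.lower : band.upper + 1, :] = row
            object.__setattr__(self, "_per_age_cache", cached)
        return cached


class OnsetTable(_BandedGradeTable):
    """P2: annual probability of DCIS onset by age band and grade.

    Onset is zero before age 20 and from age 95 on; all values are small
    (the printed source is in units of 1e-3 per year).
    """

    _what = "onset table"
    _max_value = 0.01

    def __post_init__(self) -> None:
        super().__post_init__()
        per_age = self.per_age()
        if np.any(per_age[:20] != 0.0):
            raise ValidationError("onset table: onset must be zero for ages 0-19")
        if self.max_age >= 95 and np.any(per_age[95:] != 0.0):
            raise ValidationError("onset table: onset must be zero for ages 95+")
        if np.any(per_age.sum(axis=1) > 1.0):
            raise ValidationError("onset table: grade probabilities sum to > 1")


class ProgressionTable(_BandedGradeTable):
    """P4: annual probability of DCIS -> IBC progression by age band and grade."""

    _what = "progression table"

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.per_age()[:20] != 0.0):
            raise ValidationError("progression table: must be zero for ages 0-19")


@dataclass(frozen=True)
class RegressionModel:
    """P3: annual probability of DCIS regression to healthy, per grade."""

    values: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (3,):
            raise ValidationError("regression model needs one value per grade")
        for g, x in zip(GRADES, v):
            _check_prob(float(x), f"regression probability grade {g}")

    def lookup(self, grade: int) -> float:
        return float(self.values[grade - 1])


@dataclass(frozen=True)
class ClinicalDetectionModel:
    """P6: annual probability that a present DCIS is clinically detected."""

    value: float

    def __post_init__(self) -> None:
        _check_prob(self.value, "clinical detection probability")


@dataclass(frozen=True)
class ScreeningPolicy:
    """Organized-screening programme: round schedule, participation, sensitivity.

    ``sensitivity`` is the per-examination probability (P5) that a present
    DCIS is detected at an attended round; ``participation`` is drawn
    independently per round.
    """

    start_age: int
    end_age: int
    interval: int
    participation: float
    sensitivity: float

    def __post_init__(self) -> None:
        if self.start_age > self.end_age:
            raise ValidationError("screening start_age > end_age")
        if self.interval < 1:
            raise ValidationError("screening interval must be >= 1 year")
        _check_prob(self.participation, "participation rate")
        _check_prob(self.sensitivity, "mammographic sensitivity")

    def schedule(self) -> list[int]:
        """Ordered screening ages: start, start+interval, ... <= end."""
        return list(range(self.start_age, self.end_age + 1, self.interval))


@dataclass(frozen=True)
class ParameterInterval:
    """Uncertainty interval for one scalar parameter or table-wide multiplier.

    ``parameter_path`` is a dotted identifier understood by
    :mod:`dcisim.sensitivity` (e.g. ``"onset.scale"``,
    ``"screening.participation"``).
    """

    parameter_path: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(
                f"interval for {self.parameter_path}: low {self.low} > high {self.high}"
            )


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, serializable description of one simulation scenario."""

    label: str
    cohort_size: int
    iterations: int
    seed: int
    life_table: LifeTable
    onset: OnsetTable
    regression: RegressionModel
    progression: ProgressionTable
    clinical: ClinicalDetectionModel
    screening: ScreeningPolicy | None = None
    max_age: int = DEFAULT_MAX_AGE

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        for name, table in (("life table", self.life_table.max_age),
                            ("onset", self.onset.max_age),
                            ("progression", self.progression.max_age)):
            if table != self.max_age:
                raise ValidationError(
                    f"{name} covers ages 0..{table} but max_age = {self.max_age}"
                )
        # Competing annual risks out of DCIS are one multinomial per year and
        # must leave nonnegative residual "remain" mass: P3 + P4 + P6 <= 1.
        # A sum above 1 is rejected here, never silently renormalized.
        total = (
            self.regression.values[None, :]
            + self.progression.per_age()
            + self.clinical.value
        )
        if np.any(total > 1.0):
            a, g = np.unravel_index(int(np.argmax(total)), total.shape)
            raise ValidationError(
                f"competing DCIS exit probabilities sum to {total[a, g]:.3f} > 1 "
                f"at age {a}, grade {g + 1}"
            )

    def replace(self, **changes) -> "ScenarioConfig":
        """Functional update (delegates to :func:`dataclasses.replace`)."""
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path, comment="#", skip_blank_lines=True, float_precision="round_trip"
    )


def _load_banded(path: Path, cls, scale: float, max_age: int):
    df = _read_csv(path)
    need = {"lower", "upper", "g1", "g2", "g3"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path.name}: expected columns {sorted(need)}")
    bands = [AgeBand(int(r.lower), int(r.upper)) for r in df.itertuples()]
    values = df[["g1", "g2", "g3"]].to_numpy(dtype=float) * scale
    return cls(bands=tuple(bands), values=values, max_age=max_age)


def _load_life_table(spec, base: Path, max_age: int) -> LifeTable:
    """``spec`` is ``{"bands": file}`` (endpoint ranges, x1e-2) or
    ``{"ages": file}`` (explicit per-age plain probabilities)."""
    if not isinstance(spec, Mapping) or len(spec) != 1:
        raise ValidationError("life_table must be {'bands': file} or {'ages': file}")
    kind, name = next(iter(spec.items()))
    df = _read_csv(base / name)
    if kind == "bands":
        need = {"lower", "upper", "first", "last"}
        if not need.issubset(df.columns):
            raise ValidationError(f"{name}: expected columns {sorted(need)}")
        eps = [(int(r.lower), int(r.upper), float(r.first), float(r.last))
               for r in df.itertuples()]
        return expand_life_table(eps, max_age=max_age)
    if kind == "ages":
        if not {"age", "value"}.issubset(df.columns):
            raise ValidationError(f"{name}: expected columns ['age', 'value']")
        out = np.full(max_age + 1, np.nan)
        out[df["age"].to_numpy(dtype=int)] = df["value"].to_numpy(dtype=float)
        if np.any(np.isnan(out)):
            missing = int(np.argmax(np.isnan(out)))
            raise ValidationError(f"{name}: no death probability for age {missing}")
        return LifeTable(out)
    raise ValidationError(f"unknown life_table source kind {kind!r}")


def load_scenario(source: str | Path, **overrides) -> ScenarioConfig:
    """Load and fully validate a scenario from a YAML config file.

    Table files referenced by the config are resolved relative to the config
    file's directory.  Keyword ``overrides`` replace top-level scalar keys
    (``cohort_size``, ``iterations``, ``seed``, ``label``) before validation.
    """
    path = Path(source)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: config must be a mapping")
    raw = {**raw, **overrides}
    base = path.parent
    max_age = int(raw.get("max_age", DEFAULT_MAX_AGE))

    reg = raw.get("regression", {})
    regression = RegressionModel(
        np.array([float(reg[k]) for k in ("g1", "g2", "g3")])
    )
    screening = None
    if raw.get("screening") is not None:
        s = raw["screening"]
        screening = ScreeningPolicy(
            start_age=int(s["start_age"]),
            end_age=int(s["end_age"]),
            interval=int(s["interval"]),
            participation=float(s["participation"]),
            sensitivity=float(s["sensitivity"]),
        )
    return ScenarioConfig(
        label=str(raw.get("label", path.stem)),
        cohort_size=int(raw["cohort_size"]),
        iterations=int(raw["iterations"]),
        seed=int(raw["seed"]),
        max_age=max_age,
        life_table=_load_life_table(raw["life_table"], base, max_age),
        onset=_load_banded(base / raw["onset"], OnsetTable, 1e-3, max_age),
        progression=_load_banded(base / raw["progression"], ProgressionTable, 1.0, max_age),
        regression=regression,
        clinical=ClinicalDetectionModel(float(raw["clinical"])),
        screening=screening,
    )


def save_scenario(config: ScenarioConfig, directory: str | Path) -> Path:
    """Write a scenario (config YAML + per-age/banded CSV tables) to a directory.

    The written form round-trips exactly through :func:`load_scenario`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    ages = np.arange(config.max_age + 1)
    pd.DataFrame({"age": ages, "value": config.life_table.values}).to_csv(
        directory / "life_table.csv", index=False, float_format="%.17g"
    )

    def banded_frame(table: _BandedGradeTable, scale: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower": [b.lower for b in table.bands],
                "upper": [b.upper for b in table.bands],
                "g1": table.values[:, 0] / scale,
                "g2": table.values[:, 1] / scale,
                "g3": table.values[:, 2] / scale,
            }
        )

    banded_frame(config.onset, 1e-3).to_csv(
        directory / "onset.csv", index=False, float_format="%.17g"
    )
    banded_frame(config.progression, 1.0).to_csv(
        directory / "progression.csv", index=False, float_format="%.17g"
    )

    doc: dict = {
        "label": config.label,
        "cohort_size": config.cohort_size,
        "iterations": config.iterations,
        "seed": config.seed,
        "max_age": config.max_age,
        "life_table": {"ages": "life_table.csv"},
        "onset": "onset.csv",
        "progression": "progression.csv",
        "regression": {
            "g1": float(config.regression.values[0]),
            "g2": float(config.regression.values[1]),
            "g3": float(config.regression.values[2]),
        },
        "clinical": float(config.clinical.value),
        "screening": None
        if config.screening is None
        else {
            "start_age": config.screening.start_age,
            "end_age": config.screening.end_age,
            "interval": config.screening.interval,
            "participation": config.screening.participation,
            "sensitivity": config.screening.sensitivity,
        },
    }
    out = directory / "scenario.yaml"
    out.write_text(yaml.safe_dump(doc, sort_keys=False))
    return out


def load_intervals(source: str | Path) -> list[ParameterInterval]:
    """Load parameter uncertainty intervals from a YAML file.

    Format: ``{intervals: [{parameter: path, low: x, high: y}, ...]}``.
    """
    raw = yaml.safe_load(Path(source).read_text())
    items = raw["intervals"] if isinstance(raw, Mapping) else raw
    return [
        ParameterInterval(str(d["parameter"]), float(d["low"]), float(d["high"]))
        for d in items
    ]
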