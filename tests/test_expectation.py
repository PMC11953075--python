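"""Expectation oracle: hand propagation, enumeration oracle, engine agreement."""

import numpy as np
import pytest

from dcisim.engine import Fate, simulate_cohort
from dcisim.expectation import (
    expected_detection_rates,
    expected_fate_distribution,
    expected_grade_distribution,
    propagate,
)
from dcisim.parameters import (
    AgeBand,
    ClinicalDetectionModel,
    LifeTable,
    ProgressionTable,
    RegressionModel,
    ScenarioConfig,
    ScreeningPolicy,
)

from conftest import UncappedOnset, make_config, onset_table


class TestTrivialLimits:
    def test_no_onset_no_dcis_mass(self):
        dist = propagate(make_config())
        assert np.all(dist.dcis == 0)
        assert dist.exits[0] == pytest.approx(1.0)  # all die of other causes
        assert dist.total_onset_mass == 0.0
        with pytest.raises(ValueError):
            expected_fate_distribution(dist)

    def test_single_onset_hand_propagation(self):
        """Onset 0.001 of grade 3 at age 50, perfect screen at 51: the
        screen-detected mass is exactly 0.001 and the round rate 1.0/1,000."""
        cfg = make_config(
            onset=onset_table({(50, 50): (0.0, 0.0, 0.001)}),
            screening=ScreeningPolicy(51, 51, 1, 1.0, 1.0),
        )
        dist = propagate(cfg)
        assert dist.screens[51] == pytest.approx(1.0)
        assert dist.detections[51, 2] == pytest.approx(0.001)
        rates = expected_detection_rates(dist, cfg.screening)
        total = rates.loc[rates.stratum == "total", "rate"].item()
        assert total == pytest.approx(1.0)

    def test_zero_sensitivity_zero_rates(self, nl_config):
        s = nl_config.screening
        cfg = nl_config.replace(
            screening=ScreeningPolicy(s.start_age, s.end_age, s.interval, s.participation, 0.0)
        )
        dist = propagate(cfg)
        assert dist.detections.sum() == 0.0
        rates = expected_detection_rates(dist, cfg.screening)
        assert np.all(rates["rate"] == 0.0)


def test_mass_conserved_along_full_trajectory(nl_config):
    dist = propagate(nl_config)  # raises internally on leaks > 1e-12
    start_of_year = dist.healthy + dist.dcis.sum(axis=1)
    assert start_of_year[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(start_of_year <= 1.0 + 1e-12)
    # everything is eventually absorbed, and fates account for every onset
    assert dist.exits.sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.fates.sum() == pytest.approx(dist.total_onset_mass, abs=1e-12)


def test_closed_form_fate_split_exact(constant_hazard_config):
    dist = propagate(constant_hazard_config)
    fates = expected_fate_distribution(dist)
    resolved = fates["regressed"] + fates["progressed_ibc"] + fates["clin_detected"]
    assert fates["regressed"] / resolved == pytest.approx(0.05 / 0.25, abs=1e-12)
    assert fates["progressed_ibc"] / resolved == pytest.approx(0.15 / 0.25, abs=1e-12)


class TestMonotonicity:
    def _with(self, cfg, **kw):
        s = cfg.screening
        fields = {
            "start_age": s.start_age,
            "end_age": s.end_age,
            "interval": s.interval,
            "participation": s.participation,
            "sensitivity": s.sensitivity,
        }
        fields.update(kw)
        return cfg.replace(screening=ScreeningPolicy(**fields))

    def test_detections_nondecreasing_in_sensitivity_and_participation(self, nl_config):
        det_sens = [
            propagate(self._with(nl_config, sensitivity=v)).detections.sum()
            for v in (0.4, 0.7, 1.0)
        ]
        det_part = [
            propagate(self._with(nl_config, participation=v)).detections.sum()
            for v in (0.4, 0.7, 1.0)
        ]
        assert det_sens == sorted(det_sens)
        assert det_part == sorted(det_part)

    def test_rate_increases_with_sensitivity_decreases_with_participation(self, nl_config):
        def rate(cfg):
            d = propagate(cfg)
            return d.detections.sum() / d.screens.sum()

        r_sens = [rate(self._with(nl_config, sensitivity=v)) for v in (0.4, 0.7, 1.0)]
        assert r_sens == sorted(r_sens)
        # higher participation depletes the prevalent pool: inverse effect
        r_part = [rate(self._with(nl_config, participation=v)) for v in (0.4, 0.7, 1.0)]
        assert r_part == sorted(r_part, reverse=True)


class TestEnumerationOracle:
    """Exact agreement with an independent memoized path enumeration on a
    short-horizon scenario (ages 0..30, onset at 20-22, screens at 21/23)."""

    MAX_AGE = 30

    def _toy(self):
        death = np.zeros(self.MAX_AGE + 1)
        death[25] = 0.1
        death[-1] = 1.0
        return ScenarioConfig(
            label="enum-toy",
            cohort_size=1,
            iterations=1,
            seed=0,
            max_age=self.MAX_AGE,
            life_table=LifeTable(death),
            onset=onset_table(
                {(20, 22): (0.2, 0.1, 0.3)}, max_age=self.MAX_AGE, cls=UncappedOnset
            ),
            regression=RegressionModel(np.array([0.1, 0.1, 0.1])),
            progression=ProgressionTable(
                bands=(AgeBand(0, 19), AgeBand(20, self.MAX_AGE)),
                values=np.array([[0.0, 0.0, 0.0], [0.15, 0.2, 0.25]]),
                max_age=self.MAX_AGE,
            ),
            clinical=ClinicalDetectionModel(0.05),
            screening=ScreeningPolicy(21, 23, 2, 0.8, 0.9),
        )

    def _enumerate(self, cfg):
        """Top-down memoized enumeration of all life paths: expected counts
        of each fate, screens and detections, per (age, state)."""
        from functools import lru_cache

        part, sens = cfg.screening.participation, cfg.screening.sensitivity
        rounds = set(cfg.screening.schedule())
        onset = cfg.onset.per_age()
        prog = cfg.progression.per_age()
        reg = cfg.regression.values
        p6 = cfg.clinical.value
        death = cfg.life_table.values
        zero = {
            "screens": 0.0, "detections": 0.0, "onsets": 0.0,
            **{f.name.lower(): 0.0 for f in Fate},
        }

        def add(acc, other, w):
            return {k: acc[k] + w * other[k] for k in acc}

        @lru_cache(maxsize=None)
        def expect(age, state):  # state: 0 healthy, 1..3 DCIS
            if age > cfg.max_age:
                # beyond the horizon: open episode is censored
                out = dict(zero)
                if state > 0:
                    out["censored"] = 1.0
                return out
            out = dict(zero)
            # screening
            stay = 1.0
            if age in rounds:
                out["screens"] += part
                if state > 0:
                    p_det = part * sens
                    out["detections"] += p_det
                    out["screen_detected"] += p_det
                    stay = 1.0 - p_det
            # death
            p1 = death[age]
            if state > 0:
                out["died_other"] += stay * p1
            survive = stay * (1.0 - p1)
            if survive == 0.0:
                return out
            # transitions
            if state == 0:
                rest = 1.0 - onset[age].sum()
                for g in (1, 2, 3):
                    p = onset[age][g - 1]
                    if p:
                        branch = add(dict(zero), expect(age + 1, g), 1.0)
                        branch["onsets"] += 1.0
                        out = add(out, branch, survive * p)
                out = add(out, expect(age + 1, 0), survive * rest)
            else:
                g = state - 1
                p3, p4 = reg[g], prog[age][g]
                out["regressed"] += survive * p3
                out["progressed_ibc"] += survive * p4
                out["clin_detected"] += survive * p6
                out = add(out, expect(age + 1, 0), survive * p3)
                out = add(out, expect(age + 1, state), survive * (1 - p3 - p4 - p6))
            return out

        return expect(0, 0)

    def test_exact_agreement_with_propagate(self):
        cfg = self._toy()
        expected = self._enumerate(cfg)
        dist = propagate(cfg)
        assert dist.screens.sum() == pytest.approx(expected["screens"], rel=1e-12)
        assert dist.detections.sum() == pytest.approx(expected["detections"], rel=1e-12)
        assert dist.total_onset_mass == pytest.approx(expected["onsets"], rel=1e-12)
        for f in Fate:
            name = f.name.lower()
            assert dist.fates[f].sum() == pytest.approx(expected[name], rel=1e-12, abs=1e-15)


def test_engine_agrees_with_oracle_at_small_scale(nl_small):
    """Monte Carlo aggregates match the deterministic expectation within
    3 standard errors at 3 x 20,000 women."""
    dist = propagate(nl_small)
    results = simulate_cohort(nl_small)
    n = nl_small.cohort_size * nl_small.iterations

    onset_rate = sum(r.n_episodes for r in results) / n
    se = np.sqrt(dist.total_onset_mass / n)  # ~Poisson
    assert onset_rate == pytest.approx(dist.total_onset_mass, abs=3 * se)

    det = sum(int(r.detections_by_age_grade.sum()) for r in results) / n
    exp_det = dist.detections.sum()
    assert det == pytest.approx(exp_det, abs=3 * np.sqrt(exp_det / n))

    screens = sum(r.mammograms for r in results) / n
    exp_screens = dist.screens.sum()
    # per-woman screen count has variance below (rounds)^2; crude bound
    assert screens == pytest.approx(exp_screens, abs=3 * np.sqrt(13.0 / n) * 4)


def test_grade_distribution_matches_engine(nl_small):
    dist = propagate(nl_small)
    grades = expected_grade_distribution(dist)
    assert sum(grades.values()) == pytest.approx(1.0, abs=1e-12)
    assert grades[3] > grades[2] > grades[1]
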