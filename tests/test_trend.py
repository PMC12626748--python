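"""Trend log maintenance and drift detection."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

import ringqa as rq
from ringqa.detector import ValidationError
from ringqa.trend import METRICS, TrendSeries, append, detect_drift, summarize

PROCESS_SD = 0.016  # commissioned day-to-day output SD


def _result(day, output=1.0):
    return rq.QAResult(
        timestamp=datetime(2024, 1, 1) + timedelta(days=day),
        output_constancy=output, left_target_ratio=1.0, right_target_ratio=1.0,
        field_x=130.0, field_y=77.5, ctmv_offset=(0.0, 0.0, 0.0),
        ctmv_extrapolated=(False, False, False), laser_deviation=None,
        statuses={"output": rq.Status.PASS})


def _series_from_outputs(values, start=datetime(2024, 1, 1)):
    idx = pd.DatetimeIndex([start + timedelta(days=i) for i in range(len(values))],
                           name="date")
    df = pd.DataFrame({m: np.nan for m in METRICS} | {"overall": "pass"}, index=idx)
    df["output"] = values
    return TrendSeries(df)


def test_append_grows_sorts_and_rejects_duplicates():
    s = TrendSeries.empty()
    for day in (0, 2, 1):
        s = append(s, _result(day))
    assert len(s) == 3
    assert list(s.df.index) == sorted(s.df.index)
    with pytest.raises(ValidationError):
        append(s, _result(2))


def test_summarize_matches_brute_force():
    rng = np.random.default_rng(3)
    values = 1.0 + rng.normal(0, 0.01, 40)
    s = TrendSeries.empty()
    for day, v in enumerate(values):
        s = append(s, _result(day, output=v))
    mean, sd, n = summarize(s, "output")
    assert n == 40
    assert mean == pytest.approx(float(np.mean(values)), abs=1e-12)
    assert sd == pytest.approx(float(np.std(values, ddof=1)), abs=1e-12)


def test_summarize_closed_forms():
    s = _series_from_outputs([1.01, 1.03])
    mean, sd, n = summarize(s, "output")
    assert mean == pytest.approx(1.02)
    assert sd == pytest.approx(abs(1.01 - 1.03) / np.sqrt(2))
    const = _series_from_outputs([0.7] * 5)
    assert summarize(const, "output") == (pytest.approx(0.7), 0.0, 5)
    with pytest.raises(ValidationError):
        summarize(s, "no_such_metric")


def test_year_scenario_output_sd_near_generator(plan, geom, cal):
    """Daily output SD over a simulated run tracks the generator's 0.016."""
    sds = []
    for seed in (0, 1, 2):
        days = rq.make_year_scenario(plan, geom, 60, seed=seed)
        s = TrendSeries.empty()
        for day in days:
            s = append(s, rq.evaluate(day.frame, cal,
                                      registered_shift=day.registered_shift))
        mean, sd, n = summarize(s, "output")
        sds.append(sd)
        assert n == 60
        assert mean == pytest.approx(1.006, abs=0.01)
    assert np.mean(sds) == pytest.approx(0.016, rel=0.30)


def test_year_scenario_offaxis_target_means(plan, geom, cal):
    """Left/right target ratios drift as configured (near 1.007 / 0.996)."""
    days = rq.make_year_scenario(plan, geom, 80, seed=5)
    s = TrendSeries.empty()
    for day in days:
        s = append(s, rq.evaluate(day.frame, cal))
    assert summarize(s, "left_target")[0] == pytest.approx(1.007, abs=0.005)
    assert summarize(s, "right_target")[0] == pytest.approx(0.996, abs=0.005)


def test_null_series_rarely_alarms():
    """In-control output series: <= 1 false alarm across 20 seeds."""
    alarms = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        s = _series_from_outputs(1.0 + rng.normal(0, PROCESS_SD, 180))
        alarms += len(detect_drift(s, "output", baseline_sd=PROCESS_SD))
    assert alarms <= 1


def test_gradual_drift_is_caught_before_day_180():
    """+0.01%/day output drift after an in-control lead-in raises an alarm."""
    rng = np.random.default_rng(7)
    lead_in = 60
    values = 1.0 + rng.normal(0, PROCESS_SD, lead_in + 180)
    values[lead_in:] += 1e-4 * np.arange(180)
    s = _series_from_outputs(values)
    alarms = detect_drift(s, "output", baseline_sd=PROCESS_SD)
    assert alarms, "drift went undetected"
    first = min(a.date for a in alarms)
    drift_day = (first - datetime(2024, 1, 1)).days - lead_in
    assert drift_day < 180
    assert any(a.direction == 1 for a in alarms)


def test_step_change_triggers_cusum_within_10_days():
    rng = np.random.default_rng(0)
    values = 1.0 + rng.normal(0, PROCESS_SD, 150)
    values[90:] += 0.03
    s = _series_from_outputs(values)
    cusum = [a for a in detect_drift(s, "output", baseline_sd=PROCESS_SD)
             if a.detector == "cusum"
             and (a.date - datetime(2024, 1, 1)).days >= 90]
    assert cusum
    delay = (min(a.date for a in cusum) - datetime(2024, 1, 1)).days - 90 + 1
    assert delay <= 10


def test_detectors_invariant_to_constant_offset():
    rng = np.random.default_rng(11)
    values = 1.0 + rng.normal(0, PROCESS_SD, 200)
    values[120:] += 0.025
    a1 = detect_drift(_series_from_outputs(values), "output",
                      baseline_sd=PROCESS_SD)
    a2 = detect_drift(_series_from_outputs(values + 5.0), "output",
                      baseline_sd=PROCESS_SD)
    assert [(a.date, a.detector, a.direction) for a in a1] == \
           [(a.date, a.detector, a.direction) for a in a2]


def test_detect_drift_input_checks():
    s = _series_from_outputs([1.0] * 30)
    with pytest.raises(ValidationError):
        detect_drift(s, "output")           # shorter than window
    flat = _series_from_outputs([1.0] * 90)
    with pytest.raises(ValidationError):
        detect_drift(flat, "output")        # zero baseline variance
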