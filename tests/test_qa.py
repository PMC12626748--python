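"""Daily metric computation and tolerance classification."""

import numpy as np
import pytest

import ringqa as rq
from ringqa.detector import ValidationError
from ringqa.qa import (Status, Tolerance, laser_localization, offaxis_constancy,
                       output_constancy)


def test_output_constancy_worked_example():
    """Central dose 306.39 cGy over baseline 304.72 cGy reads 1.005."""
    assert round(output_constancy(306.39, 304.72), 3) == 1.005
    assert output_constancy(10.0, 10.0) == 1.0
    assert output_constancy(0.97 * 123.4, 123.4) == pytest.approx(0.97)
    with pytest.raises(ValidationError):
        output_constancy(300.0, 0.0)


def test_offaxis_constancy_baseline_and_linearity(cal, plan, geom, baseline_frame):
    peaks = rq.measure_peaks(baseline_frame, plan)
    left, right = offaxis_constancy(peaks[rq.Role.LEFT_TARGET].dose,
                                    peaks[rq.Role.RIGHT_TARGET].dose, cal)
    assert (left, right) == (pytest.approx(1.0), pytest.approx(1.0))
    scaled = rq.simulate_measurement(plan, geom, rq.DeliveryParams(output_scale=1.02))
    speaks = rq.measure_peaks(scaled, plan)
    sl, sr = offaxis_constancy(speaks[rq.Role.LEFT_TARGET].dose,
                               speaks[rq.Role.RIGHT_TARGET].dose, cal)
    assert sl == pytest.approx(1.02, rel=1e-9)
    assert sr == pytest.approx(1.02, rel=1e-9)


def test_ctmv_offsets_baseline_zero(cal, baseline_frame):
    offsets, flags = rq.ctmv_offsets(baseline_frame, cal)
    for v in offsets:
        assert v == pytest.approx(0.0, abs=1e-3)
    assert flags == (False, False, False)


def test_ctmv_offsets_recover_applied_shift(cal, plan, geom):
    applied = (0.5, -1.0, 1.5)
    frame = rq.simulate_measurement(plan, geom, rq.DeliveryParams(shift=applied))
    offsets, _ = rq.ctmv_offsets(frame, cal)
    for a, r in zip(applied, offsets):
        assert r == pytest.approx(a, abs=0.05)


def test_ctmv_offsets_invariant_to_output_scale(cal, plan, geom):
    shift = (0.8, 0.4, -1.2)
    f1 = rq.simulate_measurement(plan, geom, rq.DeliveryParams(shift=shift))
    f2 = rq.simulate_measurement(plan, geom,
                                 rq.DeliveryParams(shift=shift, output_scale=1.03))
    for a, b in zip(rq.ctmv_offsets(f1, cal)[0], rq.ctmv_offsets(f2, cal)[0]):
        assert b == pytest.approx(a, abs=1e-9)  # mm; fp-level identical


def test_laser_localization_arithmetic(cal):
    assert laser_localization((20.0, 15.0, -22.0), cal) == (0.0, 0.0, 0.0)
    dev = laser_localization((20.18, 14.61, -22.31), cal)
    assert dev == (pytest.approx(0.18), pytest.approx(-0.39), pytest.approx(-0.31))
    # antisymmetry under swapping registered and nominal
    swapped = tuple(n - r for r, n in zip((20.18, 14.61, -22.31),
                                          cal.nominal_laser_offsets))
    assert all(a == pytest.approx(-b) for a, b in zip(dev, swapped))


def test_evaluate_baseline_all_pass(cal, baseline_frame):
    result = rq.evaluate(baseline_frame, cal,
                         registered_shift=(20.0, 15.0, -22.0))
    assert result.overall == Status.PASS
    assert set(result.statuses) == {
        "output", "left_target", "right_target", "field_x", "field_y",
        "ctmv_x", "ctmv_y", "ctmv_z", "laser_x", "laser_y", "laser_z"}
    d = result.to_dict()
    assert d["output_constancy"] == 1.0
    assert d["field_x_mm"] == 130.0


@pytest.mark.parametrize("scale, expected", [
    (1.0, Status.PASS),
    (1.025, Status.WARN),
    (1.035, Status.FAIL),
    (0.975, Status.WARN),
    (0.965, Status.FAIL),
])
def test_output_threshold_crossings(cal, plan, geom, scale, expected):
    frame = rq.simulate_measurement(plan, geom, rq.DeliveryParams(output_scale=scale))
    result = rq.evaluate(frame, cal)
    assert result.statuses["output"] == expected


def test_status_is_monotone_in_metric_deviation():
    tol = Tolerance(0.98, 1.02, 0.97, 1.03)
    values = np.linspace(1.0, 1.06, 40)
    severities = [{"pass": 0, "warn": 1, "fail": 2}[tol.classify(v).value]
                  for v in values]
    assert severities == sorted(severities)
    severities_down = [{"pass": 0, "warn": 1, "fail": 2}[tol.classify(v).value]
                       for v in np.linspace(1.0, 0.94, 40)]
    assert severities_down == sorted(severities_down)


def test_tolerance_bounds_must_nest():
    with pytest.raises(ValidationError):
        Tolerance(0.95, 1.05, 0.97, 1.03)


def test_report_display_rounding(cal, plan, geom):
    """Ratios display to 3 decimals, millimetres to 2 (sub-mm offsets keep sign)."""
    frame = rq.simulate_measurement(
        plan, geom, rq.DeliveryParams(shift=(-0.01, -0.06, 0.24),
                                      output_scale=306.39 / 304.72))
    d = rq.evaluate(frame, cal).to_dict()
    assert d["output_constancy"] == 1.005
    assert d["ctmv_offset_mm"] == [pytest.approx(-0.01, abs=0.005),
                                   pytest.approx(-0.06, abs=0.005),
                                   pytest.approx(0.24, abs=0.01)]
    assert all(len(str(abs(v)).split(".")[-1]) <= 2 for v in d["ctmv_offset_mm"])


def test_overall_status_is_worst(cal, plan, geom):
    frame = rq.simulate_measurement(plan, geom, rq.DeliveryParams(output_scale=1.035))
    result = rq.evaluate(frame, cal)
    assert result.statuses["output"] == Status.FAIL
    assert result.overall == Status.FAIL
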