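"""Daily QA metric assembly and tolerance classification.

One measurement frame plus a calibration set yields the full daily report:
output constancy, off-axis (left/right target) dose constancy, X/Y field
sizes, CT-MV isocenter offsets and, when an image-registration shift is
supplied, laser-localization deviations.  Each metric gets a pass / warn /
fail status from a configurable tolerance table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum

from .calibrate import AXES, CalibrationSet, measure_peaks, pair_ratios, predict_shift
from .detector import MeasurementFrame, ValidationError
from .plan import Role
from .profiles import compute_fwhm, extract_profiles


class Status(str, Enum):
    PASS = "pass"
    WARN = "warn"
    FAIL = "fail"


_SEVERITY = {Status.PASS: 0, Status.WARN: 1, Status.FAIL: 2}


@dataclass(frozen=True)
class Tolerance:
    """Two-level symmetric-or-not band: fail bounds enclose warn bounds."""

    warn_low: float
    warn_high: float
    fail_low: float
    fail_high: float

    def __post_init__(self) -> None:
        if not (self.fail_low <= self.warn_low <= self.warn_high <= self.fail_high):
            raise ValidationError("fail bounds must enclose warn bounds")

    def classify(self, value: float) -> Status:
        if self.fail_low <= value <= self.fail_high:
            if self.warn_low <= value <= self.warn_high:
                return Status.PASS
            return Status.WARN
        return Status.FAIL


def _sym(warn: float, fail: float) -> Tolerance:
    return Tolerance(-warn, warn, -fail, fail)


@dataclass(frozen=True)
class ToleranceTable:
    """Per-metric warn/fail bands.

    Defaults follow conventional daily-QA action levels (TG-142 style):
    output and target ratios 2%/3%, CT-MV offsets 1/2 mm, field-size
    deviation from baseline 2/3 mm, laser deviation 1.5/2 mm.  Field-size
    tolerances are expressed on the deviation from the calibration baseline.
    """

    output: Tolerance = Tolerance(0.98, 1.02, 0.97, 1.03)
    left_target: Tolerance = Tolerance(0.98, 1.02, 0.97, 1.03)
    right_target: Tolerance = Tolerance(0.98, 1.02, 0.97, 1.03)
    field_dev_mm: Tolerance = _sym(2.0, 3.0)
    ctmv_mm: Tolerance = _sym(1.0, 2.0)
    laser_mm: Tolerance = _sym(1.5, 2.0)


@dataclass(frozen=True)
class QAResult:
    """The full daily metric vector with per-metric statuses.

    Display convention: ratios to 3 decimals, millimetres to 2.
    """

    timestamp: datetime
    output_constancy: float
    left_target_ratio: float
    right_target_ratio: float
    field_x: float
    field_y: float
    ctmv_offset: tuple[float, float, float]
    ctmv_extrapolated: tuple[bool, bool, bool]
    laser_deviation: tuple[float, float, float] | None
    statuses: dict[str, Status] = field(default_factory=dict)

    @property
    def overall(self) -> Status:
        return max(self.statuses.values(), key=_SEVERITY.__getitem__)

    def to_dict(self) -> dict:
        d = {
            "timestamp": self.timestamp.isoformat(),
            "output_constancy": round(self.output_constancy, 3),
            "left_target_ratio": round(self.left_target_ratio, 3),
            "right_target_ratio": round(self.right_target_ratio, 3),
            "field_x_mm": round(self.field_x, 2),
            "field_y_mm": round(self.field_y, 2),
            "ctmv_offset_mm": [round(v, 2) for v in self.ctmv_offset],
            "ctmv_extrapolated": list(self.ctmv_extrapolated),
            "laser_deviation_mm": (None if self.laser_deviation is None
                                   else [round(v, 2) for v in self.laser_deviation]),
            "statuses": {k: v.value for k, v in self.statuses.items()},
            "overall": self.overall.value,
        }
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


# ---------------------------------------------------------------------------
# Individual metrics
# ---------------------------------------------------------------------------

def output_constancy(center_dose: float, baseline_dose: float) -> float:
    """Today's central dose over the commissioned baseline."""
    if baseline_dose <= 0:
        raise ValidationError("baseline dose must be > 0")
    return center_dose / baseline_dose


def offaxis_constancy(left_dose: float, right_dose: float,
                      cal: CalibrationSet) -> tuple[float, float]:
    """Left and right target doses relative to their baselines."""
    if cal.baseline_left_dose <= 0 or cal.baseline_right_dose <= 0:
        raise ValidationError("baseline target doses must be > 0")
    return left_dose / cal.baseline_left_dose, right_dose / cal.baseline_right_dose


def ctmv_offsets(frame: MeasurementFrame, cal: CalibrationSet,
                 ) -> tuple[tuple[float, float, float], tuple[bool, bool, bool]]:
    """CT-MV isocenter offset per axis from the designated pair ratios.

    Positive = phantom displaced toward +axis relative to baseline.  Also
    returns per-axis flags marking estimates outside the calibration range.
    """
    ratios = pair_ratios(measure_peaks(frame, cal.plan))
    estimates = [predict_shift(cal.models[a], ratios[a]) for a in AXES]
    return (tuple(e.mm for e in estimates), tuple(e.extrapolated for e in estimates))


def laser_localization(registered_shift: tuple[float, float, float],
                       cal: CalibrationSet) -> tuple[float, float, float]:
    """Deviation of the image-registration shift from the nominal offsets."""
    return tuple(r - n for r, n in zip(registered_shift, cal.nominal_laser_offsets))


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------

def evaluate(frame: MeasurementFrame, cal: CalibrationSet,
             tolerances: ToleranceTable | None = None,
             registered_shift: tuple[float, float, float] | None = None,
             ) -> QAResult:
    """Compute every daily metric and classify it against the tolerances."""
    tol = tolerances or ToleranceTable()
    peaks = measure_peaks(frame, cal.plan)
    prof_x, prof_y = extract_profiles(frame)

    out = output_constancy(peaks[Role.CENTER_OUTPUT].dose, cal.baseline_center_dose)
    left, right = offaxis_constancy(peaks[Role.LEFT_TARGET].dose,
                                    peaks[Role.RIGHT_TARGET].dose, cal)
    field_x = compute_fwhm(prof_x, cal.plan.flat_x.roi)
    field_y = compute_fwhm(prof_y, cal.plan.flat_y.roi)
    offsets, extrapolated = ctmv_offsets(frame, cal)

    statuses = {
        "output": tol.output.classify(out),
        "left_target": tol.left_target.classify(left),
        "right_target": tol.right_target.classify(right),
        "field_x": tol.field_dev_mm.classify(field_x - cal.baseline_fwhm_x),
        "field_y": tol.field_dev_mm.classify(field_y - cal.baseline_fwhm_y),
    }
    for axis, value in zip(AXES, offsets):
        statuses[f"ctmv_{axis.lower()}"] = tol.ctmv_mm.classify(value)

    laser = None
    if registered_shift is not None:
        laser = laser_localization(registered_shift, cal)
        for axis, value in zip(AXES, laser):
            statuses[f"laser_{axis.lower()}"] = tol.laser_mm.classify(value)

    return QAResult(
        timestamp=frame.timestamp,
        output_constancy=out,
        left_target_ratio=left,
        right_target_ratio=right,
        field_x=field_x,
        field_y=field_y,
        ctmv_offset=offsets,
        ctmv_extrapolated=extrapolated,
        laser_deviation=laser,
        statuses=statuses,
    )
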