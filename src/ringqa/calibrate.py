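"""Linear dose-peak-ratio -> shift calibration.

For each axis the designated peak pair's dose ratio is regressed on the
applied phantom shift over the intentional-shift suite (ordinary least
squares, ratio-on-shift); inverting the fitted line turns a daily pair
ratio into a CT-MV isocenter offset estimate.  Because the ratio is taken
between two peaks of the *same* frame, the estimate is exactly invariant to
global output drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .detector import MeasurementFrame, ValidationError
from .plan import PAIR_ROLES, PlanModel, Role
from .profiles import PeakMeasurement, compute_fwhm, extract_profiles, locate_peak, peak_ratio
from .simulate import CALIBRATION_RANGE_MM, DeliveryParams

AXES = ("X", "Y", "Z")

#: default nominal laser-marker phantom offsets (mm): LT-RT, SUP-INF, ANT-POST
DEFAULT_LASER_OFFSETS = (20.0, 15.0, -22.0)


@dataclass(frozen=True)
class ShiftModel:
    """Per-axis linear map ratio = slope * shift + intercept."""

    axis: str
    slope: float
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}")
        if self.slope == 0:
            raise ValidationError("slope must be nonzero")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"r2 must be in [0, 1], got {self.r2!r}")


class ShiftEstimate(NamedTuple):
    mm: float
    extrapolated: bool


def fit_shift_model(samples: list[tuple[float, float]], axis: str) -> ShiftModel:
    """OLS fit of pair ratio on known shift (mm) for one axis.

    ``samples`` are (ratio, known_shift_mm) pairs; at least three samples
    over at least two distinct shifts are required.
    """
    if len(samples) < 3:
        raise ValidationError(f"{axis}: need >= 3 samples, got {len(samples)}")
    ratios = np.array([s[0] for s in samples], dtype=float)
    shifts = np.array([s[1] for s in samples], dtype=float)
    if np.unique(shifts).size < 2:
        raise ValidationError(f"{axis}: all shifts identical, fit is degenerate")
    res = stats.linregress(shifts, ratios)
    # rvalue is NaN when the ratios are exactly constant; a flat response
    # cannot be inverted into a shift
    if not np.isfinite(res.rvalue) or res.slope == 0:
        raise ValidationError(f"{axis}: ratios do not respond to shifts")
    return ShiftModel(axis, float(res.slope), float(res.intercept),
                      float(min(res.rvalue ** 2, 1.0)))


def predict_shift(model: ShiftModel, ratio: float) -> ShiftEstimate:
    """Invert the fitted line: shift = (ratio - intercept) / slope.

    Flags, without failing, estimates outside the +/-1.5 mm calibration
    range.
    """
    mm = (ratio - model.intercept) / model.slope
    return ShiftEstimate(float(mm), bool(abs(mm) > CALIBRATION_RANGE_MM))


@dataclass(frozen=True)
class CalibrationSet:
    """Everything the daily analysis needs: models, baselines, plan."""

    models: dict[str, ShiftModel]
    baseline_center_dose: float
    baseline_left_dose: float
    baseline_right_dose: float
    baseline_pair_ratios: dict[str, float]
    baseline_fwhm_x: float
    baseline_fwhm_y: float
    nominal_laser_offsets: tuple[float, float, float] = DEFAULT_LASER_OFFSETS
    plan: PlanModel | None = None

    def __post_init__(self) -> None:
        missing = [a for a in AXES if a not in self.models]
        if missing:
            raise ValidationError(f"missing shift model for axis {', '.join(missing)}")
        for dose in (self.baseline_center_dose, self.baseline_left_dose,
                     self.baseline_right_dose):
            if dose <= 0:
                raise ValidationError("baseline doses must be > 0")
        if self.plan is None:
            raise ValidationError("calibration must carry its plan model")


# ---------------------------------------------------------------------------
# Peak measurement against a plan
# ---------------------------------------------------------------------------

def measure_peaks(frame: MeasurementFrame, plan: PlanModel,
                  ) -> dict[Role, PeakMeasurement]:
    """Locate every plan peak in a frame, keyed by its role."""
    prof_x, prof_y = extract_profiles(frame)
    out: dict[Role, PeakMeasurement] = {}
    for spec in plan.peaks:
        profile = prof_x if spec.axis.value == "X" else prof_y
        out[spec.role] = locate_peak(profile, spec.center, plan.search_window,
                                     peak_id=spec.id)
    return out


def pair_ratios(peaks: dict[Role, PeakMeasurement]) -> dict[str, float]:
    """The three designated same-frame pair ratios, keyed by axis."""
    return {axis: peak_ratio(peaks[num], peaks[den])
            for axis, (num, den) in PAIR_ROLES.items()}


def calibrate(plan: PlanModel, geom, suite: list[tuple[DeliveryParams, MeasurementFrame]],
              nominal_laser_offsets: tuple[float, float, float] = DEFAULT_LASER_OFFSETS,
              ) -> CalibrationSet:
    """Build a full CalibrationSet from an intentional-shift suite.

    Extracts the three pair ratios from every delivery, fits the three
    per-axis models, and records all baselines from the zero-shift member.
    """
    samples: dict[str, list[tuple[float, float]]] = {a: [] for a in AXES}
    baseline_frame = None
    for params, frame in suite:
        ratios = pair_ratios(measure_peaks(frame, plan))
        for i, axis in enumerate(AXES):
            samples[axis].append((ratios[axis], params.shift[i]))
        if params.shift == (0.0, 0.0, 0.0) and baseline_frame is None:
            baseline_frame = frame
    if baseline_frame is None:
        raise ValidationError("suite contains no zero-shift (baseline) delivery")
    for axis in AXES:
        if np.unique([s for _, s in samples[axis]]).size < 2:
            raise ValidationError(f"suite has no shift coverage on axis {axis}")
    models = {axis: fit_shift_model(samples[axis], axis) for axis in AXES}

    peaks = measure_peaks(baseline_frame, plan)
    prof_x, prof_y = extract_profiles(baseline_frame)
    return CalibrationSet(
        models=models,
        baseline_center_dose=peaks[Role.CENTER_OUTPUT].dose,
        baseline_left_dose=peaks[Role.LEFT_TARGET].dose,
        baseline_right_dose=peaks[Role.RIGHT_TARGET].dose,
        baseline_pair_ratios=pair_ratios(peaks),
        baseline_fwhm_x=compute_fwhm(prof_x, plan.flat_x.roi),
        baseline_fwhm_y=compute_fwhm(prof_y, plan.flat_y.roi),
        nominal_laser_offsets=tuple(nominal_laser_offsets),
        plan=plan,
    )
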