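"""Synthetic delivery simulator for the daily-QA plan.

The forward model writes, for each diode at position ``p`` on arm ``a``::

    dose = output_scale * [ trapezoid_a(p; nominal FWHM * field_scale_a)
             + sum over peaks on a of
               amplitude * (1 + k . shift) * exp(-(p - center - lat)^2 / (2 w^2)) ]
           * (1 + eps),   eps ~ N(0, noise_sd) i.i.d. per diode

where ``lat`` is the lateral component of the phantom shift seen by that arm
(dx for the X arm, dy for the Y arm) and the ANT-POST component dz acts only
through the sensitivity vectors ``k``.  Noise-free simulation is
bit-reproducible; noisy simulation is reproducible given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timedelta
from importlib import resources

import numpy as np

from .detector import Axis, DiodeArrayGeometry, MeasurementFrame, ValidationError
from .plan import PlanModel, Role

#: largest shift magnitude (mm) the linear response model is trusted for
SHIFT_VALIDITY_MM = 5.0

#: calibration range of the shift models (mm)
CALIBRATION_RANGE_MM = 1.5

#: default per-diode fractional noise (0.5%)
DEFAULT_NOISE_SD = 0.005


@dataclass(frozen=True)
class DeliveryParams:
    """Controlled perturbations of one plan delivery."""

    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    output_scale: float = 1.0
    field_scale_x: float = 1.0
    field_scale_y: float = 1.0
    noise_sd: float = 0.0
    seed: int | None = None
    # off-axis target drift multipliers (B and C peak amplitudes); kept at 1
    # except in long-run machine-drift scenarios
    left_target_scale: float = 1.0
    right_target_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.output_scale <= 0:
            raise ValidationError("output_scale must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if max(abs(s) for s in self.shift) > SHIFT_VALIDITY_MM:
            raise ValidationError(
                f"|shift| components must be <= {SHIFT_VALIDITY_MM:g} mm "
                "(linear response validity region)"
            )


def _axis_doses(plan: PlanModel, positions: np.ndarray, axis: Axis,
                params: DeliveryParams) -> np.ndarray:
    shift = np.asarray(params.shift, dtype=float)
    lat = shift[0] if axis == Axis.X else shift[1]
    field_scale = params.field_scale_x if axis == Axis.X else params.field_scale_y
    dose = plan.flat(axis).profile(positions, field_scale)
    for peak in plan.peaks_on(axis):
        amp = peak.amplitude * (1.0 + float(np.dot(peak.sensitivity, shift)))
        if peak.role == Role.LEFT_TARGET:
            amp *= params.left_target_scale
        elif peak.role == Role.RIGHT_TARGET:
            amp *= params.right_target_scale
        dose += amp * np.exp(-((positions - peak.center - lat) ** 2)
                             / (2.0 * peak.width ** 2))
    return params.output_scale * dose


def simulate_measurement(plan: PlanModel, geom: DiodeArrayGeometry,
                         params: DeliveryParams,
                         timestamp: datetime | None = None) -> MeasurementFrame:
    """Simulate one delivery of ``plan`` onto ``geom`` under ``params``."""
    plan.check_geometry(geom)
    dose = np.concatenate([
        _axis_doses(plan, geom.x_positions, Axis.X, params),
        _axis_doses(plan, geom.y_positions, Axis.Y, params),
    ])
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        dose = dose * (1.0 + rng.normal(0.0, params.noise_sd, size=dose.shape))
    dose = np.maximum(dose, 0.0)
    ts = timestamp or datetime(2024, 1, 1, 7, 30)
    meta = {
        "plan": "dailyqa-default",
        "shift_mm": "{:g},{:g},{:g}".format(*params.shift),
        "output_scale": f"{params.output_scale:g}",
    }
    return MeasurementFrame(geom, dose, ts, meta)


# ---------------------------------------------------------------------------
# Validation suite (the intentional-shift deliveries)
# ---------------------------------------------------------------------------

def load_suite_manifest() -> list[tuple[float, float, float]]:
    """The 43 intentional-shift combinations, from the shipped manifest.

    One unshifted baseline, 18 single-axis shifts (+/-0.5, 1.0, 1.5 mm per
    axis) and 24 multi-axis combinations fixed once in
    ``data/validation_suite.csv``.
    """
    text = resources.files("ringqa.data").joinpath("validation_suite.csv").read_text()
    shifts: list[tuple[float, float, float]] = []
    for row in csv.DictReader(filter(lambda l: not l.startswith("#"), text.splitlines())):
        shifts.append((float(row["dx_mm"]), float(row["dy_mm"]), float(row["dz_mm"])))
    return shifts


def make_validation_suite(plan: PlanModel, geom: DiodeArrayGeometry,
                          noise_sd: float = 0.0, seed: int | None = None,
                          ) -> list[tuple[DeliveryParams, MeasurementFrame]]:
    """Simulate the full 43-delivery intentional-shift validation suite."""
    shifts = load_suite_manifest()
    child_seeds: list[int | None]
    if noise_sd > 0:
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(len(shifts))]
    else:
        child_seeds = [None] * len(shifts)
    suite = []
    for (dx, dy, dz), s in zip(shifts, child_seeds):
        params = DeliveryParams(shift=(dx, dy, dz), noise_sd=noise_sd, seed=s)
        suite.append((params, simulate_measurement(plan, geom, params)))
    return suite


# ---------------------------------------------------------------------------
# Long-run (trend) scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DailyDelivery:
    date: datetime
    params: DeliveryParams
    frame: MeasurementFrame
    registered_shift: tuple[float, float, float]


@dataclass(frozen=True)
class YearScenario:
    """Distribution of day-to-day machine behaviour for trend simulations.

    Defaults emulate a stable service year: output constancy fluctuating a
    few percent around a mean slightly above one, small residual CT-MV
    offsets, mild off-axis target drift, and laser registrations scattered
    around the nominal phantom offsets.
    """

    output_mean: float = 1.006
    output_sd: float = 0.016
    output_drift_per_day: float = 0.0
    output_step: float = 0.0            # additive step applied from step_day on
    step_day: int = 0
    left_target_mean: float = 1.007
    left_target_sd: float = 0.005
    right_target_mean: float = 0.996
    right_target_sd: float = 0.004
    ctmv_mean: tuple[float, float, float] = (-0.335, 0.19, -0.544)
    ctmv_sd: tuple[float, float, float] = (0.23, 0.19, 0.36)
    laser_nominal: tuple[float, float, float] = (20.0, 15.0, -22.0)
    laser_mean: tuple[float, float, float] = (20.18, 14.61, -22.31)
    laser_sd: tuple[float, float, float] = (0.26, 0.31, 0.45)
    noise_sd: float = DEFAULT_NOISE_SD


def make_year_scenario(plan: PlanModel, geom: DiodeArrayGeometry,
                       n_days: int, seed: int,
                       scenario: YearScenario | None = None,
                       start: datetime | None = None) -> list[DailyDelivery]:
    """Simulate ``n_days`` consecutive daily-QA deliveries."""
    sc = scenario or YearScenario()
    rng = np.random.default_rng(seed)
    start = start or datetime(2024, 1, 2, 7, 30)
    days = []
    for i in range(n_days):
        out = rng.normal(sc.output_mean, sc.output_sd) + sc.output_drift_per_day * i
        if i >= sc.step_day:
            out += sc.output_step
        shift = tuple(rng.normal(m, s) for m, s in zip(sc.ctmv_mean, sc.ctmv_sd))
        registered = tuple(rng.normal(m, s) for m, s in zip(sc.laser_mean, sc.laser_sd))
        out = max(out, 1e-6)
        # the *reported* target ratio is (output_scale x target amplitude
        # multiplier), so divide the drawn total ratio by the day's output
        left = rng.normal(sc.left_target_mean, sc.left_target_sd)
        right = rng.normal(sc.right_target_mean, sc.right_target_sd)
        params = DeliveryParams(
            shift=shift, output_scale=out, noise_sd=sc.noise_sd,
            seed=int(rng.integers(2 ** 31)),
            left_target_scale=left / out,
            right_target_scale=right / out,
        )
        date = start + timedelta(days=i)
        days.append(DailyDelivery(
            date, params, simulate_measurement(plan, geom, params, timestamp=date),
            registered))
    return days
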