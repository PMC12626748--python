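"""The daily-QA plan model.

The QA plan paints a deliberately structured dose map onto the diode array:
a flat field for the field-size check, a central peak for output constancy,
two off-axis target peaks for profile constancy, and three designated peak
pairs whose dose ratios respond linearly to phantom shifts along LT-RT (X),
SUP-INF (Y) and ANT-POST (Z).  Each pair has one shift-modulated member and
one insensitive reference member, so the pair ratio is exactly linear in the
shift and exactly invariant to global output drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .detector import Axis, DiodeArrayGeometry, ValidationError


class Role(str, Enum):
    CENTER_OUTPUT = "center_output"
    LEFT_TARGET = "left_target"
    RIGHT_TARGET = "right_target"
    X_PAIR_LEFT = "x_pair_left"
    X_PAIR_RIGHT = "x_pair_right"
    Y_PAIR_INF = "y_pair_inf"
    Y_PAIR_SUP = "y_pair_sup"
    Z_PAIR_A = "z_pair_a"
    Z_PAIR_B = "z_pair_b"


#: roles that must appear exactly once in a plan
UNIQUE_ROLES = set(Role)

#: designated pair (numerator role, denominator role) per shift axis
PAIR_ROLES: dict[str, tuple[Role, Role]] = {
    "X": (Role.X_PAIR_LEFT, Role.X_PAIR_RIGHT),
    "Y": (Role.Y_PAIR_INF, Role.Y_PAIR_SUP),
    "Z": (Role.Z_PAIR_A, Role.Z_PAIR_B),
}


@dataclass(frozen=True)
class PeakSpec:
    """One designed dose peak (contour A-I of the plan).

    ``sensitivity`` is the fractional amplitude change per mm of phantom
    shift along (X, Y, Z); the delivered amplitude is
    ``amplitude * (1 + k . shift)``.
    """

    id: str
    axis: Axis
    center: float
    amplitude: float
    width: float
    role: Role
    sensitivity: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValidationError(f"peak {self.id}: amplitude must be > 0")
        if self.width <= 0:
            raise ValidationError(f"peak {self.id}: width must be > 0")
        if len(self.sensitivity) != 3:
            raise ValidationError(f"peak {self.id}: sensitivity must be a 3-vector")


@dataclass(frozen=True)
class FlatRegion:
    """Trapezoidal flat-field parameters for one axis.

    The field is a plateau of ``plateau_dose`` cGy over |p| <= plateau_half_width,
    falling linearly to zero over ``shoulder`` mm on each side.
    """

    plateau_half_width: float
    shoulder: float
    plateau_dose: float
    roi: tuple[float, float]

    def profile(self, positions: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Trapezoid dose at ``positions``; ``scale`` multiplies the geometry."""
        p = self.plateau_half_width * scale
        s = self.shoulder * scale
        a = np.abs(np.asarray(positions, dtype=float))
        out = np.clip((p + s - a) / s, 0.0, 1.0)
        return self.plateau_dose * out


@dataclass(frozen=True)
class PlanModel:
    peaks: tuple[PeakSpec, ...]
    nominal_field_x: float
    nominal_field_y: float
    flat_x: FlatRegion
    flat_y: FlatRegion
    search_window: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        roles = [p.role for p in self.peaks]
        for role in UNIQUE_ROLES:
            n = roles.count(role)
            if n != 1:
                raise ValidationError(f"plan must contain exactly one {role.value} peak, got {n}")

    def peak(self, role: Role) -> PeakSpec:
        for p in self.peaks:
            if p.role == role:
                return p
        raise KeyError(role)  # pragma: no cover - guarded by __post_init__

    def peaks_on(self, axis: Axis) -> list[PeakSpec]:
        return [p for p in self.peaks if p.axis == axis]

    def flat(self, axis: Axis) -> FlatRegion:
        return self.flat_x if axis == Axis.X else self.flat_y

    def check_geometry(self, geom: DiodeArrayGeometry) -> None:
        """Every peak center must lie within the span of its arm."""
        for p in self.peaks:
            pos = geom.positions(p.axis)
            if not (pos[0] <= p.center <= pos[-1]):
                raise ValidationError(
                    f"peak {p.id} center {p.center:g} mm outside {p.axis.value} arm span"
                )


# ---------------------------------------------------------------------------
# Default plan
# ---------------------------------------------------------------------------

#: designed field sizes (FWHM, mm) of the default plan
NOMINAL_FIELD_X = 130.0
NOMINAL_FIELD_Y = 77.5

#: baseline central dose of the default plan (cGy): X plateau + central peak
BASELINE_CENTER_DOSE = 304.72

_X_PLATEAU_DOSE = 200.0
_CENTER_AMPLITUDE = BASELINE_CENTER_DOSE - _X_PLATEAU_DOSE
_Y_PLATEAU_DOSE = 300.0
_SHOULDER = 10.0


def _solve_plateau_half_width(fwhm: float, shoulder: float,
                              plateau_dose: float, roi_max: float) -> float:
    """Plateau half-width that puts the half-of-ROI-max crossing at fwhm/2.

    On the linear shoulder the trapezoid equals ``plateau_dose*(1-(x-p)/s)``;
    the crossing of level roi_max/2 must land at x = fwhm/2.
    """
    level = roi_max / 2.0
    if level >= plateau_dose:
        raise ValidationError("half-maximum level must fall on the shoulder")
    return fwhm / 2.0 - shoulder * (1.0 - level / plateau_dose)


def default_plan() -> PlanModel:
    """The nine-peak daily-QA plan with 130 x 77.5 mm nominal field sizes.

    Pair-ratio sensitivities: d(ratio)/d(shift) = +0.05 /mm (X),
    -0.08 /mm (Y, inverse correlation) and +0.035 /mm (Z, weakest axis).
    """
    peaks = (
        PeakSpec("A", Axis.X, 0.0, _CENTER_AMPLITUDE, 5.0, Role.CENTER_OUTPUT),
        PeakSpec("B", Axis.X, -140.0, 250.0, 4.0, Role.LEFT_TARGET),
        PeakSpec("C", Axis.X, 140.0, 250.0, 4.0, Role.RIGHT_TARGET),
        PeakSpec("D", Axis.X, -100.0, 240.0, 4.0, Role.X_PAIR_LEFT, (0.05, 0.0, 0.0)),
        PeakSpec("E", Axis.X, 100.0, 240.0, 4.0, Role.X_PAIR_RIGHT),
        PeakSpec("F", Axis.Y, -64.0, 220.0, 4.0, Role.Y_PAIR_INF, (0.0, -0.08, 0.0)),
        PeakSpec("G", Axis.Y, 64.0, 220.0, 4.0, Role.Y_PAIR_SUP),
        PeakSpec("H", Axis.Y, -88.0, 200.0, 4.0, Role.Z_PAIR_A, (0.0, 0.0, 0.035)),
        PeakSpec("I", Axis.Y, 88.0, 200.0, 4.0, Role.Z_PAIR_B),
    )
    flat_x = FlatRegion(
        plateau_half_width=_solve_plateau_half_width(
            NOMINAL_FIELD_X, _SHOULDER, _X_PLATEAU_DOSE, BASELINE_CENTER_DOSE),
        shoulder=_SHOULDER,
        plateau_dose=_X_PLATEAU_DOSE,
        roi=(-75.0, 75.0),
    )
    flat_y = FlatRegion(
        plateau_half_width=_solve_plateau_half_width(
            NOMINAL_FIELD_Y, _SHOULDER, _Y_PLATEAU_DOSE, _Y_PLATEAU_DOSE),
        shoulder=_SHOULDER,
        plateau_dose=_Y_PLATEAU_DOSE,
        roi=(-50.0, 50.0),
    )
    return PlanModel(peaks, NOMINAL_FIELD_X, NOMINAL_FIELD_Y, flat_x, flat_y)
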