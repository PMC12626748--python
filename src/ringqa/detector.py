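"""Diode-array geometry and measurement containers.

The detector modelled here is a planar QA device with discrete diodes laid
out on two orthogonal arms through the isocenter: a long lateral (X, LT-RT)
arm and a shorter longitudinal (Y, SUP-INF) arm.  All positions are in the
phantom frame, isocenter-centered, in millimetres: X positive toward patient
left, Y positive toward superior, Z positive toward anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum

import numpy as np


class Axis(str, Enum):
    X = "X"
    Y = "Y"


DEFAULT_DIODE_COUNT = 223


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


def _check_strictly_increasing(a: np.ndarray, label: str) -> None:
    if len(a) >= 2 and not np.all(np.diff(a) > 0):
        raise ValidationError(f"{label} positions must be strictly increasing")


def _check_brackets_zero(a: np.ndarray, label: str) -> None:
    if len(a) == 0 or a[0] > 0 or a[-1] < 0:
        raise ValidationError(f"{label} arm must contain or bracket position 0")


@dataclass(frozen=True)
class DiodeArrayGeometry:
    """Positions of the diodes on the two arms of the 2D array.

    Parameters
    ----------
    x_positions, y_positions
        Ordered diode coordinates (mm) on the lateral and longitudinal arm.
    device_name
        Free-form device label.
    """

    x_positions: np.ndarray
    y_positions: np.ndarray
    device_name: str = "tomodose-like-223"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_positions", np.asarray(self.x_positions, dtype=float))
        object.__setattr__(self, "y_positions", np.asarray(self.y_positions, dtype=float))
        _check_strictly_increasing(self.x_positions, "X")
        _check_strictly_increasing(self.y_positions, "Y")
        _check_brackets_zero(self.x_positions, "X")
        _check_brackets_zero(self.y_positions, "Y")
        span_x = self.x_positions[-1] - self.x_positions[0]
        if span_x < 400.0:
            raise ValidationError(
                f"X arm span {span_x:g} mm < 400 mm (device must cover 40 cm fields)"
            )

    @property
    def n_diodes(self) -> int:
        return len(self.x_positions) + len(self.y_positions)

    def positions(self, axis: Axis) -> np.ndarray:
        return self.x_positions if axis == Axis.X else self.y_positions


def default_geometry(device_name: str = "tomodose-like-223") -> DiodeArrayGeometry:
    """Two-arm layout with 2 mm pitch within +/-66 mm and 4 mm outside.

    The X arm runs -200..+200 mm (covers a 40 cm lateral field), the Y arm
    -104..+108 mm.  The Y arm is trimmed by one diode at the inferior end so
    the two arms total exactly 223 diodes.  The true vendor layout is not
    public, so the geometry is fully configurable; this default only has to
    resolve the QA plan's peaks and field edges.
    """
    inner = np.arange(-66.0, 66.0 + 1e-9, 2.0)

    def arm(end: float) -> np.ndarray:
        outer = np.arange(68.0, end + 1e-9, 4.0)
        return np.concatenate([-outer[::-1], inner, outer])

    x = arm(200.0)
    y = arm(108.0)[1:]  # trim inferior-most diode -> 223 total
    geom = DiodeArrayGeometry(x, y, device_name)
    assert geom.n_diodes == DEFAULT_DIODE_COUNT
    return geom


@dataclass(frozen=True)
class MeasurementFrame:
    """One delivery's dose samples over the whole array.

    ``doses`` holds X-arm doses first (in ``geometry.x_positions`` order),
    then Y-arm doses, in cGy.
    """

    geometry: DiodeArrayGeometry
    doses: np.ndarray
    timestamp: datetime
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        if len(self.doses) != self.geometry.n_diodes:
            raise ValidationError(
                f"dose count {len(self.doses)} != diode count {self.geometry.n_diodes}"
            )
        if not np.all(np.isfinite(self.doses)):
            raise ValidationError("doses must be finite")
        if np.any(self.doses < 0):
            raise ValidationError("doses must be >= 0")
        if not isinstance(self.timestamp, datetime):
            raise ValidationError("timestamp must be a datetime")

    @property
    def x_doses(self) -> np.ndarray:
        return self.doses[: len(self.geometry.x_positions)]

    @property
    def y_doses(self) -> np.ndarray:
        return self.doses[len(self.geometry.x_positions):]


@dataclass(frozen=True)
class Profile:
    """A 1D dose profile along one arm."""

    axis: Axis
    positions: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        if len(self.positions) != len(self.doses):
            raise ValidationError("positions and doses must have equal length")
        _check_strictly_increasing(self.positions, self.axis.value)
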