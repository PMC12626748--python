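"""Profile extraction and peak/field quantification.

This is the measurement side of the QA chain: split a frame into its X and
Y arm profiles, locate the designed dose peaks with sub-spacing accuracy,
and measure the field size as the FWHM of the flat region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import Axis, MeasurementFrame, Profile, ValidationError


@dataclass(frozen=True)
class PeakMeasurement:
    """A located dose peak: refined position (mm) and dose (cGy).

    ``refined`` is False when the windowed maximum sat at a window edge or
    the local curvature was degenerate, in which case the raw diode sample
    is returned unrefined.
    """

    peak_id: str
    position: float
    dose: float
    refined: bool = True


def extract_profiles(frame: MeasurementFrame) -> tuple[Profile, Profile]:
    """Partition a frame's diodes into the X-arm and Y-arm profiles."""
    geom = frame.geometry
    if len(geom.x_positions) == 0 or len(geom.y_positions) == 0:
        raise ValidationError("frame has an empty arm")
    return (
        Profile(Axis.X, geom.x_positions, frame.x_doses),
        Profile(Axis.Y, geom.y_positions, frame.y_doses),
    )


def _parabolic_apex(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Apex of the quadratic through three points with arbitrary spacing.

    Returns None when the points are not concave (no interior maximum).
    """
    (x1, x2, x3), (y1, y2, y3) = x, y
    d21, d31, d32 = x2 - x1, x3 - x1, x3 - x2
    # quadratic coefficient of the Lagrange interpolant
    a = (y1 / (d21 * d31)) - (y2 / (d21 * d32)) + (y3 / (d31 * d32))
    if a >= 0:
        return None
    b = (y2 - y1) / d21 - a * (x1 + x2)
    xv = -b / (2.0 * a)
    c = y2 - a * x2 ** 2 - b * x2
    return xv, a * xv ** 2 + b * xv + c


def locate_peak(profile: Profile, nominal_center: float, window: float = 10.0,
                peak_id: str = "") -> PeakMeasurement:
    """Find and refine the dose peak nearest ``nominal_center``.

    The maximum diode within ``nominal_center +/- window`` is refined by a
    three-point parabolic fit; ties in the windowed maximum resolve toward
    the diode nearest the nominal center.  When the maximum lies at a window
    edge (monotone segment) or the curvature is non-concave, the raw sample
    is returned with ``refined=False``.
    """
    pos, dose = profile.positions, profile.doses
    lo, hi = nominal_center - window, nominal_center + window
    if hi < pos[0] or lo > pos[-1]:
        raise ValidationError(
            f"window [{lo:g}, {hi:g}] mm outside profile span "
            f"[{pos[0]:g}, {pos[-1]:g}] mm")
    idx = np.flatnonzero((pos >= lo) & (pos <= hi))
    if len(idx) < 3:
        raise ValidationError(f"window [{lo:g}, {hi:g}] mm contains < 3 diodes")
    w_pos, w_dose = pos[idx], dose[idx]
    maxima = np.flatnonzero(w_dose == w_dose.max())
    k = maxima[np.argmin(np.abs(w_pos[maxima] - nominal_center))]
    if k == 0 or k == len(idx) - 1:
        return PeakMeasurement(peak_id, float(w_pos[k]), float(w_dose[k]), refined=False)
    apex = _parabolic_apex(w_pos[k - 1:k + 2], w_dose[k - 1:k + 2])
    if apex is None:
        return PeakMeasurement(peak_id, float(w_pos[k]), float(w_dose[k]), refined=False)
    position, value = apex
    # a refined apex cannot leave the bracketing interval
    position = float(np.clip(position, w_pos[k - 1], w_pos[k + 1]))
    return PeakMeasurement(peak_id, position, float(value))


def _crossing(p1: float, d1: float, p2: float, d2: float, level: float) -> float:
    return p1 + (level - d1) * (p2 - p1) / (d2 - d1)


def compute_fwhm(profile: Profile, roi: tuple[float, float]) -> float:
    """Full width at half maximum of the profile within ``roi``.

    The half-maximum is 50% of the maximum dose inside the ROI; the two
    crossings are found by linear interpolation between the bracketing
    diodes on each shoulder, walking outward from the maximum.
    """
    lo, hi = roi
    idx = np.flatnonzero((profile.positions >= lo) & (profile.positions <= hi))
    if len(idx) < 3:
        raise ValidationError("ROI contains fewer than 3 diodes")
    pos, dose = profile.positions[idx], profile.doses[idx]
    imax = int(np.argmax(dose))
    level = dose[imax] / 2.0

    def walk(direction: int) -> float:
        i = imax
        while 0 <= i + direction < len(pos):
            j = i + direction
            if dose[j] < level:
                return _crossing(pos[i], dose[i], pos[j], dose[j], level)
            i = j
        raise ValidationError(
            "field edge not contained in ROI (no half-maximum crossing on "
            f"{'right' if direction > 0 else 'left'} shoulder)")

    return walk(+1) - walk(-1)


def peak_ratio(a: PeakMeasurement, b: PeakMeasurement) -> float:
    """Dose ratio a/b of two located peaks."""
    if a.dose <= 0 or b.dose <= 0:
        raise ValidationError("peak doses must be > 0 to form a ratio")
    return a.dose / b.dose
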