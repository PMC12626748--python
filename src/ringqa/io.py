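"""Readers and writers for the package's documented text formats.

The vendor's measurement export dialect is proprietary, so the package
defines its own canonical interchange formats, all versioned with a
``format_version`` key:

* measurement CSV — a ``key,value`` header block (``format_version``,
  ``device``, ``timestamp``, plus free-form metadata), then a
  ``axis,position_mm,dose_cGy`` column header and one row per diode;
* calibration bundle — JSON holding the three shift models, all baselines,
  the nominal laser offsets and the plan model;
* tolerance table — YAML with one warn/fail band per metric;
* trend log — CSV, one dated row per daily QA result.
"""

from __future__ import annotations

import json
from datetime import datetime
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import CalibrationSet, ShiftModel
from .detector import (Axis, DiodeArrayGeometry, MeasurementFrame,
                       ValidationError)
from .plan import FlatRegion, PeakSpec, PlanModel, Role
from .trend import TREND_FORMAT_VERSION, TrendSeries
from .qa import Tolerance, ToleranceTable

MEASUREMENT_FORMAT_VERSION = 1
BUNDLE_FORMAT_VERSION = 1

_COLUMN_HEADER = "axis,position_mm,dose_cGy"
_MANDATORY_KEYS = ("format_version", "device", "timestamp")


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


# ---------------------------------------------------------------------------
# Measurement CSV
# ---------------------------------------------------------------------------

def read_measurement(path: str | Path) -> MeasurementFrame:
    """Read a measurement CSV; diode order is normalized per arm."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#"):
            continue
        if line.strip() == _COLUMN_HEADER:
            body_start = i + 1
            break
        parts = line.split(",", 1)
        if len(parts) != 2 or not parts[0].strip():
            raise FormatError(f"{path}: malformed header line {i + 1}: {line!r}")
        header[parts[0].strip()] = parts[1].strip()
    if body_start is None:
        raise FormatError(f"{path}: missing column header {_COLUMN_HEADER!r}")
    for key in _MANDATORY_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing mandatory header key {key!r}")
    try:
        timestamp = datetime.fromisoformat(header["timestamp"])
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable timestamp: {exc}") from exc

    samples: dict[Axis, list[tuple[float, float]]] = {Axis.X: [], Axis.Y: []}
    for i, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed data row, line {i}: {line!r}")
        try:
            axis = Axis(parts[0].strip())
            pos, dose = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed data row, line {i}: {exc}") from exc
        samples[axis].append((pos, dose))

    arrays: dict[Axis, tuple[np.ndarray, np.ndarray]] = {}
    for axis, rows in samples.items():
        rows.sort()
        pos = np.array([r[0] for r in rows])
        if len(pos) >= 2 and np.any(np.diff(pos) <= 0):
            raise ValidationError(f"{path}: duplicate positions on {axis.value} arm")
        arrays[axis] = (pos, np.array([r[1] for r in rows]))

    geometry = DiodeArrayGeometry(arrays[Axis.X][0], arrays[Axis.Y][0],
                                  device_name=header["device"])
    doses = np.concatenate([arrays[Axis.X][1], arrays[Axis.Y][1]])
    meta = {k: v for k, v in header.items() if k not in _MANDATORY_KEYS}
    return MeasurementFrame(geometry, doses, timestamp, meta)


def write_measurement(frame: MeasurementFrame, path: str | Path) -> None:
    """Write a measurement CSV re-readable by :func:`read_measurement`.

    Positions and doses are printed with full round-trip precision.
    """
    lines = [
        f"format_version,{MEASUREMENT_FORMAT_VERSION}",
        f"device,{frame.geometry.device_name}",
        f"timestamp,{frame.timestamp.isoformat()}",
    ]
    for key, value in frame.meta.items():
        if key in _MANDATORY_KEYS:
            continue
        if "," in key or "\n" in str(value):
            raise FormatError(f"metadata key/value not representable: {key!r}")
        lines.append(f"{key},{value}")
    lines.append(_COLUMN_HEADER)
    for axis, positions, doses in (
        (Axis.X, frame.geometry.x_positions, frame.x_doses),
        (Axis.Y, frame.geometry.y_positions, frame.y_doses),
    ):
        for p, d in zip(positions, doses):
            lines.append(f"{axis.value},{float(p)!r},{float(d)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Calibration bundle JSON
# ---------------------------------------------------------------------------

def _peak_to_dict(p: PeakSpec) -> dict:
    return {"id": p.id, "axis": p.axis.value, "center": p.center,
            "amplitude": p.amplitude, "width": p.width, "role": p.role.value,
            "sensitivity": list(p.sensitivity)}


def _peak_from_dict(d: dict) -> PeakSpec:
    return PeakSpec(d["id"], Axis(d["axis"]), d["center"], d["amplitude"],
                    d["width"], Role(d["role"]), tuple(d["sensitivity"]))


def _flat_to_dict(f: FlatRegion) -> dict:
    return {"plateau_half_width": f.plateau_half_width, "shoulder": f.shoulder,
            "plateau_dose": f.plateau_dose, "roi": list(f.roi)}


def _flat_from_dict(d: dict) -> FlatRegion:
    return FlatRegion(d["plateau_half_width"], d["shoulder"], d["plateau_dose"],
                      tuple(d["roi"]))


def plan_to_dict(plan: PlanModel) -> dict:
    return {
        "peaks": [_peak_to_dict(p) for p in plan.peaks],
        "nominal_field_x": plan.nominal_field_x,
        "nominal_field_y": plan.nominal_field_y,
        "flat_x": _flat_to_dict(plan.flat_x),
        "flat_y": _flat_to_dict(plan.flat_y),
        "search_window": plan.search_window,
    }


def plan_from_dict(d: dict) -> PlanModel:
    return PlanModel(
        tuple(_peak_from_dict(p) for p in d["peaks"]),
        d["nominal_field_x"], d["nominal_field_y"],
        _flat_from_dict(d["flat_x"]), _flat_from_dict(d["flat_y"]),
        d.get("search_window", 10.0),
    )


def write_plan(plan: PlanModel, path: str | Path) -> None:
    doc = {"format_version": 1} | plan_to_dict(plan)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_plan(path: str | Path) -> PlanModel:
    return plan_from_dict(json.loads(Path(path).read_text()))


def write_geometry(geom: DiodeArrayGeometry, path: str | Path) -> None:
    doc = {"format_version": 1, "device_name": geom.device_name,
           "x_positions": [float(p) for p in geom.x_positions],
           "y_positions": [float(p) for p in geom.y_positions]}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_geometry(path: str | Path) -> DiodeArrayGeometry:
    doc = json.loads(Path(path).read_text())
    return DiodeArrayGeometry(doc["x_positions"], doc["y_positions"],
                              doc.get("device_name", "unnamed"))


def write_bundle(cal: CalibrationSet, path: str | Path) -> None:
    doc = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "models": {a: {"slope": m.slope, "intercept": m.intercept, "r2": m.r2}
                   for a, m in cal.models.items()},
        "baseline_center_dose": cal.baseline_center_dose,
        "baseline_left_dose": cal.baseline_left_dose,
        "baseline_right_dose": cal.baseline_right_dose,
        "baseline_pair_ratios": dict(cal.baseline_pair_ratios),
        "baseline_fwhm_x": cal.baseline_fwhm_x,
        "baseline_fwhm_y": cal.baseline_fwhm_y,
        "nominal_laser_offsets": list(cal.nominal_laser_offsets),
        "plan": plan_to_dict(cal.plan),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _bundle_from_dict(doc: dict, source: str) -> CalibrationSet:
    try:
        models = {a: ShiftModel(a, m["slope"], m["intercept"], m["r2"])
                  for a, m in doc["models"].items()}
        return CalibrationSet(
            models=models,
            baseline_center_dose=doc["baseline_center_dose"],
            baseline_left_dose=doc["baseline_left_dose"],
            baseline_right_dose=doc["baseline_right_dose"],
            baseline_pair_ratios=dict(doc["baseline_pair_ratios"]),
            baseline_fwhm_x=doc["baseline_fwhm_x"],
            baseline_fwhm_y=doc["baseline_fwhm_y"],
            nominal_laser_offsets=tuple(doc["nominal_laser_offsets"]),
            plan=plan_from_dict(doc["plan"]),
        )
    except KeyError as exc:
        raise FormatError(f"{source}: missing bundle field {exc}") from exc


def read_bundle(path: str | Path) -> CalibrationSet:
    doc = json.loads(Path(path).read_text())
    return _bundle_from_dict(doc, str(path))


def default_bundle() -> CalibrationSet:
    """The shipped noise-free calibration of the default plan."""
    doc = json.loads(resources.files("ringqa.data")
                     .joinpath("default_bundle.json").read_text())
    return _bundle_from_dict(doc, "ringqa.data/default_bundle.json")


# ---------------------------------------------------------------------------
# Tolerance table YAML
# ---------------------------------------------------------------------------

_TOL_FIELDS = ("output", "left_target", "right_target", "field_dev_mm",
               "ctmv_mm", "laser_mm")


def write_tolerances(tol: ToleranceTable, path: str | Path) -> None:
    doc = {"format_version": 1}
    for name in _TOL_FIELDS:
        t: Tolerance = getattr(tol, name)
        doc[name] = {"warn_low": t.warn_low, "warn_high": t.warn_high,
                     "fail_low": t.fail_low, "fail_high": t.fail_high}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_tolerances(path: str | Path) -> ToleranceTable:
    doc = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    for name in _TOL_FIELDS:
        if name in doc:
            d = doc[name]
            try:
                kwargs[name] = Tolerance(d["warn_low"], d["warn_high"],
                                         d["fail_low"], d["fail_high"])
            except (KeyError, TypeError) as exc:
                raise FormatError(f"{path}: bad tolerance entry {name!r}: {exc}")
    return ToleranceTable(**kwargs)


# ---------------------------------------------------------------------------
# Trend log CSV
# ---------------------------------------------------------------------------

def write_trend(series: TrendSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ringqa-trend format_version={TREND_FORMAT_VERSION}\n")
        series.df.to_csv(fh)


def read_trend(path: str | Path) -> TrendSeries:
    df = pd.read_csv(path, comment="#", parse_dates=["date"], index_col="date")
    return TrendSeries(df)
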