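# ringqa

Automated daily quality assurance (QA) analysis for ring-gantry linacs that
have no light field or crosshair — machines on which the classic "eyeball
the crosshair" geometry checks are impossible, so dosimetric and geometric
performance must be read out of a single delivery of a structured QA plan
onto a 2D diode array (223 diodes on two orthogonal arms through the
isocenter).

From one measurement the package computes, in the style of a TG-142-type
daily program:

* **Output constancy** — central peak dose over the commissioned baseline,
  `O = D_center / D_baseline`;
* **Off-axis dose constancy** — left/right target peak doses over their
  baselines;
* **Field-size constancy** — FWHM of the flat region of interest on each
  arm (130 mm × 77.5 mm nominal), with half-maximum crossings interpolated
  between diodes;
* **CT–MV isocenter offsets** — per axis *a* ∈ {LT–RT, SUP–INF, ANT–POST},
  a designated pair of dose peaks whose same-frame dose ratio responds
  linearly to phantom shift: `r_a = s_a · Δ_a + c_a`, calibrated by least
  squares over an intentional-shift suite (±1.5 mm in 0.5 mm steps, alone
  and combined, 43 deliveries) and inverted daily as
  `Δ̂_a = (r_a − c_a) / s_a`. Same-frame ratios make the estimate exactly
  invariant to output drift;
* **Laser localization** — image-registration shift minus the nominal
  phantom marker offsets (20, 15, −22) mm;
* **Trend monitoring** — a dated log with per-metric mean/SD and two drift
  detectors (rolling OLS slope and a two-sided CUSUM on standardized
  residuals).

A forward simulator (`simulate_measurement`, `make_validation_suite`,
`make_year_scenario`) generates ground-truth deliveries for every stage, so
the whole chain is testable without a machine. Each metric is classified
pass / warn / fail against a configurable tolerance table.

## Worked example

`examples/01_daily_analysis.py` simulates a morning whose central dose
reads 306.39 cGy against the 304.72 cGy baseline, with a small residual
phantom offset, and analyzes it against the shipped calibration bundle:

```sh
$ python examples/01_daily_analysis.py
{
  "timestamp": "2024-01-01T07:30:00",
  "output_constancy": 1.005,
  "left_target_ratio": 1.005,
  "right_target_ratio": 1.005,
  "field_x_mm": 130.0,
  "field_y_mm": 77.5,
  "ctmv_offset_mm": [-0.01, -0.06, 0.24],
  "laser_deviation_mm": [0.18, -0.39, -0.31],
  ...
  "overall": "pass"
}
```

Reading: beam output is 0.5% above baseline (inside the 2% warning band);
field sizes sit at their 130/77.5 mm baselines; the CT–MV offsets recovered
from the three peak-pair ratios reproduce the applied (−0.01, −0.06,
0.24) mm phantom offset; `laser_deviation_mm` compares the registration
shift to the nominal marker offsets. The other examples cover shift-model
calibration with noise, field-size checking and long-run drift detection.

The same workflow is available from the shell:

```sh
ringqa simulate --scenario validation --out suite --seed 0
ringqa calibrate --suite-dir suite --out bundle.json
ringqa analyze --measurement day.csv --bundle bundle.json --out report.json
ringqa trend --log trend.csv --metric output --detect --plot trend.png
```

`analyze` exits 0/1/2/3 for pass/warn/fail/error, so it can gate a
therapist-facing checklist script.

## Formats

All interchange formats are versioned plain text: measurement CSV
(`key,value` header + `axis,position_mm,dose_cGy` rows), calibration bundle
JSON, tolerance YAML and trend CSV — see `docs/methods.md` and the
docstrings in `ringqa.io`.
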