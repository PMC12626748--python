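# Methods

## The measurement model

The detector is a planar QA device with 223 diodes on two orthogonal arms
through the isocenter. Positions are phantom-frame millimetres: X positive
toward patient left (LT–RT), Y toward superior (SUP–INF), Z toward anterior
(ANT–POST). The true vendor diode layout is not public, so the default
geometry is a documented stand-in chosen to resolve the plan's structures:
2 mm pitch within ±66 mm of center, 4 mm outside, X arm spanning
−200…+200 mm (a 40 cm lateral field must fit), Y arm −104…+108 mm, trimmed
by one diode at the inferior end so the arms total exactly 223. Geometry is
fully configurable; nothing downstream assumes this layout beyond "the
peaks and field edges are sampled".

The simulator writes, per diode at position `p` on arm `a`:

```
dose = output_scale * [ T_a(p; F_a * field_scale_a)
         + Σ_peaks A_i (1 + k_i · Δ) exp(−(p − c_i − lat_a)² / 2w_i²) ]
       * (1 + ε),   ε ~ N(0, noise_sd) i.i.d.
```

where `T_a` is a trapezoidal flat field (plateau + linear shoulders), `Δ`
the phantom shift, `lat_a` its in-arm lateral component (dx on X, dy on Y;
dz is out-of-plane and acts only through the sensitivity vectors `k_i`),
and `A_i, c_i, w_i` the peak amplitudes, centers and Gaussian sigmas.
Noise-free simulation is bit-reproducible; noisy simulation is reproducible
given a seed. Shifts are accepted up to ±5 mm (linearity validity region);
the calibration itself spans ±1.5 mm.

Multiplicative Gaussian peaks on a trapezoid and a linear amplitude
response are modeling choices: the physical claim being emulated is only
that designated peak-pair ratios correlate linearly with shifts over
±1.5 mm.

## The default QA plan

Nine peaks (ids A–I). On the X arm: the central output peak A at 0 mm
(104.72 cGy on a 200 cGy plateau, so the baseline central dose is
304.72 cGy), off-axis targets B/C at ±140 mm, and the LT–RT pair D/E at
±100 mm. On the Y arm: the SUP–INF pair F/G at ±64 mm and the ANT–POST
pair H/I at ±88 mm (both outside the 77.5 mm field, standing on zero
background). Nominal field sizes are 130 mm (X) and 77.5 mm (Y); plateau
half-widths are solved at construction so that the half-of-ROI-maximum
crossing lands exactly at ±F/2 — on X the ROI maximum is the central peak
top (304.72 cGy), on Y the plateau itself.

Each pair has one shift-modulated member and one insensitive reference
member: `k_D = (+0.05, 0, 0)`, `k_F = (0, −0.08, 0)`, `k_H = (0, 0,
+0.035)`, all other `k = 0`. Two properties motivated this over giving both
members opposite-signed sensitivities:

1. the pair ratio `(1 + kΔ)/1` is *exactly* linear in the shift, whereas
   opposite-signed members give `(1 + kΔ)/(1 − kΔ)`, whose quadratic term
   is large enough at these slopes to leave visible lack-of-fit (≈0.06 mm
   systematic inversion error at ±1.5 mm on the Y axis);
2. with both members sharing width and grid phase, the parabolic-refinement
   bias (below) is identical for both and cancels exactly in the ratio.

The Y slope is negative (inverse ratio–shift correlation) and the Z slope
is deliberately the weakest — anterior–posterior motion is out of the
detector plane, so its dosimetric signature is intrinsically fainter and Z
remains the worst-recovered axis. With 0.5% per-diode noise the ratio noise
is ≈0.007 (two refined peaks), giving expected per-delivery shift errors of
σ ≈ 0.007/|slope| ≈ 0.14/0.09/0.20 mm on X/Y/Z — submillimeter on every
axis, ordered X ≈ Y ≪ Z in relative difficulty.

## Profile analysis

* **Peak location**: maximum diode in a ±10 mm window around the nominal
  center (ties resolve toward the nominal), refined by the apex of the
  quadratic through the three bracketing samples (arbitrary spacing). If
  the maximum sits at a window edge or the triple is not concave, the raw
  sample is returned flagged `refined=False`. Against a densely
  oversampled argmax oracle the refined position is good to ≤0.2 mm for
  peak widths at or above the diode pitch; the bias grows as width
  approaches pitch.
* **FWHM**: half-maximum is 50% of the ROI maximum (robust to global
  scaling by construction); crossings are linearly interpolated between the
  bracketing diodes found by walking outward from the maximum. On linear
  shoulders the interpolation is exact to ~1e-9 mm; in general the error is
  below one diode spacing.
* **Ratios**: same-frame ratios of the designated pair members. Global
  output scaling cancels exactly (to floating-point rounding, ≲1e-12
  relative), which is what decouples geometric QA from output drift.

## Calibration

Ordinary least squares of ratio on applied shift per axis
(`scipy.stats.linregress`; an independent normal-equations oracle lives in
the tests), fitted over all 43 suite deliveries — multi-axis combinations
included, since each axis's ratio responds only to its own shift component.
The fit direction is ratio-on-shift; inversion is analytic in
`predict_shift`, which flags (not fails) estimates outside ±1.5 mm.
Baselines (center/target doses, pair ratios, FWHMs) come from the
zero-shift delivery. The 43-delivery manifest — 1 baseline, 18 single-axis
shifts, 3 documented representative combinations and 21 further
combinations from a balanced Latin hypercube over the ±1.5 mm grid,
generated once with a fixed seed — is shipped as
`src/ringqa/data/validation_suite.csv` and never regenerated at run time.

## Tolerances

The source program states warning thresholds without numeric values, so the
defaults are conventional TG-142-style action levels, fully overridable via
the YAML table: output and target ratios 2% warn / 3% fail; CT–MV offsets
1 / 2 mm; field-size deviation from baseline 2 / 3 mm; laser deviation
1.5 / 2 mm. Status classification is monotone by construction (fail bounds
enclose warn bounds). Display rounding: ratios to 3 decimals, millimetres
to 2.

## Trend monitoring and drift detection

One row per day. Two detectors run on each metric's residuals from a
baseline period (first 45 records; the SD may instead be supplied as a
commissioned process SD):

* **rolling OLS slope** over a 60-day window, alarming at
  |slope| > 0.005%/day with p < 0.001;
* **two-sided tabular CUSUM** with reference value k = 0.5σ and decision
  interval h = 10σ, reset after each alarm.

Both operate on mean-subtracted values and are therefore invariant to
constant offsets. The operating point was set by a design-time simulation
at the package's default output noise (σ = 0.016): ≈0.04 false alarms per
180-day in-control series, ≳97% detection of a +0.01%/day drift within 180
drift days (after a 60-day in-control lead-in — a baseline estimated from
already-drifting data is not a baseline), and a median 6-day CUSUM delay on
a +3% step. Textbook k = 0.5/h = 5 settings were rejected because, with the
baseline mean and SD *estimated* from a finite window, their realized
false-alarm rate is an order of magnitude above the nominal ARL.

## What the synthetic generator does and does not emulate

The year-scenario generator draws daily output, target-ratio, CT–MV and
laser-registration values from the long-run means and SDs of a stable
service year (output 1.006 ± 0.016, targets 1.007 ± 0.005 / 0.996 ± 0.004,
sub-mm CT–MV offsets, lasers scattered ~0.3 mm about their nominals), with
optional injected drifts and steps. It does not emulate: detector
reproducibility drift or setup error beyond these distributions, dose-rate
or temperature dependence, asymmetric field changes, MLC failures, couch
rotations, or any imaging-chain failure mode — a registration shift is an
*input* here, not something computed from images. Passing tests therefore
demonstrate correctness of the analysis chain under the stated statistical
model, not clinical performance of a physical detector.

## Numerical choices and degenerate inputs

* Parabolic apex positions are clipped to the bracketing interval.
* A flat windowed maximum (plateau) falls back to the raw diode sample.
* FWHM requires both crossings inside the ROI, else a named error.
* OLS requires ≥3 samples over ≥2 distinct shifts; an exactly flat ratio
  response is rejected as uninvertible.
* Doses are clipped at zero after noise; measurement files print full
  round-trip precision (`repr`), so write→read is value-exact.
* Problem sizes used in tests and the acceptance script — 43 deliveries,
  223 diodes, 60–240-day trend series, 20-seed batches — are the package's
  working defaults; every simulation completes in seconds on one core.

## Known limitations

* The diode layout, plan peak placement and sensitivity magnitudes are
  plausible stand-ins, not vendor data; real calibrations will have other
  slopes (the pipeline re-fits them from measurements by design).
* The linear ratio–shift model is trusted only to ±1.5 mm and extrapolation
  is flagged, not prevented.
* Only 3D translational offsets are modelled; rotations are out of scope.
* The FWHM definition references the ROI maximum; programs that reference
  the central-axis dose will read slightly different absolute field sizes
  (the *constancy* check against a same-definition baseline is unaffected).
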