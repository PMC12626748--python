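"""Analyze one simulated daily-QA delivery against the shipped calibration.

Simulates a morning delivery whose central dose reads 306.39 cGy (against
the 304.72 cGy commissioning baseline) with a small residual phantom
offset, then prints the full daily report.
"""

import ringqa as rq

plan, geom = rq.default_plan(), rq.default_geometry()
cal = rq.default_bundle()

# today's machine: output up 0.55%, phantom a fraction of a mm off
# (noise-free so the printed numbers show the metrics' arithmetic exactly;
# see example 02 for the noisy case)
params = rq.DeliveryParams(shift=(-0.01, -0.06, 0.24),
                           output_scale=306.39 / 304.72)
frame = rq.simulate_measurement(plan, geom, params)

result = rq.evaluate(frame, cal, registered_shift=(20.18, 14.61, -22.31))
print(result.to_json())

# output_constancy 1.005 -> beam output 0.5% above baseline (well inside the
# 2% warning band); ctmv_offset_mm are the CT-MV isocenter offsets recovered
# from the three dose-peak-ratio models (sub-mm); laser_deviation_mm compares
# the image-registration shift to the nominal (20, 15, -22) mm marker offsets.
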