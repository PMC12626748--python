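{
 "format_version": 1,
 "models": {
  "X": {
   "slope": 0.05000000000000217,
   "intercept": 0.9999999999999704,
   "r2": 0.9999999999999991
  },
  "Y": {
   "slope": -0.07999998964941006,
   "intercept": 0.9999999999718162,
   "r2": 0.9999999999998659
  },
  "Z": {
   "slope": 0.03500027410444926,
   "intercept": 0.9999999212469882,
   "r2": 0.9999999974912597
  }
 },
 "baseline_center_dose": 304.72,
 "baseline_left_dose": 250.0,
 "baseline_right_dose": 250.0,
 "baseline_pair_ratios": {
  "X": 0.9999999999999697,
  "Y": 1.0,
  "Z": 1.0
 },
 "baseline_fwhm_x": 130.0,
 "baseline_fwhm_y": 77.50000008989875,
 "nominal_laser_offsets": [
  20.0,
  15.0,
  -22.0
 ],
 "plan": {
  "peaks": [
   {
    "id": "A",
    "axis": "X",
    "center": 0.0,
    "amplitude": 104.72000000000003,
    "width": 5.0,
    "role": "center_output",
    "sensitivity": [
     0.0,
     0.0,
     0.0
    ]
   },
   {
    "id": "B",
    "axis": "X",
    "center": -140.0,
    "amplitude": 250.0,
    "width": 4.0,
    "role": "left_target",
    "sensitivity": [
     0.0,
     0.0,
     0.0
    ]
   },
   {
    "id": "C",
    "axis": "X",
    "center": 140.0,
    "amplitude": 250.0,
    "width": 4.0,
    "role": "right_target",
    "sensitivity": [
     0.0,
     0.0,
     0.0
    ]
   },
   {
    "id": "D",
    "axis": "X",
    "center": -100.0,
    "amplitude": 240.0,
    "width": 4.0,
    "role": "x_pair_left",
    "sensitivity": [
     0.05,
     0.0,
     0.0
    ]
   },
   {
    "id": "E",
    "axis": "X",
    "center": 100.0,
    "amplitude": 240.0,
    "width": 4.0,
    "role": "x_pair_right",
    "sensitivity": [
     0.0,
     0.0,
     0.0
    ]
   },
   {
    "id": "F",
    "axis": "Y",
    "center": -64.0,
    "amplitude": 220.0,
    "width": 4.0,
    "role": "y_pair_inf",
    "sensitivity": [
     0.0,
     -0.08,
     0.0
    ]
   },
   {
    "id": "G",
    "axis": "Y",
    "center": 64.0,
    "amplitude": 220.0,
    "width": 4.0,
    "role": "y_pair_sup",
    "sensitivity": [
     0.0,
     0.0,
     0.0
    ]
   },
   {
    "id": "H",
    "axis": "Y",
    "center": -88.0,
    "amplitude": 200.0,
    "width": 4.0,
    "role": "z_pair_a",
    "sensitivity": [
     0.0,
     0.0,
     0.035
    ]
   },
   {
    "id": "I",
    "axis": "Y",
    "center": 88.0,
    "amplitude": 200.0,
    "width": 4.0,
    "role": "z_pair_b",
    "sensitivity": [
     0.0,
     0.0,
     0.0
    ]
   }
  ],
  "nominal_field_x": 130.0,
  "nominal_field_y": 77.5,
  "flat_x": {
   "plateau_half_width": 62.618,
   "shoulder": 10.0,
   "plateau_dose": 200.0,
   "roi": [
    -75.0,
    75.0
   ]
  },
  "flat_y": {
   "plateau_half_width": 33.75,
   "shoulder": 10.0,
   "plateau_dose": 300.0,
   "roi": [
    -50.0,
    50.0
   ]
  },
  "search_window": 10.0
 }
}
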