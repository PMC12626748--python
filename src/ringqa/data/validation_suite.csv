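# intentional-shift manifest: 1 baseline + 18 single-axis + 24 multi-axis deliveries
kind,dx_mm,dy_mm,dz_mm
baseline,0,0,0
single,-1.5,0,0
single,-1,0,0
single,-0.5,0,0
single,0.5,0,0
single,1,0,0
single,1.5,0,0
single,0,-1.5,0
single,0,-1,0
single,0,-0.5,0
single,0,0.5,0
single,0,1,0
single,0,1.5,0
single,0,0,-1.5
single,0,0,-1
single,0,0,-0.5
single,0,0,0.5
single,0,0,1
single,0,0,1.5
combo,-0.5,-1.5,-1
combo,-1,-0.5,-0.5
combo,1,1,-1.5
combo,-1.5,1.5,0.5
combo,0.5,0,-1
combo,-1,-1.5,-1
combo,0,-1,1.5
combo,1.5,1,-1.5
combo,0,-0.5,1.5
combo,1.5,-1.5,1
combo,0.5,0,1.5
combo,-1.5,0.5,0
combo,-0.5,-0.5,0
combo,-0.5,-1.5,-1.5
combo,1,-1,-1.5
combo,1,-0.5,0
combo,-1,0.5,1
combo,-1.5,1.5,-0.5
combo,0.5,0,-0.5
combo,1,1,0.5
combo,-0.5,0.5,-1
combo,1.5,-1,-0.5
combo,-1,1.5,1
combo,0,1,0.5
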