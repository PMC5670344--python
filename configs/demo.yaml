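# Small synthetic demo: two groups of six subjects on a three-electrode
# montage, generated directly at the 256 Hz analysis rate, with B = 199
# surrogates.  Runs end to end in well under a minute:
#
#   phaselag run-all --config configs/demo.yaml
input_dir: demo/input
output_dir: demo/output
simulate: true
simulation:
  n_per_group: {case: 6, control: 6}
  channel_labels: [Fz, Cz, Pz]
  eog_labels: [VEOGup, VEOGdown]
  fs_hz: 256.0
  duration_s: 150.0
  lag_rad: [0.0, 0.6283185307179586, 1.2566370614359172]
  eog_propagation: [0.10, 0.07, 0.05]
n_surrogates: 199
seed: 7
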