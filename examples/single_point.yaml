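# Desk-scale single-point imaging run: one unit-RCS target 6 cm from the
# centre at azimuth 180 deg, water-filled 17 cm container.
seed: 1
geometry:
  ring_radius_m: 0.085
  opening_angle_deg: 20.0
sweep:
  f_start_hz: 1.0e+8
  f_stop_hz: 4.8e+9
  n_points: 64
rotation:
  n_positions: 90
medium:
  eps_r: 80.0
  container_radius_m: 0.085
grid:
  n_side: 32
  imaging_radius_m: 0.08
phantom:
  kind: single_point
solver:
  window: hann
output:
  upsample: 321
  n_peaks: 1
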