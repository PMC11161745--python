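# Full-scale zero-field LEM ensemble, random initial states (scenario I).
#
# Three 0.91/0.72 um magnetite grains, X-aligned at a 40 nm gap, 20 nm
# cells, 10 random initial states.  Expected outcome (long run, hours on a
# workstation): ensemble Msc ~ 7.33 fAm^2 with a wide spread
# (+-4.22 fAm^2), Mr/Ms ~ 0.018, chain-axis component dominant in >= 8/10
# repeats, multivortex domain states.
#
#   magnetofossil lem --config configs/full_scale_scenario_I.yaml \
#       --out runs/scenario_I --seed 0
seed: 0
stages:
  geometry: true
  lem: true
  uturn: false
grain:
  long_axis_nm: 910.0
  short_axis_nm: 720.0
  shape: rounded_cuboid
  mineral: magnetite
chain:
  n: 3
  gap_nm: 40.0
  axis: X
grid:
  cell_nm: 20.0
solver:
  tol: 1.0e-6
  max_evals: 200000
scenario:
  which: I
  n_repeats: 10
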