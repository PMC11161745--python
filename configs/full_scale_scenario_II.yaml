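# Full-scale zero-field LEM, uniform chain-axis initial state (scenario II).
# Expected outcome: Msc ~ 6.91 fAm^2 (Mr/Ms ~ 0.017) for the X-aligned
# magnetite chain.
#
#   magnetofossil lem --config configs/full_scale_scenario_II.yaml \
#       --out runs/scenario_II --seed 0
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
  which: II
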