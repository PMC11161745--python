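# Full-scale direction-averaged hysteresis: 20 Fibonacci-lattice field
# directions, -250..250 mT in 2 mT steps, warm-started at every step.
# Expected outcome (overnight): thin-waisted averaged loop with ~2 mT
# coercivity for the X-aligned magnetite chain.
#
#   magnetofossil loop --config configs/full_scale_hysteresis.yaml \
#       --out runs/hysteresis --seed 0
seed: 0
stages:
  geometry: true
  loop: true
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
  tol: 1.0e-5
  max_evals: 50000
protocol:
  n_directions: 20
  B_start_mT: 250.0
  B_end_mT: -250.0
  B_step_mT: 2.0
  start_state: saturated
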