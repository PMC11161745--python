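# 20-step growth series: the whole 3-grain system scaled from 86 nm to
# 823 nm grain long axes (gaps scaled proportionally), each step
# warm-started from the previous converged state, cell size graded from
# 9 nm to 20 nm.  Expected outcome: SD -> SV -> MV with multivortex
# nucleation above ~500 nm.
#
#   magnetofossil growth --config configs/growth_series.yaml \
#       --out runs/growth --seed 0
seed: 0
stages:
  growth: true
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
solver:
  tol: 1.0e-5
  max_evals: 50000
growth:
  n_steps: 20
  min_long_axis_nm: 86.0
  max_long_axis_nm: 823.0
  proportional_gap: true
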