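# Energy barrier between a full-size single grain's state and its
# 180-degree mirror, on a 16 nm grid, followed by the Néel relaxation
# time.  Expected outcome: a barrier of many thousands of kT — relaxation
# times far beyond the age of the Solar System.
#
#   magnetofossil barrier --config configs/full_scale_barrier.yaml \
#       --out runs/barrier --seed 0
seed: 0
stages:
  barrier: true
  uturn: false
grain:
  long_axis_nm: 910.0
  short_axis_nm: 720.0
  shape: rounded_cuboid
  mineral: magnetite
grid:
  cell_nm: 16.0
solver:
  tol: 1.0e-6
  max_evals: 200000
barrier:
  n_images: 15
  rotation_axis: Z
  neb_tol: 1.0e-3
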