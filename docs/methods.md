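# Methods

## The physical model

The package treats a giant magnetofossil chain at two scales.

**Grain scale.** Each grain is a continuum ferrimagnet whose state is a
unit magnetization direction field **m**(r).  The energy functional
contains four terms:

* exchange, `A |∇m|²`, with A = 1.33×10⁻¹¹ J/m (magnetite) or
  1.00×10⁻¹¹ J/m (maghemite);
* cubic magnetocrystalline anisotropy,
  `K₁ (mx²my² + my²mz² + mz²mx²)`, with K₁ = −1.24×10⁴ J/m³ (magnetite)
  and −4.60×10³ J/m³ (maghemite) — negative K₁ makes the ⟨111⟩ body
  diagonals easy;
* magnetostatic self-energy, `−(μ₀/2) Ms m·H_d`, with
  Ms = 4.8×10⁵ / 3.8×10⁵ A/m;
* Zeeman energy `−Ms m·B` for an applied field B (tesla).

A converged minimizer state is a *local energy minimum* (LEM); which LEM
is reached depends on the initial state, which is the modelling handle for
different biomineralization histories: independent nucleation of each
grain (random initial spins, "scenario I", run as a 10-member seeded
ensemble) versus growth of an already-aligned chain (uniform initial state
along the chain axis, "scenario II").

**Organism scale.** A chain of N grains inside a prolate cell of full
length a and width b behaves as a compass needle with moment
`Mn = Msc3/3 · N`, where Msc3 is the rescaled moment `M·Ms·V` of the
simulated three-grain chain.  Thermal rotation competes with the magnetic
torque through the Langevin argument `x = Mn·B/kBT`; the average
alignment is `coth x − 1/x` and the 180°-reorientation (U-turn) time is
`τ = A/(Mn·B)·ln(2x)` with the prolate-body rotational drag coefficient
`A = (16/3)πηc³/|½ln((a+c)/(a−c)) − ac/b²|`, `c = √(a²−b²)`.

Two readings of the drag formula are possible and only one reproduces the
model chain's own worked numbers: a and b are *full* axes (not
semi-axes), and the bracket — which is negative for every a > b — enters
through its absolute value (drag must be positive).  Both choices are
validated by direct evaluation: with Msc3 = 7.33 fAm², N = 12, b = 2 µm,
η = 10⁻³ N·s·m⁻², T = 293.15 K and B = 6 µT they give A = 8.41×10⁻¹⁹
N·m·s and τ = 21.3 s, matching the reference worked example.  The N↔a
mapping is one grain per micrometre of body length (N = 12 → a = 12 µm).

## Discretization and the demagnetizing field

Grains are voxelized on a regular cubic grid (cells inside the analytic
surface by centre test).  The default grain shape is a superellipsoid
`|x/A|^p + |y/B|^p + |z/C|^p ≤ 1` with exponent p = 2.3, chosen once so
that the default 0.91/0.72 µm grain has a volume of ≈0.28 µm³ — about 60%
of its bounding cuboid, which is what the segmented tomographic particle
occupies; a pure ellipsoid (0.247 µm³) or the full cuboid (0.47 µm³)
would bias every absolute moment.  Magnetite geometries are shrunk
isotropically to 90% of the nominal (maghemite) volume, reflecting the
≈10% volume change of the maghemite↔magnetite transformation.

The demagnetizing field is the discrete convolution of the magnetization
with the exact cell-averaged demagnetizing tensor of rectangular cells
(the Newell f/g second-difference formulas), evaluated with zero-padded
real FFTs.  This reproduces the cube self-term N = 1/3 exactly, the
uniformly magnetized cube/sphere energy (1/6)μ₀Ms²V to better than
1%/3%, and the point-dipole interaction at 10-cell distance to 0.4%.
Exchange uses 6-neighbour bonds between occupied cells (free boundaries);
anisotropy axes are grid-aligned (the crystallographic orientation of the
segmented grain is unknown; grid alignment is consistent with vortex
structures along [111] and is configurable in principle through the grain
shape).  The anisotropy energy is gauged to its per-cell minimum (K₁/3
for K₁ < 0) so all reported terms except Zeeman are non-negative.

Cell sizes: 20 nm for full-size (µm) grains — a deliberate compromise
above the 9 nm magnetite exchange length that keeps three-grain chains
tractable and is known to slightly *underestimate* moments of strongly
inhomogeneous states, i.e. it is conservative for magnetotaxis claims —
grading down to 9 nm for the smallest growth-series steps.  Chain gaps
are rounded to whole cells, with sub-cell proportional gaps realized as
one cell so grains never merge; realized gaps are recorded in run
manifests.

## Minimization

States are parametrized by unconstrained per-cell 3-vectors σ with
m = σ/|σ| and relaxed by L-BFGS-B on the nondimensionalized energy
(units of μ₀Ms²V_cell), with analytic gradients projected onto the sphere
tangent space.  Because σ norms drift, the optimizer is restarted from the
renormalized state until the true residual — the maximum per-cell
projected-gradient norm over μ₀Ms²V_cell — falls below tolerance
(default 10⁻⁷; non-convergence is flagged on the result, never silent).

Hysteresis and acquisition branches use a different mode: monotone
projected gradient descent with a 0.05 rad per-cell step cap
(`minimize_tracked`).  Quasi-Newton steps can hop the shallow barrier of
an about-to-vanish minimum near a switching field, which would
systematically bias coercivities low; capped descent follows the local
basin until it actually disappears, which is what a zero-temperature
hysteresis branch means.  On a single-cell macrospin this reproduces the
brute-force basin-tracking switching field to the 2 mT field step.

## Vortex cores and domain-state classification

The vorticity ω = ∇×m is computed with central differences inside the
magnetic region and one-sided differences at its boundary; the
normalized helicity H = m·ω/‖ω‖ is set to zero where ‖ω‖ is negligible
(≤10⁻⁶ of the maximum), which makes uniform states helicity-free by
convention.

A vortex core is detected as a connected filament of cells (≥3 cells in
count and extent) where the magnetization is aligned with the curl
(|H| ≥ 0.3) *and* the curl is concentrated (‖ω‖·Δx ≥ 0.25 rad/cell).
Both gates matter: in a relaxed vortex state |H| ≥ 0.3 alone covers much
of the grain plus detached noise specks, so a bare helicity threshold
cannot isolate cores.  Right- and left-handed cores (H > 0 / H < 0) are
counted as separate components because adjacent vortices of a multivortex
state have opposite handedness even where their high-|H| envelopes touch.
Grains are classified independently — 0 cores → SD (requiring mean
|⟨m⟩| > 0.8, otherwise flagged ambiguous), 1 → SV, ≥2 → MV — and an
assembly inherits the label of its most complex grain, so a chain of
single-vortex grains is SV, not MV.  All thresholds are keyword
parameters with these defaults.

On the growth series this classifier yields: uniform SD at 86 nm, one
core per grain from ~150 nm, and small opposite-handed satellite cores
nucleating beside the dominant core from the mid-500 nm steps upward,
with the dominant core still two orders of magnitude larger at 823 nm —
a multivortex state whose structure remains dominated by one large
vortex, matching the expected SD → SV → MV progression with MV
nucleation above ~520 nm.

## Energy barriers and relaxation

Opposite domain states are generated by rotating a converged state 180°
about an axis perpendicular to the chain/long axis (geometry-preserving
flip of positions and vector components); cells left unassigned by shape
asymmetry are filled with seeded random spins and re-minimized.  The
minimum-energy path between the two LEMs uses a nudged elastic band with
per-cell geodesic (slerp) initialization, improved-tangent projection,
spring forces scaled to the mean inter-image distance, FIRE relaxation on
the sphere, and a climbing image once the path is roughly converged
(default 15 images).  If the profile crosses interior metastable dips,
the band is re-run between the two minima flanking the dominant saddle
("refined" path), so the reported barrier E_m is the rate-limiting one.
On a single-cell toy the band recovers the analytic cubic saddle
|K₁|V/12 between adjacent ⟨111⟩ wells to better than 0.1%.

Relaxation times follow the Arrhenius/Néel law τ = C·exp(E_m/kBT) with
C = 10⁻⁹ s, kB = 1.3806×10⁻²³ J/K, T = 293.15 K; barriers beyond the
float range return +inf (blocked on any timescale).  Even an 86 nm SD
grain carries a barrier of hundreds of kBT, i.e. geological stability;
full-size grains are further beyond by orders of magnitude.

## What the synthetic data does and does not emulate

The generator reproduces the *idealized* study system: identical
superellipsoid grains, perfectly linear chains, uniform gaps, grid-aligned
crystal axes.  Real magnetofossil chains have irregular grain shapes,
misalignments, size dispersion and collapsed configurations; passing
tests therefore demonstrate correctness of the model chain on the
idealized geometry, not insensitivity to morphological disorder.  The
three-grain moments used by the organism model are ensemble
results of the full-scale micromagnetic runs; the desk-scale suite
verifies the machinery that produces them on reduced systems and ships
the exact full-scale configurations (`configs/`) for the overnight
reproductions (ensemble Msc ≈ 7.33 fAm², Mr/Ms ≈ 0.018, ≈2 mT averaged
coercivity).

## Problem sizes and numerical defaults

* Growth series (tests and acceptance script): 12 steps, 86 → 823 nm,
  cell size graded 9 → 20 nm (up to ~70 000 occupied cells at the largest
  step), LEM tolerance 10⁻⁵, ≤20 000 evaluations per step, first step
  uniform along the chain axis, subsequent steps warm-started by
  nearest-neighbour rescaling of the previous state.  The reported
  MV-onset size has the granularity of the series step (~67 nm).
* Scaled surrogate chains in tests: 150–500 nm grains with
  proportionally scaled gaps.  The chain-axis preference of the
  random-init ensemble strengthens with grain size (4/10 repeats at
  150 nm, 7/10 at 500 nm); the ≥8/10 full-scale property is part of the
  scenario-I configuration.
* Hysteresis tests: a 48 nm cube at 6 nm cells against a brute-force
  single-spin basin-tracking oracle; finite-cube incoherence lowers the
  switching field ~8% below the macrospin value.
* NEB: 11–15 images, force tolerance 10⁻⁴–10⁻⁶ (dimensionless, same
  normalization as the LEM residual).

## Known limitations

* The regular-grid solver differs from tetrahedral finite elements:
  domain-state transition sizes can shift by a few percent to tens of
  nanometres, staircase boundaries add artificial surface roughness, and
  20 nm cells under-resolve the exchange length for the largest grains.
* Vortex-core counting near the SV→MV boundary is sensitive to the
  (documented) detector thresholds; satellite cores a few cells long are
  at the resolution limit.
* The organism model is a rigid prolate body in Stokes flow: no
  flagellar propulsion, no chain flexibility, no hydrodynamic wall
  effects.
* Material constants are ambient-temperature values; no temperature
  dependence, magnetoelasticity, or surface anisotropy.
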