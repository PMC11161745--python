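"""Local-energy-minimum (LEM) micromagnetics on voxel assemblies.

Energy functional (SI units, J) over the occupied cells of a
:class:`~magnetofossil.geometry.VoxelAssembly`:

* exchange      E_ex  = A * dx * sum_<ij> |m_i - m_j|^2   (6-neighbour bonds)
* anisotropy    E_an  = sum_i [K1 (mx^2 my^2 + my^2 mz^2 + mz^2 mx^2) - e_min] Vc
* magnetostatic E_d   = -(mu0/2) sum_i Ms m_i . H_d,i Vc
* Zeeman        E_z   = -sum_i Ms m_i . B Vc              (B applied, in T)

The anisotropy is gauged to its per-cell minimum (K1/3 for K1 < 0, i.e.
easy <111>), so every term is non-negative except Zeeman.  Cubic anisotropy
axes are the grid axes.

Minimization runs L-BFGS-B on an unconstrained per-cell 3-vector sigma with
m = sigma/|sigma|; the reported residual is the maximum projected gradient
per cell normalized by mu0 Ms^2 Vc (dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize as _scipy_minimize

from .demag import DemagKernel
from .geometry import VoxelAssembly
from .materials import MU0, Material

__all__ = [
    "MagnetizationField",
    "EnergyBreakdown",
    "LEMResult",
    "LEMSolver",
    "total_energy",
    "demag_field",
    "minimize_lem",
    "run_scenario",
    "grow_chain_states",
    "random_field",
    "uniform_field",
]

_AXIS_VECS = {"X": np.array([1.0, 0, 0]), "Y": np.array([0, 1.0, 0]),
              "Z": np.array([0, 0, 1.0])}


@dataclass
class MagnetizationField:
    """Unit magnetization direction per occupied cell.

    ``m`` has shape (n_occupied, 3) in the order of ``np.argwhere`` on the
    assembly occupancy (C order).  ``as_grid()`` scatters to the full grid
    with zeros outside the magnetic region.
    """

    assembly: VoxelAssembly
    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (self.assembly.n_cells, 3):
            raise ValueError(
                f"m has shape {self.m.shape}, expected "
                f"({self.assembly.n_cells}, 3)"
            )

    def normalize(self) -> "MagnetizationField":
        self.m /= np.linalg.norm(self.m, axis=1, keepdims=True)
        return self

    def copy(self) -> "MagnetizationField":
        return MagnetizationField(self.assembly, self.m.copy())

    def as_grid(self) -> np.ndarray:
        grid = np.zeros(self.assembly.shape + (3,))
        grid[self.assembly.occupancy] = self.m
        return grid

    @property
    def mean_m(self) -> np.ndarray:
        """Volume-weighted mean magnetization vector (cells are equal-volume)."""
        return self.m.mean(axis=0)

    @property
    def M(self) -> float:
        """Norm of the mean magnetization — the remanence ratio Mr/Ms."""
        return float(np.linalg.norm(self.mean_m))


def uniform_field(assembly: VoxelAssembly, direction) -> MagnetizationField:
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    m = np.tile(d / n, (assembly.n_cells, 1))
    return MagnetizationField(assembly, m)


def random_field(assembly: VoxelAssembly, seed) -> MagnetizationField:
    """Per-cell isotropic random unit vectors from a seeded generator."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(assembly.n_cells, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return MagnetizationField(assembly, v)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy terms in joules; ``total`` is their sum."""

    exchange: float
    anisotropy: float
    demag: float
    zeeman: float

    @property
    def total(self) -> float:
        return self.exchange + self.anisotropy + self.demag + self.zeeman

    def as_dict(self) -> dict:
        return {
            "exchange_J": self.exchange,
            "anisotropy_J": self.anisotropy,
            "demag_J": self.demag,
            "zeeman_J": self.zeeman,
            "total_J": self.total,
        }


@dataclass
class LEMResult:
    """A converged (or flagged) local energy minimum."""

    field: MagnetizationField
    energies: EnergyBreakdown
    material: Material
    init_mode: str
    seed: int | None = None
    iterations: int = 0
    n_evaluations: int = 0
    converged: bool = True
    residual: float = np.nan
    initial_energy: float = np.nan

    @property
    def mean_m(self) -> np.ndarray:
        return self.field.mean_m

    @property
    def M(self) -> float:
        return self.field.M

    @property
    def Mr_over_Ms(self) -> float:
        return self.M

    @property
    def Msc(self) -> float:
        """Rescaled moment M * Ms * V in A m^2."""
        return self.M * self.material.Ms * self.field.assembly.V

    def axis_moments(self) -> np.ndarray:
        """Per-axis rescaled moments (|mean mx|, |mean my|, |mean mz|)*Ms*V."""
        return np.abs(self.mean_m) * self.material.Ms * self.field.assembly.V


class LEMSolver:
    """Caches the demag kernel and exchange bonds for one assembly/material."""

    def __init__(self, assembly: VoxelAssembly, material: Material):
        if assembly.n_cells == 0:
            raise ValueError("assembly has no occupied cells")
        self.assembly = assembly
        self.material = material
        self.kernel = DemagKernel(assembly.shape, assembly.cell_size)
        self._index_grid = np.full(assembly.shape, -1, dtype=np.int64)
        self._index_grid[assembly.occupancy] = np.arange(assembly.n_cells)
        self._bonds = self._build_bonds()
        self._occ = assembly.occupancy

    def _build_bonds(self) -> np.ndarray:
        """(n_bonds, 2) occupied-cell index pairs for 6-neighbour bonds."""
        idx = self._index_grid
        pairs = []
        for ax in range(3):
            a = np.moveaxis(idx, ax, 0)[:-1].reshape(-1)
            b = np.moveaxis(idx, ax, 0)[1:].reshape(-1)
            ok = (a >= 0) & (b >= 0)
            pairs.append(np.stack([a[ok], b[ok]], axis=1))
        if not pairs:
            return np.zeros((0, 2), dtype=np.int64)
        return np.concatenate(pairs, axis=0)

    # -- energy terms -----------------------------------------------------

    def demag_field(self, m: np.ndarray) -> np.ndarray:
        """H_d (A/m) at the occupied cells for unit magnetization m."""
        grid = np.zeros(self.assembly.shape + (3,))
        grid[self._occ] = m * self.material.Ms
        H = self.kernel.field(grid)
        return H[self._occ]

    def energy_terms(self, m: np.ndarray, applied_B=None) -> EnergyBreakdown:
        e_ex, g = self._exchange(m, want_grad=False)
        e_an, _ = self._anisotropy(m, want_grad=False)
        Hd = self.demag_field(m)
        Vc = self.assembly.cell_volume
        e_d = -0.5 * MU0 * self.material.Ms * float(np.sum(m * Hd)) * Vc
        e_z = 0.0
        if applied_B is not None:
            B = np.asarray(applied_B, dtype=float)
            e_z = -self.material.Ms * float(np.sum(m @ B)) * Vc
        return EnergyBreakdown(e_ex, e_an, e_d, e_z)

    def _exchange(self, m, want_grad=True):
        A = self.material.Aex
        dx = self.assembly.cell_size
        i, j = self._bonds[:, 0], self._bonds[:, 1]
        diff = m[i] - m[j]
        e = A * dx * float(np.sum(diff * diff))
        g = None
        if want_grad:
            g = np.zeros_like(m)
            np.add.at(g, i, 2.0 * A * dx * diff)
            np.add.at(g, j, -2.0 * A * dx * diff)
        return e, g

    def _anisotropy(self, m, want_grad=True):
        K1 = self.material.K1
        Vc = self.assembly.cell_volume
        sq = m * m
        cross = sq[:, 0] * sq[:, 1] + sq[:, 1] * sq[:, 2] + sq[:, 2] * sq[:, 0]
        e_min = K1 / 3.0 if K1 < 0 else 0.0
        e = float(np.sum(K1 * cross - e_min)) * Vc
        g = None
        if want_grad:
            other = np.empty_like(m)
            other[:, 0] = sq[:, 1] + sq[:, 2]
            other[:, 1] = sq[:, 0] + sq[:, 2]
            other[:, 2] = sq[:, 0] + sq[:, 1]
            g = 2.0 * K1 * Vc * m * other
        return e, g

    def energy_and_grad(self, m: np.ndarray, applied_B=None):
        """Total energy (J) and gradient dE/dm, shape (n, 3)."""
        Vc = self.assembly.cell_volume
        Ms = self.material.Ms
        e_ex, g_ex = self._exchange(m)
        e_an, g_an = self._anisotropy(m)
        Hd = self.demag_field(m)
        e_d = -0.5 * MU0 * Ms * float(np.sum(m * Hd)) * Vc
        g_d = -MU0 * Ms * Hd * Vc
        g = g_ex + g_an + g_d
        e = e_ex + e_an + e_d
        if applied_B is not None:
            B = np.asarray(applied_B, dtype=float)
            e += -Ms * float(np.sum(m @ B)) * Vc
            g += -Ms * Vc * B[None, :]
        return e, g

    def residual(self, m: np.ndarray, applied_B=None) -> float:
        """Max per-cell projected-gradient norm / (mu0 Ms^2 Vc)."""
        _, g = self.energy_and_grad(m, applied_B)
        g_perp = g - np.sum(g * m, axis=1, keepdims=True) * m
        scale = MU0 * self.material.Ms**2 * self.assembly.cell_volume
        return float(np.max(np.linalg.norm(g_perp, axis=1))) / scale

    # -- minimization -----------------------------------------------------

    def minimize_tracked(
        self,
        init: MagnetizationField,
        applied_B=None,
        tol: float = 1e-5,
        max_evals: int = 20_000,
        step_cap: float = 0.05,
        init_mode: str = "given",
    ) -> LEMResult:
        """Basin-tracking relaxation for warm-started field sweeps.

        Monotone projected gradient descent with a per-cell step cap
        (radians), so the state follows its local minimum as the field
        changes and cannot hop a still-existing barrier the way a
        quasi-Newton step can.  Switching then happens only when the basin
        actually disappears, which is what a zero-temperature hysteresis
        branch means.
        """
        scale = MU0 * self.material.Ms**2 * self.assembly.cell_volume
        m = init.m.copy()
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        e0 = self.energy_terms(init.m, applied_B).total
        lr = 0.01
        nev = 0
        resid = np.inf
        e, g = self.energy_and_grad(m, applied_B)
        nev += 1
        while nev < max_evals:
            gp = g - np.sum(g * m, axis=1, keepdims=True) * m
            resid = float(np.max(np.linalg.norm(gp, axis=1))) / scale
            if resid <= tol:
                break
            dm = -(lr / scale) * gp
            sn = np.linalg.norm(dm, axis=1, keepdims=True)
            dm *= np.clip(step_cap / np.maximum(sn, 1e-30), None, 1.0)
            trial = m + dm
            trial /= np.linalg.norm(trial, axis=1, keepdims=True)
            e2, g2 = self.energy_and_grad(trial, applied_B)
            nev += 1
            if e2 <= e:
                m, e, g = trial, e2, g2
                lr = min(lr * 1.5, 10.0)
            else:
                lr *= 0.5
        fld = MagnetizationField(self.assembly, m)
        return LEMResult(
            field=fld,
            energies=self.energy_terms(m, applied_B),
            material=self.material,
            init_mode=init_mode,
            iterations=nev,
            n_evaluations=nev,
            converged=bool(resid <= tol),
            residual=resid,
            initial_energy=e0,
        )

    def minimize(
        self,
        init: MagnetizationField,
        applied_B=None,
        tol: float = 1e-7,
        max_evals: int = 100_000,
        init_mode: str = "given",
        seed: int | None = None,
    ) -> LEMResult:
        """Relax ``init`` to a local energy minimum.

        ``tol`` is the dimensionless per-cell normalized projected-gradient
        tolerance; non-convergence within ``max_evals`` energy evaluations
        is flagged on the result, never silent.
        """
        n = self.assembly.n_cells
        # Nondimensionalize by the magnetostatic energy of one cell so the
        # objective and gradient are O(1) for the line search.
        scale = MU0 * self.material.Ms**2 * self.assembly.cell_volume
        e0 = self.energy_terms(init.m, applied_B).total

        nev = 0

        def fun(x):
            nonlocal nev
            nev += 1
            sigma = x.reshape(n, 3)
            norms = np.linalg.norm(sigma, axis=1, keepdims=True)
            m = sigma / norms
            e, g = self.energy_and_grad(m, applied_B)
            g_perp = g - np.sum(g * m, axis=1, keepdims=True) * m
            return e / scale, (g_perp / norms).ravel() / scale

        # Restart rounds: the sigma norms drift during L-BFGS-B, which makes
        # its internal projected gradient stale; renormalizing and
        # restarting recovers the true residual cheaply.
        x = init.m.astype(float).ravel().copy()
        nit = 0
        resid = np.inf
        for _ in range(8):
            remaining = max_evals - nev
            if remaining <= 0:
                break
            res = _scipy_minimize(
                fun,
                x,
                jac=True,
                method="L-BFGS-B",
                options={
                    "maxfun": remaining,
                    "maxiter": remaining,
                    "ftol": 1e-16,
                    "gtol": 0.5 * tol,
                    "maxcor": 12,
                },
            )
            nit += int(res.nit)
            m = res.x.reshape(n, 3)
            m /= np.linalg.norm(m, axis=1, keepdims=True)
            resid = self.residual(m, applied_B)
            x = m.ravel().copy()
            if resid <= tol or res.nit == 0:
                break
        fld = MagnetizationField(self.assembly, m)
        energies = self.energy_terms(m, applied_B)
        return LEMResult(
            field=fld,
            energies=energies,
            material=self.material,
            init_mode=init_mode,
            seed=seed,
            iterations=nit,
            n_evaluations=nev,
            converged=bool(resid <= tol),
            residual=resid,
            initial_energy=e0,
        )


# -- module-level convenience wrappers ------------------------------------


def total_energy(
    field: MagnetizationField,
    material: Material,
    applied_B=None,
    solver: LEMSolver | None = None,
) -> EnergyBreakdown:
    """Energy breakdown of a magnetization state (J)."""
    solver = solver or LEMSolver(field.assembly, material)
    return solver.energy_terms(field.m, applied_B)


def demag_field(
    field: MagnetizationField,
    material: Material,
    solver: LEMSolver | None = None,
) -> np.ndarray:
    """Demagnetizing field H_d (A/m) at the occupied cells."""
    solver = solver or LEMSolver(field.assembly, material)
    return solver.demag_field(field.m)


def minimize_lem(
    assembly: VoxelAssembly,
    material: Material,
    init: Literal["random", "uniform"] | MagnetizationField = "random",
    applied_B=None,
    seed: int | None = None,
    tol: float = 1e-7,
    max_evals: int = 100_000,
    direction=None,
    solver: LEMSolver | None = None,
) -> LEMResult:
    """Find a LEM from a random, uniform, or given initial state."""
    solver = solver or LEMSolver(assembly, material)
    if isinstance(init, MagnetizationField):
        fld, mode = init, "given"
    elif init == "random":
        if seed is None:
            raise ValueError("random init requires a seed")
        fld, mode = random_field(assembly, seed), f"random(seed={seed})"
    elif init == "uniform":
        if direction is None:
            direction = _AXIS_VECS.get(assembly.chain_axis or "X")
        fld = uniform_field(assembly, direction)
        mode = "uniform"
    else:
        raise ValueError(f"unknown init {init!r}")
    return solver.minimize(
        fld, applied_B=applied_B, tol=tol, max_evals=max_evals,
        init_mode=mode, seed=seed,
    )


@dataclass
class ScenarioSummary:
    results: list
    Msc_mean: float
    Msc_sd: float
    Mr_over_Ms_mean: float
    Mr_over_Ms_sd: float
    seeds: list


def run_scenario(
    assembly: VoxelAssembly,
    material: Material,
    scenario: Literal["I", "II"],
    n_repeats: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_evals: int = 100_000,
) -> ScenarioSummary:
    """Zero-field LEM ensembles.

    Scenario I runs ``n_repeats`` random initial states (independent
    biomineralization of each region); scenario II a single uniform initial
    state along the chain axis (growth in place from an aligned nucleus).
    """
    solver = LEMSolver(assembly, material)
    results: list[LEMResult] = []
    seeds: list[int | None] = []
    if scenario == "I":
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                       ss.spawn(n_repeats)]
        for s in child_seeds:
            results.append(
                minimize_lem(assembly, material, init="random", seed=s,
                             tol=tol, max_evals=max_evals, solver=solver)
            )
            seeds.append(s)
    elif scenario == "II":
        results.append(
            minimize_lem(assembly, material, init="uniform",
                         tol=tol, max_evals=max_evals, solver=solver)
        )
        seeds.append(None)
    else:
        raise ValueError("scenario must be 'I' or 'II'")
    msc = np.array([r.Msc for r in results])
    mr = np.array([r.Mr_over_Ms for r in results])
    ddof = 1 if len(results) > 1 else 0
    return ScenarioSummary(
        results=results,
        Msc_mean=float(msc.mean()),
        Msc_sd=float(msc.std(ddof=ddof)),
        Mr_over_Ms_mean=float(mr.mean()),
        Mr_over_Ms_sd=float(mr.std(ddof=ddof)),
        seeds=seeds,
    )


def _transfer_state(
    prev: MagnetizationField, new_assembly: VoxelAssembly
) -> MagnetizationField:
    """Nearest-neighbour rescaling of a converged state onto a scaled copy."""
    old = prev.assembly
    grid = prev.as_grid()
    # Fill unoccupied old cells with the nearest occupied value so that
    # shape mismatches at the voxelized boundary inherit sane directions.
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~old.occupancy, return_indices=True
    )
    filled = grid[ix, iy, iz]
    new_idx = np.argwhere(new_assembly.occupancy)
    frac = new_idx / (np.array(new_assembly.shape) - 1).clip(min=1)
    old_idx = np.rint(frac * (np.array(old.shape) - 1)).astype(int)
    m = filled[old_idx[:, 0], old_idx[:, 1], old_idx[:, 2]]
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return MagnetizationField(new_assembly, m / norms).normalize()


def grow_chain_states(
    series: list[VoxelAssembly],
    material: Material,
    tol: float = 1e-7,
    max_evals: int = 100_000,
    classify=None,
) -> list[LEMResult]:
    """LEM states along a growth series, each warm-started from the last.

    The first (smallest) step starts uniform along the chain axis; each
    subsequent step starts from the previous converged state rescaled onto
    the new grid.  When ``classify`` (a callable on MagnetizationField) is
    given, its label is stored in ``result.domain_state``.
    """
    results: list[LEMResult] = []
    prev: MagnetizationField | None = None
    for asm in series:
        if prev is None:
            init: Literal["uniform"] | MagnetizationField = "uniform"
            res = minimize_lem(asm, material, init="uniform",
                               tol=tol, max_evals=max_evals)
        else:
            res = minimize_lem(asm, material, init=_transfer_state(prev, asm),
                               tol=tol, max_evals=max_evals)
        if classify is not None:
            res.domain_state = classify(res.field)  # type: ignore[attr-defined]
        results.append(res)
        prev = res.field
    return results
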