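"""Minimum-energy paths between opposite domain states and Néel relaxation.

A converged state and its 180-degree-rotated mirror are connected with a
nudged-elastic-band (NEB) path: a chain of intermediate magnetization
images relaxed perpendicular to the path with spring coupling along it
(improved-tangent formulation, optional climbing image).  The barrier Em is
the maximum path energy above the lower endpoint, and the Néel relaxation
time follows the Arrhenius law

    tau = C * exp(Em / (kB * T)),   C = 1e-9 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LEMSolver, MagnetizationField, random_field
from .materials import KB, MU0, T_AMBIENT

__all__ = [
    "EnergyPath",
    "RelaxationModel",
    "mirrored_state",
    "neb_path",
    "refine_between_minima",
    "relaxation_time",
]

_PERP_AXES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


def mirrored_state(
    state: MagnetizationField, axis: str = "Z", seed: int = 0
) -> MagnetizationField:
    """180-degree rotation of the vector field about a grid axis.

    Rotating about Z maps position (x, y, z) -> (-x, -y, z) and vector
    (mx, my, mz) -> (-mx, -my, mz); with the default axis perpendicular to
    the chain this sends +chain-axis states to -chain-axis states.  Cells
    of an irregular (rotation-asymmetric) shape that receive no vector are
    filled with seeded random unit moments; callers should re-minimize.
    """
    ax = _AXIS_INDEX[axis.upper()]
    p, q = _PERP_AXES[ax]
    grid = state.as_grid()
    rot = np.flip(np.flip(grid, axis=p), axis=q).copy()
    rot[..., p] *= -1.0
    rot[..., q] *= -1.0
    asm = state.assembly
    m = rot[asm.occupancy]
    norms = np.linalg.norm(m, axis=1)
    missing = norms < 0.5
    if missing.any():
        fill = random_field(asm, seed).m
        m[missing] = fill[missing]
    return MagnetizationField(asm, m).normalize()


@dataclass
class EnergyPath:
    """An ordered chain of magnetization images with their energies."""

    images: list
    energies: np.ndarray        # J, one per image
    converged: bool = True
    refined: bool = False

    @property
    def path_index(self) -> np.ndarray:
        """Normalized 0-100 coordinate along the path."""
        n = len(self.images)
        return np.linspace(0.0, 100.0, n)

    @property
    def Em(self) -> float:
        """Barrier height above the lower-energy endpoint (J), >= 0."""
        lower = min(self.energies[0], self.energies[-1])
        return float(max(self.energies.max() - lower, 0.0))

    def interior_minima(self) -> list[int]:
        """Indices of interior images lower than both neighbours."""
        e = self.energies
        return [
            i
            for i in range(1, len(e) - 1)
            if e[i] < e[i - 1] and e[i] < e[i + 1]
        ]


def _slerp_path(mA: np.ndarray, mB: np.ndarray, n_images: int) -> list[np.ndarray]:
    """Per-cell geodesic interpolation between two unit-vector fields.

    Antipodal cells (undefined geodesic) are routed through a deterministic
    perpendicular direction.
    """
    dot = np.clip(np.sum(mA * mB, axis=1), -1.0, 1.0)
    omega = np.arccos(dot)
    anti = omega > np.pi - 1e-6
    # perpendicular helper for antipodal cells: pick the coordinate axis
    # least aligned with mA and orthogonalize
    if anti.any():
        a = mA[anti]
        pick = np.argmin(np.abs(a), axis=1)
        e = np.zeros_like(a)
        e[np.arange(len(a)), pick] = 1.0
        e -= a * np.sum(e * a, axis=1, keepdims=True)
        e /= np.linalg.norm(e, axis=1, keepdims=True)
    ts = np.linspace(0.0, 1.0, n_images)
    path = []
    sin_om = np.sin(omega)
    safe = sin_om > 1e-9
    for t in ts:
        m = (1 - t) * mA + t * mB  # fallback: nearly parallel cells
        w1 = np.where(safe, np.sin((1 - t) * omega) / np.where(safe, sin_om, 1), 1 - t)
        w2 = np.where(safe, np.sin(t * omega) / np.where(safe, sin_om, 1), t)
        m = w1[:, None] * mA + w2[:, None] * mB
        if anti.any():
            # great circle through the perpendicular helper
            th = t * np.pi
            m[anti] = np.cos(th)[..., None] * mA[anti] + np.sin(th)[..., None] * e
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        path.append(m)
    return path


def neb_path(
    endA: MagnetizationField,
    endB: MagnetizationField,
    solver: LEMSolver,
    n_images: int = 15,
    spring: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 4000,
    climb: bool = True,
) -> EnergyPath:
    """Relax a nudged-elastic-band path between two converged LEM states.

    ``tol`` is the dimensionless per-cell NEB-force tolerance (normalized
    by mu0 Ms^2 Vc, as in the LEM solver); ``spring`` defaults to the
    energy scale divided by the mean inter-image distance.  The highest
    image switches to climbing mode once the path is roughly converged.
    Non-convergence is flagged on the result.
    """
    scale = MU0 * solver.material.Ms**2 * solver.assembly.cell_volume
    mA, mB = endA.m, endB.m
    n = mA.shape[0]
    path = _slerp_path(mA, mB, n_images)

    def e_and_g(m):
        e, g = solver.energy_and_grad(m)
        gp = g - np.sum(g * m, axis=1, keepdims=True) * m
        return e / scale, gp / scale

    # FIRE relaxation of the movable images
    dt, dt_max = 0.05, 0.5
    alpha0, f_alpha, f_inc, f_dec, n_min = 0.1, 0.99, 1.1, 0.5, 5
    alpha = alpha0
    n_good = 0
    v = [np.zeros_like(mA) for _ in range(n_images)]
    climbing_on = False
    climb_idx = -1
    converged = False

    energies = np.empty(n_images)
    grads = [None] * n_images
    for it in range(max_iter):
        for i in range(n_images):
            energies[i], grads[i] = e_and_g(path[i])
        if spring is None:
            dists = [
                np.linalg.norm(path[i + 1] - path[i])
                for i in range(n_images - 1)
            ]
            k_spring = 1.0 / max(float(np.mean(dists)), 1e-12)
        else:
            k_spring = spring

        jmax = int(np.argmax(energies))
        fmax = 0.0
        forces = [np.zeros_like(mA), *[None] * (n_images - 2),
                  np.zeros_like(mA)]
        for i in range(1, n_images - 1):
            prev_d = path[i] - path[i - 1]
            next_d = path[i + 1] - path[i]
            e0, e1, e2 = energies[i - 1], energies[i], energies[i + 1]
            if e2 > e1 > e0:
                tau = next_d
            elif e2 < e1 < e0:
                tau = prev_d
            else:
                dmax = max(abs(e2 - e1), abs(e0 - e1))
                dmin = min(abs(e2 - e1), abs(e0 - e1))
                if e2 > e0:
                    tau = dmax * next_d + dmin * prev_d
                else:
                    tau = dmin * next_d + dmax * prev_d
            # constrain tangent to the sphere tangent space
            tau -= np.sum(tau * path[i], axis=1, keepdims=True) * path[i]
            tn = np.linalg.norm(tau)
            tau = tau / tn if tn > 0 else tau
            g = grads[i]
            f_true = -(g - float(np.sum(g * tau)) * tau)
            if climbing_on and i == climb_idx:
                f = -g + 2.0 * float(np.sum(g * tau)) * tau
            else:
                f_spr = k_spring * (
                    np.linalg.norm(next_d) - np.linalg.norm(prev_d)
                ) * tau
                f = f_true + f_spr
            forces[i] = f
            fmax = max(fmax, float(np.max(np.linalg.norm(
                f_true if not (climbing_on and i == climb_idx) else f,
                axis=1))))

        if fmax < tol:
            if climb and not climbing_on:
                climbing_on = True
                climb_idx = jmax
                v = [np.zeros_like(mA) for _ in range(n_images)]
                continue
            converged = True
            break
        if climb and not climbing_on and fmax < 20 * tol:
            climbing_on = True
            climb_idx = jmax
            v = [np.zeros_like(mA) for _ in range(n_images)]

        # FIRE update over the concatenated movable images
        P = sum(float(np.sum(forces[i] * v[i])) for i in range(1, n_images - 1))
        if P > 0:
            n_good += 1
            if n_good > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            n_good = 0
            dt *= f_dec
            alpha = alpha0
            v = [np.zeros_like(mA) for _ in range(n_images)]
        vnorm = math.sqrt(sum(float(np.sum(v[i] ** 2))
                              for i in range(1, n_images - 1)))
        fnorm = math.sqrt(sum(float(np.sum(forces[i] ** 2))
                              for i in range(1, n_images - 1)))
        for i in range(1, n_images - 1):
            v[i] = (1 - alpha) * v[i] + (
                alpha * forces[i] * (vnorm / fnorm if fnorm > 0 else 0.0)
            )
            v[i] += dt * forces[i]
            step = dt * v[i]
            # cap the per-cell step at 0.2 rad to keep the retraction sane
            sn = np.linalg.norm(step, axis=1, keepdims=True)
            step = step * np.clip(0.2 / np.maximum(sn, 1e-12), None, 1.0)
            newm = path[i] + step
            path[i] = newm / np.linalg.norm(newm, axis=1, keepdims=True)
            v[i] -= np.sum(v[i] * path[i], axis=1, keepdims=True) * path[i]

    for i in range(n_images):
        energies[i] = solver.energy_terms(path[i]).total
    images = [MagnetizationField(solver.assembly, p) for p in path]
    return EnergyPath(images=images, energies=energies.copy(),
                      converged=converged)


def refine_between_minima(
    path: EnergyPath,
    solver: LEMSolver,
    tol: float = 1e-4,
    lem_tol: float = 1e-6,
    **neb_kwargs,
) -> EnergyPath:
    """Re-run the NEB between the minima flanking the dominant barrier.

    When the initial path shows interior metastable dips, the two path
    minima (interior or endpoint) bracketing the global maximum are relaxed
    to true LEMs and a fresh NEB is computed between them, isolating the
    rate-limiting barrier.  Without interior minima the input path is
    returned unchanged.
    """
    interior = path.interior_minima()
    if not interior:
        return path
    n = len(path.images)
    minima = [0, *interior, n - 1]
    jmax = int(np.argmax(path.energies))
    left = max((i for i in minima if i < jmax), default=0)
    right = min((i for i in minima if i > jmax), default=n - 1)
    endA = solver.minimize(path.images[left].copy(), tol=lem_tol).field
    endB = solver.minimize(path.images[right].copy(), tol=lem_tol).field
    refined = neb_path(endA, endB, solver, tol=tol, **neb_kwargs)
    refined.refined = True
    return refined


@dataclass(frozen=True)
class RelaxationModel:
    """Arrhenius (Néel) relaxation-time model."""

    C: float = 1e-9          # attempt-time prefactor, s
    T: float = T_AMBIENT     # K
    kB: float = KB           # J/K

    @property
    def ET(self) -> float:
        """Thermal energy kB*T (J)."""
        return self.kB * self.T

    def tau(self, Em: float) -> float:
        return relaxation_time(Em, self)


def relaxation_time(Em: float, model: RelaxationModel | None = None) -> float:
    """Néel relaxation time tau = C exp(Em / kB T) in seconds.

    Barriers beyond the float64 exponential range return +inf (the grain is
    blocked on any conceivable timescale).
    """
    if Em < 0:
        raise ValueError("Em must be >= 0")
    model = model or RelaxationModel()
    x = Em / model.ET
    if x > 700.0:
        return float("inf")
    return model.C * math.exp(x)
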