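"""Applied-field protocols: hysteresis and magnetization-acquisition curves.

Loops are direction-averaged over a quasi-uniform set of sphere directions
(a golden-angle Fibonacci lattice with a seeded random rotation), the field
is stepped from +B to -B and back (default 250 mT in 2 mT steps), each step
warm-starting the minimization from the previous converged state, and the
normalized projected moment

    m = (mean(M) . b) / 1        (b the applied-field unit direction)

is averaged across directions.  Coercivity is the linearly interpolated
zero crossing of the averaged descending branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import (
    LEMSolver,
    MagnetizationField,
    minimize_lem,
    random_field,
    uniform_field,
)
from .geometry import VoxelAssembly
from .materials import Material

__all__ = [
    "FieldProtocol",
    "LoopResult",
    "fibonacci_directions",
    "projected_moment",
    "hysteresis_loop",
    "acquisition_curve",
    "coercivity",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_directions(n: int, seed: int | None = None) -> np.ndarray:
    """Quasi-uniform unit vectors from a golden-angle sphere lattice.

    With a ``seed`` the whole lattice is rotated by a random rotation drawn
    from that seed (deterministic per seed); without one the raw lattice is
    returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    if seed is not None:
        rng = np.random.default_rng(seed)
        # uniform random rotation via a normalized random quaternion
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, zq = q
        R = np.array(
            [
                [1 - 2 * (y * y + zq * zq), 2 * (x * y - zq * w), 2 * (x * zq + y * w)],
                [2 * (x * y + zq * w), 1 - 2 * (x * x + zq * zq), 2 * (y * zq - x * w)],
                [2 * (x * zq - y * w), 2 * (y * zq + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        dirs = dirs @ R.T
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def projected_moment(fld: MagnetizationField, direction) -> float:
    """Volume-weighted mean magnetization projected on a unit direction."""
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("direction must be non-zero")
    return float(fld.mean_m @ (d / nd))


@dataclass(frozen=True)
class FieldProtocol:
    """Field sweep description.

    ``B_start`` -> ``B_end`` in steps of ``B_step`` (all in tesla) along
    each direction; ``start_state`` chooses saturated (hysteresis) or
    random (acquisition) initial magnetization.
    """

    directions: np.ndarray = field(
        default_factory=lambda: fibonacci_directions(20, seed=0)
    )
    B_start: float = 0.25
    B_end: float = -0.25
    B_step: float = 0.002
    start_state: Literal["saturated", "random"] = "saturated"

    def grid(self) -> np.ndarray:
        n = int(round(abs(self.B_end - self.B_start) / self.B_step)) + 1
        return np.linspace(self.B_start, self.B_end, n)


@dataclass
class LoopResult:
    """Per-direction and direction-averaged loop branches."""

    B_grid: np.ndarray                       # tesla, descending order
    per_direction: np.ndarray                # (n_dir, n_B) descending m
    per_direction_asc: np.ndarray | None     # (n_dir, n_B) ascending m
    directions: np.ndarray
    flagged_steps: list = field(default_factory=list)

    @property
    def averaged(self) -> np.ndarray:
        return self.per_direction.mean(axis=0)

    @property
    def averaged_asc(self) -> np.ndarray | None:
        if self.per_direction_asc is None:
            return None
        return self.per_direction_asc.mean(axis=0)

    @property
    def coercivity_mT(self) -> float:
        return coercivity(self)

    def increments(self) -> np.ndarray:
        """Per-direction step increments dm along the recorded branch."""
        return np.diff(self.per_direction, axis=1)


def _sweep_branch(
    solver: LEMSolver,
    start: MagnetizationField,
    direction: np.ndarray,
    B_values: np.ndarray,
    tol: float,
    max_evals: int,
    flagged: list,
    tag: str,
):
    """Warm-started minimizations along one field branch."""
    state = start
    ms = np.empty(len(B_values))
    for k, B in enumerate(B_values):
        res = solver.minimize_tracked(
            state, applied_B=B * direction, tol=tol, max_evals=max_evals,
            init_mode="given",
        )
        if not res.converged:
            flagged.append({"branch": tag, "B_T": float(B),
                            "residual": res.residual})
        state = res.field
        ms[k] = projected_moment(state, direction)
    return ms, state


def hysteresis_loop(
    assembly: VoxelAssembly,
    material: Material,
    protocol: FieldProtocol | None = None,
    tol: float = 1e-5,
    max_evals: int = 20_000,
    both_branches: bool = True,
) -> LoopResult:
    """Direction-averaged major hysteresis loop.

    Each direction starts saturated along +direction at ``B_start``; the
    descending branch runs to ``B_end`` and (optionally) the ascending
    branch back up, warm-starting every step.  Non-converged steps are
    recorded in ``flagged_steps``, never dropped.
    """
    protocol = protocol or FieldProtocol()
    solver = LEMSolver(assembly, material)
    grid = protocol.grid()
    flagged: list = []
    desc = np.empty((len(protocol.directions), len(grid)))
    asc = np.empty_like(desc) if both_branches else None
    for di, d in enumerate(protocol.directions):
        start = uniform_field(assembly, d)
        desc[di], end_state = _sweep_branch(
            solver, start, d, grid, tol, max_evals, flagged, f"desc[{di}]"
        )
        if both_branches:
            asc[di], _ = _sweep_branch(
                solver, end_state, d, grid[::-1], tol, max_evals, flagged,
                f"asc[{di}]",
            )
    return LoopResult(
        B_grid=grid,
        per_direction=desc,
        per_direction_asc=asc,
        directions=np.asarray(protocol.directions),
        flagged_steps=flagged,
    )


def acquisition_curve(
    assembly: VoxelAssembly,
    material: Material,
    protocol: FieldProtocol | None = None,
    seed: int = 0,
    tol: float = 1e-5,
    max_evals: int = 20_000,
) -> LoopResult:
    """In-field magnetization acquisition from random initial states.

    The field ramps upward from 0 to ``B_start`` (250 mT default) along
    each direction, starting from an independent seeded random state; the
    recorded branch is ascending in field, and ``increments()`` gives the
    per-step magnetization gains whose distribution over field separates
    the soft and hard acquisition modes.
    """
    base = protocol or FieldProtocol()
    grid = np.arange(0.0, abs(base.B_start) + base.B_step / 2, base.B_step)
    solver = LEMSolver(assembly, material)
    flagged: list = []
    curves = np.empty((len(base.directions), len(grid)))
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in
             ss.spawn(len(base.directions))]
    for di, d in enumerate(base.directions):
        start = random_field(assembly, child[di])
        curves[di], _ = _sweep_branch(
            solver, start, d, grid, tol, max_evals, flagged, f"acq[{di}]"
        )
    return LoopResult(
        B_grid=grid,
        per_direction=curves,
        per_direction_asc=None,
        directions=np.asarray(base.directions),
        flagged_steps=flagged,
    )


def coercivity(loop: LoopResult) -> float:
    """Zero crossing (mT) of the averaged descending branch.

    Linear interpolation between the last non-negative and first negative
    sample; returns NaN (flagged by the caller) when the branch never
    crosses zero.
    """
    B = loop.B_grid
    m = loop.averaged
    if B[0] < B[-1]:  # ensure descending order
        B, m = B[::-1], m[::-1]
    sign = np.sign(m)
    for k in range(len(m) - 1):
        if sign[k] >= 0 and sign[k + 1] < 0:
            b0, b1 = B[k], B[k + 1]
            m0, m1 = m[k], m[k + 1]
            bc = b0 - m0 * (b1 - b0) / (m1 - m0)
            return abs(bc) * 1e3
    return float("nan")
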