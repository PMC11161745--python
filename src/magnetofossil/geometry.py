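"""Synthetic grain, chain and growth-series geometries on a regular voxel grid.

The segmented micrometre-scale grain that motivates these models is an
elongated, rounded cuboid ("cuboid-euhedral") particle with maximum/minimum
elongation axes of 0.91/0.72 um (axial ratio 1.26).  We emulate it with a
superellipsoid

    |x/A|^p + |y/B|^p + |z/C|^p <= 1

whose exponent ``p`` interpolates between an ellipsoid (p=2) and a sharp
cuboid (p -> inf).  The default exponent 2.3 gives a particle volume of
~0.28 um^3 for the default axes — about 60% of the bounding cuboid, which is
what the segmented particle occupies.

Conventions: X is the grain long axis, Z the short axis; assemblies are
centred at the origin; cell indices are 0-based.  Maghemitization is treated
as a 10% volume expansion, so magnetite geometries are shrunk isotropically
by a factor 0.9^(1/3) relative to the (segmented, maghemite) nominal axes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "GrainSpec",
    "ChainSpec",
    "GrowthSeriesSpec",
    "VoxelAssembly",
    "build_grain",
    "build_chain",
    "build_growth_series",
    "superellipsoid_volume",
    "DEFAULT_GRAIN",
    "DEFAULT_CHAIN",
    "DEFAULT_SERIES",
]

#: Fractional volume change of the maghemite -> magnetite back-transformation.
MAGNETITE_VOLUME_FACTOR = 0.90

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


class ResolutionError(ValueError):
    """Raised when the voxel size is too coarse to resolve a grain."""


class GeometryError(ValueError):
    """Raised for inconsistent geometric specifications (e.g. overlaps)."""


@dataclass(frozen=True)
class GrainSpec:
    """Single-grain geometry.

    Parameters
    ----------
    long_axis, short_axis :
        Full maximum/minimum elongation axes in metres (long along X,
        short along Y and Z).
    shape :
        ``"rounded_cuboid"`` uses the default superellipsoid exponent 2.3;
        ``"superellipsoid_exponent"`` uses :attr:`exponent` as given
        (2 = ellipsoid, large = sharp cuboid).
    mineral :
        ``"magnetite"`` geometries are shrunk to 90% of the nominal
        (maghemite) volume.
    """

    long_axis: float = 0.91e-6
    short_axis: float = 0.72e-6
    shape: Literal["rounded_cuboid", "superellipsoid_exponent"] = "rounded_cuboid"
    exponent: float = 2.3
    mineral: Literal["magnetite", "maghemite"] = "magnetite"

    def __post_init__(self) -> None:
        if self.long_axis <= 0 or self.short_axis <= 0:
            raise GeometryError("grain axes must be positive")
        if self.long_axis < self.short_axis:
            raise GeometryError("long_axis must be >= short_axis")
        if self.exponent < 2.0:
            raise GeometryError("superellipsoid exponent must be >= 2")

    @property
    def axial_ratio(self) -> float:
        return self.long_axis / self.short_axis

    @property
    def volume_scale(self) -> float:
        """Isotropic linear scale applied for the mineral volume rule."""
        if self.mineral == "magnetite":
            return MAGNETITE_VOLUME_FACTOR ** (1.0 / 3.0)
        return 1.0

    @property
    def realized_axes(self) -> tuple[float, float, float]:
        """Full (X, Y, Z) axes after the mineral volume adjustment, in m."""
        s = self.volume_scale
        return (self.long_axis * s, self.short_axis * s, self.short_axis * s)

    @property
    def analytic_volume(self) -> float:
        """Closed-form superellipsoid volume (m^3) of the realized grain."""
        ax, ay, az = self.realized_axes
        return superellipsoid_volume(ax, ay, az, self.exponent)

    def scaled(self, factor: float) -> "GrainSpec":
        return replace(
            self,
            long_axis=self.long_axis * factor,
            short_axis=self.short_axis * factor,
        )


def superellipsoid_volume(ax: float, ay: float, az: float, p: float) -> float:
    """Volume of ``|x/A|^p + |y/B|^p + |z/C|^p <= 1`` with full axes ax..az.

    Uses the closed form 8*A*B*C * Gamma(1+1/p)^3 / Gamma(1+3/p) with
    semi-axes A = ax/2 etc.
    """
    semi = (ax / 2.0) * (ay / 2.0) * (az / 2.0)
    return 8.0 * semi * math.gamma(1.0 + 1.0 / p) ** 3 / math.gamma(1.0 + 3.0 / p)


@dataclass(frozen=True)
class ChainSpec:
    """Linear chain of identical grains along X (long axes) or Z (short)."""

    n_grains: int = 3
    gap: float = 40e-9
    axis: Literal["X", "Z"] = "X"

    def __post_init__(self) -> None:
        if self.n_grains < 1:
            raise GeometryError("n_grains must be >= 1")
        if self.gap < 0:
            raise GeometryError("gap must be >= 0")

    def scaled(self, factor: float) -> "ChainSpec":
        return replace(self, gap=self.gap * factor)


@dataclass(frozen=True)
class GrowthSeriesSpec:
    """Uniform scaling series emulating organism growth.

    The default reproduces a 20-step series with grain long axes from
    0.086 um to 0.823 um; the whole system (grains and gaps) is scaled
    together so gap/long_axis stays constant.
    """

    n_steps: int = 20
    min_long_axis: float = 0.086e-6
    max_long_axis: float = 0.823e-6
    proportional_gap: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise GeometryError("n_steps must be >= 2")
        if not self.max_long_axis > self.min_long_axis > 0:
            raise GeometryError("series sizes must be strictly increasing")

    def long_axes(self) -> np.ndarray:
        return np.linspace(self.min_long_axis, self.max_long_axis, self.n_steps)


@dataclass
class VoxelAssembly:
    """A discretized magnetic region: grains plus empty gap cells.

    Attributes
    ----------
    cell_size :
        Edge length of the cubic voxels (m).
    occupancy :
        Boolean array, shape (nx, ny, nz); True where magnetic.
    grain_id :
        int array, same shape; 0 outside, 1..n_grains inside each grain.
    origin :
        Physical coordinate (m) of the centre of cell (0, 0, 0); the
        assembly is centred on the coordinate origin.
    chain_axis :
        "X"/"Z" chain direction, or None for a single grain.
    """

    cell_size: float
    occupancy: np.ndarray
    grain_id: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    chain_axis: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.occupancy.shape)

    @property
    def n_cells(self) -> int:
        """Number of occupied (magnetic) cells."""
        return int(self.occupancy.sum())

    @property
    def cell_volume(self) -> float:
        return self.cell_size**3

    @property
    def V(self) -> float:
        """Total magnetic volume (m^3): occupied cells x cell volume."""
        return self.n_cells * self.cell_volume

    @property
    def n_grains(self) -> int:
        return int(self.grain_id.max())

    def grain_volume(self, gid: int) -> float:
        return int((self.grain_id == gid).sum()) * self.cell_volume

    def cell_centers(self) -> np.ndarray:
        """(n_occupied, 3) physical coordinates of occupied cell centres."""
        idx = np.argwhere(self.occupancy)
        return self.origin + idx * self.cell_size

    def extent(self) -> np.ndarray:
        """Physical occupied extent (m) along each axis, cell-edge to edge."""
        idx = np.argwhere(self.occupancy)
        return (idx.max(axis=0) - idx.min(axis=0) + 1) * self.cell_size

    def manifest(self) -> dict:
        ext = self.extent()
        return {
            "cell_size_m": self.cell_size,
            "grid_shape": list(self.shape),
            "n_occupied_cells": self.n_cells,
            "n_grains": self.n_grains,
            "V_m3": self.V,
            "extent_m": [float(e) for e in ext],
            "chain_axis": self.chain_axis,
            **self.meta,
        }


def _superellipsoid_mask(
    axes: tuple[float, float, float], p: float, cell_size: float
) -> np.ndarray:
    """Voxelize a centred superellipsoid; cells are inside if their centre is."""
    half = np.asarray(axes) / 2.0
    n = np.maximum(np.ceil(np.asarray(axes) / cell_size).astype(int), 1)
    # Centre the grid on the particle: coordinates of cell centres.
    coords = [
        (np.arange(ni) - (ni - 1) / 2.0) * cell_size for ni in n
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    r = (
        np.abs(X / half[0]) ** p
        + np.abs(Y / half[1]) ** p
        + np.abs(Z / half[2]) ** p
    )
    return r <= 1.0


def build_grain(spec: GrainSpec, cell_size: float = 20e-9) -> VoxelAssembly:
    """Voxelize a single grain.

    Raises :class:`ResolutionError` when ``cell_size > short_axis / 4``:
    coarser grids cannot represent the particle shape or its domain
    structure even qualitatively.
    """
    ax, ay, az = spec.realized_axes
    if cell_size > min(ay, az) / 4.0:
        raise ResolutionError(
            f"cell_size {cell_size:.3g} m too coarse for short axis "
            f"{min(ay, az):.3g} m (need <= short_axis/4)"
        )
    p = spec.exponent if spec.shape == "superellipsoid_exponent" else 2.3
    if spec.shape == "rounded_cuboid":
        p = 2.3
    mask = _superellipsoid_mask((ax, ay, az), p, cell_size)
    grain_id = mask.astype(np.int32)
    origin = -(np.array(mask.shape) - 1) / 2.0 * cell_size
    asm = VoxelAssembly(
        cell_size=cell_size,
        occupancy=mask,
        grain_id=grain_id,
        origin=origin,
        chain_axis=None,
        meta={
            "grain_long_axis_m": ax,
            "grain_short_axis_m": ay,
            "mineral": spec.mineral,
            "superellipsoid_exponent": p,
            "analytic_volume_m3": spec.analytic_volume,
        },
    )
    return asm


def build_chain(
    grain: GrainSpec, chain: ChainSpec, cell_size: float = 20e-9
) -> VoxelAssembly:
    """Voxelize ``n_grains`` identical grains along the chain axis.

    The centre-to-centre pitch is the grain extent along the axis plus the
    gap, with the gap rounded to a whole number of cells (the realized gap
    is recorded in the manifest).
    """
    single = build_grain(grain, cell_size)
    if chain.n_grains == 1:
        single.chain_axis = chain.axis
        return single

    ax_i = _AXIS_INDEX[chain.axis]
    gmask = single.occupancy
    glen = gmask.shape[ax_i]  # grain extent along chain axis, in cells

    # Gap rounded to a whole number of cells; a positive nominal gap is
    # never rounded to zero (grains must stay disjoint), so sub-cell gaps
    # are realized as one cell and recorded in the manifest.
    if chain.gap == 0:
        gap_cells = 0
    else:
        gap_cells = max(1, int(round(chain.gap / cell_size)))
    pitch = glen + gap_cells
    if pitch < glen:
        raise GeometryError("grains overlap")

    shape = list(gmask.shape)
    shape[ax_i] = glen + (chain.n_grains - 1) * pitch
    occupancy = np.zeros(shape, dtype=bool)
    grain_id = np.zeros(shape, dtype=np.int32)
    for g in range(chain.n_grains):
        sl = [slice(None)] * 3
        sl[ax_i] = slice(g * pitch, g * pitch + glen)
        sl = tuple(sl)
        if occupancy[sl][gmask].any():
            raise GeometryError("grains overlap")
        occupancy[sl] |= gmask
        grain_id[sl][gmask] = g + 1

    origin = -(np.array(shape) - 1) / 2.0 * cell_size
    meta = dict(single.meta)
    meta.update(
        {
            "n_grains": chain.n_grains,
            "nominal_gap_m": chain.gap,
            "realized_gap_m": gap_cells * cell_size,
            "pitch_cells": pitch,
        }
    )
    return VoxelAssembly(
        cell_size=cell_size,
        occupancy=occupancy,
        grain_id=grain_id,
        origin=origin,
        chain_axis=chain.axis,
        meta=meta,
    )


def growth_cell_size(long_axis: float) -> float:
    """Default voxel size for a growth-series step.

    Interpolates linearly from 9 nm at an 86 nm grain to 20 nm at an
    823 nm grain (clipped outside), mirroring the mesh-size compromise
    between exchange-length resolution for small grains and tractable
    system size for micrometre grains.
    """
    lo, hi = 0.086e-6, 0.823e-6
    t = np.clip((long_axis - lo) / (hi - lo), 0.0, 1.0)
    return float(9e-9 + t * (20e-9 - 9e-9))


def build_growth_series(
    grain: GrainSpec,
    chain: ChainSpec,
    series: GrowthSeriesSpec,
    cell_size_fn=None,
) -> list[VoxelAssembly]:
    """Build the ordered list of uniformly scaled chain assemblies.

    Each step scales the entire system (grain axes and, when
    ``proportional_gap``, the gap) by the same factor, so every step is a
    scaled copy of the full chain.  ``cell_size_fn(long_axis) -> m`` allows
    coarser test resolutions; the default is :func:`growth_cell_size`.
    """
    if cell_size_fn is None:
        cell_size_fn = growth_cell_size
    assemblies = []
    for target in series.long_axes():
        factor = target / grain.long_axis
        gspec = grain.scaled(factor)
        cspec = chain.scaled(factor) if series.proportional_gap else chain
        asm = build_chain(gspec, cspec, cell_size=cell_size_fn(target))
        asm.meta["growth_long_axis_m"] = float(target)
        asm.meta["growth_scale_factor"] = float(factor)
        assemblies.append(asm)
    return assemblies


def connected_grains(assembly: VoxelAssembly) -> int:
    """Number of 6-connected components in the occupancy mask."""
    _, n = ndimage.label(assembly.occupancy)
    return int(n)


DEFAULT_GRAIN = GrainSpec()
DEFAULT_CHAIN = ChainSpec()
DEFAULT_SERIES = GrowthSeriesSpec()
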