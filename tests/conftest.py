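"""Shared fixtures: small voxel systems that run in seconds."""

from __future__ import annotations

import numpy as np
import pytest

from magnetofossil.core import LEMSolver
from magnetofossil.geometry import (
    ChainSpec,
    GrainSpec,
    VoxelAssembly,
    build_chain,
    build_grain,
)
from magnetofossil.materials import MAGNETITE


def cube_spec(edge: float, mineral: str = "maghemite") -> GrainSpec:
    """A sharp-cornered cube of the given edge length.

    Maghemite keeps the nominal dimensions (no mineral volume shrink), so
    voxel counts are exact.
    """
    return GrainSpec(
        long_axis=edge,
        short_axis=edge,
        shape="superellipsoid_exponent",
        exponent=40.0,
        mineral=mineral,
    )


def single_cell_assembly(cell: float = 10e-9) -> VoxelAssembly:
    return VoxelAssembly(
        cell_size=cell,
        occupancy=np.ones((1, 1, 1), dtype=bool),
        grain_id=np.ones((1, 1, 1), dtype=np.int32),
    )


@pytest.fixture(scope="session")
def sd_cube():
    """50 nm cube at 10 nm cells — a comfortably single-domain magnetite grain."""
    return build_grain(cube_spec(50e-9), 10e-9)


@pytest.fixture(scope="session")
def sd_cube_solver(sd_cube):
    return LEMSolver(sd_cube, MAGNETITE)


@pytest.fixture(scope="session")
def single_spin():
    """One isolated cubic cell: the single-spin toy (uniform demag, pure
    cubic anisotropy landscape)."""
    return single_cell_assembly()


@pytest.fixture(scope="session")
def single_spin_solver(single_spin):
    return LEMSolver(single_spin, MAGNETITE)


@pytest.fixture(scope="session")
def small_chain():
    """Scaled-down 3-grain X chain (150 nm grains, proportional 7 nm gap)."""
    scale = 150.0 / 910.0
    grain = GrainSpec().scaled(scale)
    chain = ChainSpec(n_grains=3, gap=40e-9 * scale, axis="X")
    return build_chain(grain, chain, cell_size=10e-9)


@pytest.fixture(scope="session")
def small_chain_solver(small_chain):
    return LEMSolver(small_chain, MAGNETITE)
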