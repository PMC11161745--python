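"""Magnetic material constants for the magnetofossil minerals.

Both minerals have negative first cubic anisotropy constant, so the easy
axes are the <111> body diagonals of the (grid-aligned) crystal lattice.
Constants are for ambient temperature and pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Vacuum permeability (N A^-2).
MU0 = 4.0e-7 * np.pi
#: Boltzmann constant (J K^-1).
KB = 1.3806e-23
#: Ambient temperature used throughout (K).
T_AMBIENT = 293.15


@dataclass(frozen=True)
class Material:
    """Micromagnetic constants of a cubic ferrimagnet.

    Parameters
    ----------
    name :
        Mineral name.
    Aex :
        Exchange stiffness (J m^-1).
    K1 :
        First cubic magnetocrystalline anisotropy constant (J m^-3).
        Negative K1 puts the easy axes along <111>.
    Ms :
        Saturation magnetization (A m^-1).
    """

    name: str
    Aex: float
    K1: float
    Ms: float

    @property
    def easy_axes(self) -> np.ndarray:
        """Unit easy axes: <111> for K1 < 0, <100> for K1 > 0."""
        if self.K1 < 0:
            axes = np.array(
                [[1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1]], dtype=float
            )
            return axes / np.sqrt(3.0)
        return np.eye(3)

    @property
    def exchange_length(self) -> float:
        """Magnetostatic exchange length sqrt(2 Aex / (mu0 Ms^2)) in m."""
        return float(np.sqrt(2.0 * self.Aex / (MU0 * self.Ms**2)))


MAGNETITE = Material(name="magnetite", Aex=1.33e-11, K1=-1.24e4, Ms=4.8e5)
MAGHEMITE = Material(name="maghemite", Aex=1.00e-11, K1=-4.60e3, Ms=3.8e5)

MATERIALS = {"magnetite": MAGNETITE, "maghemite": MAGHEMITE}


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown mineral {name!r}; choose from {sorted(MATERIALS)}"
        ) from None
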