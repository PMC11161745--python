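"""Magnetostatic (demagnetizing) field on a regular grid.

The demagnetizing field of a uniformly-magnetized-cell discretization is a
discrete convolution of the magnetization with the cell-averaged
demagnetizing tensor N:

    H_d(r_i) = - sum_j N(r_i - r_j) . Ms m_j

The tensor components are the classical Newell/Aharoni second differences
of the auxiliary potentials f (diagonal) and g (off-diagonal), which
average the interaction between two uniformly magnetized rectangular cells
exactly.  The convolution is evaluated with zero-padded real FFTs; the six
independent kernel transforms are cached per (grid shape, cell size).

Conventions: N is symmetric with trace 1; a single cubic cell has
N_xx = N_yy = N_zz = 1/3, so the self-field of an isolated cube is
-(1/3) Ms m and its energy density (mu0/2) Ms^2 / 3.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

__all__ = ["DemagKernel", "newell_f", "newell_g"]


def _safe_div(a, b):
    out = np.zeros(np.broadcast(a, b).shape)
    np.divide(a, b, out=out, where=(b != 0))
    return out


def newell_f(x, y, z):
    """Newell auxiliary function f for the diagonal tensor components."""
    x, y, z = np.abs(x), np.abs(y), np.abs(z)
    r = np.sqrt(x * x + y * y + z * z)
    out = np.zeros_like(r)

    xsq, ysq, zsq = x * x, y * y, z * z
    # asinh terms: asinh(y / sqrt(x^2 + z^2)) etc., guarded for zero norms
    d_xz = np.sqrt(xsq + zsq)
    d_xy = np.sqrt(xsq + ysq)
    t1 = 0.5 * y * (zsq - xsq) * np.arcsinh(_safe_div(y, d_xz))
    t2 = 0.5 * z * (ysq - xsq) * np.arcsinh(_safe_div(z, d_xy))
    t3 = -x * y * z * np.arctan(_safe_div(y * z, x * r))
    t4 = (1.0 / 6.0) * (2 * xsq - ysq - zsq) * r
    out = t1 + t2 + t3 + t4
    return out


def newell_g(x, y, z):
    """Newell auxiliary function g for the off-diagonal tensor components."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    z = np.abs(z)
    r = np.sqrt(x * x + y * y + z * z)

    xsq, ysq, zsq = x * x, y * y, z * z
    d_xy = np.sqrt(xsq + ysq)
    d_yz = np.sqrt(ysq + zsq)
    d_xz = np.sqrt(xsq + zsq)
    t1 = x * y * z * np.arcsinh(_safe_div(z, d_xy))
    t2 = (y / 6.0) * (3.0 * zsq - ysq) * np.arcsinh(_safe_div(x, d_yz))
    t3 = (x / 6.0) * (3.0 * zsq - xsq) * np.arcsinh(_safe_div(y, d_xz))
    t4 = -(z**3 / 6.0) * np.arctan(_safe_div(x * y, z * r))
    t5 = -(z * ysq / 2.0) * np.arctan(_safe_div(x * z, y * r))
    t6 = -(z * xsq / 2.0) * np.arctan(_safe_div(y * z, x * r))
    t7 = -x * y * r / 3.0
    return t1 + t2 + t3 + t4 + t5 + t6 + t7


def _second_difference(func, X, Y, Z, d):
    """27-point triple second difference of ``func`` over one cell spacing.

    Implements Delta_x Delta_y Delta_z applied to the auxiliary potential,
    yielding the cell-averaged tensor component up to the -1/(4 pi V)
    prefactor.
    """
    dx, dy, dz = d
    total = np.zeros(np.broadcast(X, Y, Z).shape)
    for i, wi in ((-1, 1.0), (0, -2.0), (1, 1.0)):
        for j, wj in ((-1, 1.0), (0, -2.0), (1, 1.0)):
            for k, wk in ((-1, 1.0), (0, -2.0), (1, 1.0)):
                total += wi * wj * wk * func(X + i * dx, Y + j * dy, Z + k * dz)
    return total


class DemagKernel:
    """Cell-averaged demagnetizing-tensor convolution on a (nx, ny, nz) grid.

    Parameters
    ----------
    shape :
        Grid shape (nx, ny, nz).
    cell_size :
        Cubic cell edge (m).

    Notes
    -----
    ``field(M)`` maps a full-grid magnetization array (nx, ny, nz, 3) in
    A m^-1 to the demagnetizing field H_d in A m^-1 on the same grid.  The
    operator is linear and symmetric (reciprocity), which the energy
    gradient relies on.
    """

    def __init__(self, shape: tuple[int, int, int], cell_size: float):
        self.shape = tuple(shape)
        self.cell_size = float(cell_size)
        self._build()

    def _build(self) -> None:
        nx, ny, nz = self.shape
        d = (self.cell_size,) * 3
        # Displacement lattice covering r_i - r_j for the padded circular
        # convolution: indices -n+1 .. n-1, wrapped into a 2n grid.
        px, py, pz = 2 * nx, 2 * ny, 2 * nz
        ox = np.fft.fftfreq(px, 1.0 / px).astype(int)  # 0..n-1, -n..-1 order
        oy = np.fft.fftfreq(py, 1.0 / py).astype(int)
        oz = np.fft.fftfreq(pz, 1.0 / pz).astype(int)
        X = ox[:, None, None] * self.cell_size
        Y = oy[None, :, None] * self.cell_size
        Z = oz[None, None, :] * self.cell_size

        pref = -1.0 / (4.0 * np.pi * self.cell_size**3)
        # Diagonal terms from f with the distinguished axis first.
        nxx = pref * _second_difference(lambda a, b, c: newell_f(a, b, c), X, Y, Z, d)
        nyy = pref * _second_difference(lambda a, b, c: newell_f(b, a, c), X, Y, Z, d)
        nzz = pref * _second_difference(lambda a, b, c: newell_f(c, b, a), X, Y, Z, d)
        # Off-diagonal terms from g: Nxy distinguishes (x, y), etc.
        nxy = pref * _second_difference(lambda a, b, c: newell_g(a, b, c), X, Y, Z, d)
        nxz = pref * _second_difference(lambda a, b, c: newell_g(a, c, b), X, Y, Z, d)
        nyz = pref * _second_difference(lambda a, b, c: newell_g(b, c, a), X, Y, Z, d)

        self._pad = (px, py, pz)
        self._Nk = [
            sp_fft.rfftn(comp) for comp in (nxx, nyy, nzz, nxy, nxz, nyz)
        ]

    @property
    def self_demag(self) -> float:
        """Diagonal self-term N_xx(0) — 1/3 for cubic cells."""
        k = sp_fft.irfftn(self._Nk[0], s=self._pad)
        return float(k[0, 0, 0])

    def field(self, M: np.ndarray) -> np.ndarray:
        """Demagnetizing field H_d (A m^-1) for magnetization M (A m^-1).

        M has shape (nx, ny, nz, 3); cells outside the magnetic region must
        carry M = 0.
        """
        nx, ny, nz = self.shape
        pad = self._pad
        mk = [sp_fft.rfftn(M[..., c], s=pad) for c in range(3)]
        Nxx, Nyy, Nzz, Nxy, Nxz, Nyz = self._Nk
        hx = Nxx * mk[0] + Nxy * mk[1] + Nxz * mk[2]
        hy = Nxy * mk[0] + Nyy * mk[1] + Nyz * mk[2]
        hz = Nxz * mk[0] + Nyz * mk[1] + Nzz * mk[2]
        H = np.empty_like(M)
        for c, hk in enumerate((hx, hy, hz)):
            H[..., c] = -sp_fft.irfftn(hk, s=pad)[:nx, :ny, :nz]
        return H
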