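"""Real spherical harmonics and the density-normalized d_lm convention.

The aspherical deformation terms of a Hansen-Coppens pseudoatom use
*density-normalized* real spherical harmonics d_lm with

    integral |d_lm| dOmega = 2   for l >= 1
    integral  d_00  dOmega = 1   (d_00 = 1/4pi)

so that a multipole population P_lm transfers exactly |P_lm| electrons
between the positive and negative lobes of the harmonic.  Internally we
work with orthonormal real spherical harmonics y_lm (no Condon-Shortley
phase) and convert with per-(l,m) constants computed numerically once.

Index convention for m: -l..l, with m < 0 the sine harmonics, m > 0 the
cosine harmonics, m = 0 the zonal one.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial, pi, sqrt

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import lpmv

MAX_L = 4


def _theta_part(l: int, m: int, x):
    """Normalized associated-Legendre factor Theta_lm(cos theta = x).

    y_lm = Theta_lm(x) * {cos(m phi), 1, sin(|m| phi)}; includes the
    sqrt(2) factor for m != 0 and strips the Condon-Shortley phase.
    """
    am = abs(m)
    norm = sqrt((2 * l + 1) / (4 * pi) * factorial(l - am) / factorial(l + am))
    val = (-1.0) ** am * norm * lpmv(am, l, x)
    if m != 0:
        val = val * sqrt(2.0)
    return val


def real_sph_harm(l: int, m: int, theta, phi):
    """Orthonormal real spherical harmonic y_lm(theta, phi)."""
    x = np.cos(theta)
    t = _theta_part(l, m, x)
    if m > 0:
        return t * np.cos(m * np.asarray(phi))
    if m < 0:
        return t * np.sin(-m * np.asarray(phi))
    return t * np.ones_like(np.asarray(phi, dtype=float))


def real_sph_harm_xyz(l: int, m: int, xyz):
    """y_lm evaluated at Cartesian direction vectors (need not be unit)."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    r = np.linalg.norm(xyz, axis=-1)
    safe = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(xyz[..., 2] / safe, -1.0, 1.0))
    phi = np.arctan2(xyz[..., 1], xyz[..., 0])
    return real_sph_harm(l, m, theta, phi)


@lru_cache(maxsize=None)
def abs_angular_integral(l: int, m: int) -> float:
    """integral |y_lm| dOmega, by piecewise quadrature between sign changes."""
    am = abs(m)

    def theta_abs(x):
        return abs(_theta_part(l, am, x))

    # locate zeros of the Legendre factor in (-1, 1)
    xs = np.linspace(-1.0, 1.0, 4001)
    vals = _theta_part(l, am, xs)
    brk = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            brk.append(xs[i])
        elif vals[i] * vals[i + 1] < 0:
            brk.append(brentq(lambda x: _theta_part(l, am, x), xs[i], xs[i + 1]))
    pts = [-1.0] + brk + [1.0]
    theta_int = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        theta_int += quad(theta_abs, a, b, limit=200)[0]
    if m == 0:
        return 2 * pi * theta_int
    # integral over phi of |cos m phi| or |sin m phi| is 4 for any m >= 1
    return 4.0 * theta_int


@lru_cache(maxsize=None)
def density_normalization(l: int, m: int) -> float:
    """Constant D_lm with d_lm = D_lm * y_lm (HCMM density normalization)."""
    if l == 0:
        return 1.0 / sqrt(4 * pi)  # d_00 = 1/(4 pi)
    return 2.0 / abs_angular_integral(l, m)


def d_lm_xyz(l: int, m: int, xyz):
    """Density-normalized harmonic d_lm at Cartesian directions."""
    return density_normalization(l, m) * real_sph_harm_xyz(l, m, xyz)


def racah_norm(l: int) -> float:
    """C_lm = racah_norm(l) * y_lm (Racah / spherical-tensor convention)."""
    return sqrt(4 * pi / (2 * l + 1))


@lru_cache(maxsize=None)
def _fibonacci_sphere(n: int = 64) -> np.ndarray:
    """Deterministic well-spread unit vectors (for rotation-matrix fits)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * pi * (3.0 - sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


@lru_cache(maxsize=None)
def _design_pinv(l: int):
    u = _fibonacci_sphere()
    y = np.column_stack([real_sph_harm_xyz(l, m, u) for m in range(-l, l + 1)])
    return np.linalg.pinv(y)


def sh_rotation_matrix(l: int, rot: np.ndarray) -> np.ndarray:
    """Matrix M with  y_lm(R^T u) = sum_m' M[m, m'] y_lm'(u).

    ``rot`` is a proper rotation whose columns are the local axes expressed
    in the global frame; M maps local-frame harmonic coefficients to
    global-frame ones via ``c_global = M.T @ c_local``.  Built by sampling
    both sides on a fixed spherical point set and solving exactly (the
    harmonics of degree l span a (2l+1)-dimensional space).
    """
    if l == 0:
        return np.ones((1, 1))
    u = _fibonacci_sphere()
    u_loc = u @ rot  # row-vectors: R^T u
    y_loc = np.column_stack(
        [real_sph_harm_xyz(l, m, u_loc) for m in range(-l, l + 1)]
    )
    return (_design_pinv(l) @ y_loc).T


def rotate_coeffs(l: int, rot: np.ndarray, coeffs_local: np.ndarray) -> np.ndarray:
    """Re-express harmonic coefficients given in a local frame in the global one."""
    if l == 0:
        return np.asarray(coeffs_local, dtype=float).copy()
    m = sh_rotation_matrix(l, rot)
    return m.T @ np.asarray(coeffs_local, dtype=float)
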