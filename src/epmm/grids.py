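"""Atom-centered quadrature grids for exact-potential integration.

Radial: Gauss-Chebyshev (second kind) with a Becke-style rational mapping
r = r_m (1+x)/(1-x) onto (0, inf).  Angular: Gauss-Legendre x uniform-phi
product grids on the sphere; the supported "ladder" of angular sizes is
2k^2 (exact for spherical harmonics up to degree 2k-1), and a requested
size is rounded up to the next rung (590 -> 648, 974 -> 1058).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import pi

import numpy as np

__all__ = ["QuadratureSpec", "angular_ladder", "angular_grid", "radial_grid", "atom_grid"]

#: Becke-style midpoint radii (Bohr) per element for the radial mapping.
RADIAL_SCALE = {
    "H": 0.8, "C": 1.4, "N": 1.25, "O": 1.1, "F": 1.0,
    "Na": 2.2, "Mg": 2.0, "P": 1.9, "S": 1.9, "Cl": 1.8,
}
RADIAL_SCALE_DEFAULT = 1.5

_LADDER = tuple(2 * k * k for k in range(4, 41))


def angular_ladder() -> tuple[int, ...]:
    return _LADDER


@dataclass(frozen=True)
class QuadratureSpec:
    """Numerical integration settings for the exact-potential zone.

    ``rcrit`` (Angstrom) is the pair separation below which the exact
    Coulomb integral replaces the multipole expansion.
    """

    n_radial: int = 99
    n_angular: int = 590
    rcrit: float = 5.0
    integration_scheme_id: str = "gc2-becke/gl-product"

    def __post_init__(self):
        if self.n_radial < 20:
            raise ValueError(f"n_radial = {self.n_radial} below the minimum of 20")
        if self.n_angular < _LADDER[0]:
            raise ValueError(f"n_angular = {self.n_angular} below the minimum {_LADDER[0]}")
        if self.rcrit <= 0:
            raise ValueError("rcrit must be positive")

    @property
    def n_angular_actual(self) -> int:
        for rung in _LADDER:
            if rung >= self.n_angular:
                return rung
        return _LADDER[-1]


@lru_cache(maxsize=32)
def angular_grid(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors and weights (summing to 4 pi) for a ladder size."""
    if n_points not in _LADDER:
        raise ValueError(f"{n_points} is not on the angular ladder {_LADDER[:6]}...")
    k = int(round((n_points / 2) ** 0.5))
    x, wx = np.polynomial.legendre.leggauss(k)
    nphi = 2 * k
    phi = (np.arange(nphi) + 0.5) * 2 * pi / nphi
    wphi = 2 * pi / nphi
    st = np.sqrt(1.0 - x * x)
    pts = np.empty((k * nphi, 3))
    w = np.empty(k * nphi)
    for i in range(k):
        s = slice(i * nphi, (i + 1) * nphi)
        pts[s, 0] = st[i] * np.cos(phi)
        pts[s, 1] = st[i] * np.sin(phi)
        pts[s, 2] = x[i]
        w[s] = wx[i] * wphi
    return pts, w


@lru_cache(maxsize=64)
def radial_grid(n: int, r_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Nodes r_i (Bohr) and weights for integral f(r) dr on (0, inf)."""
    i = np.arange(1, n + 1)
    theta = i * pi / (n + 1)
    x = np.cos(theta)
    w_gc = pi / (n + 1) * np.sin(theta)  # includes removal of the GC weight fn
    r = r_m * (1.0 + x) / (1.0 - x)
    jac = 2.0 * r_m / (1.0 - x) ** 2
    return r[::-1].copy(), (w_gc * jac)[::-1].copy()


@lru_cache(maxsize=64)
def atom_grid(element: str, n_radial: int, n_angular: int):
    """3D grid (offsets in Bohr, volume weights) centered on an atom."""
    r_m = RADIAL_SCALE.get(element, RADIAL_SCALE_DEFAULT)
    r, wr = radial_grid(n_radial, r_m)
    u, wu = angular_grid(n_angular)
    pts = (r[:, None, None] * u[None, :, :]).reshape(-1, 3)
    w = (wr[:, None] * r[:, None] ** 2 * wu[None, :]).reshape(-1)
    return pts, w
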