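"""Intermolecular electrostatic energies: multipole (MM), exact-potential
(EP), the EPMM hybrid, penetration, and point-charge Coulomb sums.

The exact pair energy integrates the analytic electrostatic potential of
one pseudoatom (closed forms via incomplete gamma functions, including the
aspherical deformation terms) against the partner's continuous electron
density on an atom-centered quadrature grid, plus the nucleus-potential
and nucleus-nucleus terms.  The multipole energy is the spherical-tensor
(Buckingham-type) interaction of total-charge-density moments up to l = 4
per atom, evaluated in the pair frame with the axis along the
internuclear vector.

Penetration energy is E_pen = E_EPMM - E_MM: the short-range correction
from overlapping charge clouds, identically zero when no pair lies inside
the exact-potential zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, factorial, pi, sqrt

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaincc

from . import harmonics
from .constants import ANGSTROM_TO_BOHR, COULOMB_KCAL_A, HARTREE_TO_KCALMOL
from .density import MolecularDensityModel, Pseudoatom, moments_racah
from .grids import QuadratureSpec, atom_grid

__all__ = [
    "InteractionEnergy",
    "PointChargeSet",
    "multipole_pair_energy",
    "exact_pair_energy",
    "epmm_energy",
    "point_charge_energy",
    "pseudoatom_potential",
]


# ---------------------------------------------------------------------------
# analytic potentials


def _lower_gamma(k: float, x: np.ndarray) -> np.ndarray:
    return gammainc(k, x) * factorial(int(k) - 1)


def _upper_gamma(k: float, x: np.ndarray) -> np.ndarray:
    return gammaincc(k, x) * factorial(int(k) - 1)


def _spherical_primitive_potential(coef, p, alpha, r):
    """Potential (a.u.) of density coef * s^p * exp(-alpha s) at radii r."""
    x = alpha * r
    inner = _lower_gamma(p + 3, x) / (alpha ** (p + 3) * r)
    outer = _upper_gamma(p + 2, x) / alpha ** (p + 2)
    return 4.0 * pi * coef * (inner + outer)


def _spherical_electron_primitives(par) -> list[tuple[float, int, float]]:
    """(coef, p, alpha) of the spherical electron density of a pseudoatom."""
    prims = []
    for q in par.wavefunction.core_primitives():
        prims.append((par.p_core * q.coef, q.p, q.alpha))
    k = par.kappa
    for q in par.wavefunction.valence_primitives():
        prims.append((par.p_val * q.coef * k ** (q.p + 3), q.p, q.alpha * k))
    p00 = par.p_lm.get((0, 0), 0.0)
    if p00 != 0.0:
        kp = par.kappa_prime
        n0 = par.radial.n_of_l[0]
        beta = par.radial.zeta * kp
        a = beta ** (n0 + 3) / factorial(n0 + 2) / (4.0 * pi)
        prims.append((p00 * a, n0, beta))
    return prims


def electron_potential(atom: Pseudoatom, points_bohr: np.ndarray) -> np.ndarray:
    """Electrostatic potential (a.u.) generated by the pseudoatom's electron
    density treated as a *positive* charge cloud, at global points in Bohr.

    Closed forms via incomplete gamma functions, finite everywhere; the
    total-charge potential is Z/r minus this.
    """
    par = atom.parameters
    d = points_bohr - atom.position * ANGSTROM_TO_BOHR
    r = np.linalg.norm(d, axis=-1)
    r = np.where(r > 0, r, 1e-30)
    v = np.zeros_like(r)
    for coef, p, alpha in _spherical_electron_primitives(par):
        v = v + _spherical_primitive_potential(coef, p, alpha, r)
    by_l: dict[int, dict[int, float]] = {}
    for (l, m), val in par.p_lm.items():
        if l >= 1 and val != 0.0:
            by_l.setdefault(l, {})[m] = val
    if by_l:
        frame = atom._frame_or_raise()
        d_loc = d @ frame
        kp = par.kappa_prime
        zeta = par.radial.zeta
        for l, ms in by_l.items():
            n = par.radial.n_of_l[l]
            beta = zeta * kp
            a = beta ** (n + 3) / factorial(n + 2)
            x = beta * r
            inner = _lower_gamma(n + l + 3, x) / (beta ** (n + l + 3) * r ** (l + 1))
            outer = r**l * _upper_gamma(n + 2 - l, x) / beta ** (n + 2 - l)
            radial = 4.0 * pi / (2 * l + 1) * a * (inner + outer)
            ang = np.zeros(len(d_loc))
            for m, val in ms.items():
                ang += val * harmonics.d_lm_xyz(l, m, d_loc)
            v = v + radial * ang
    return v


def pseudoatom_potential(atom: Pseudoatom, points_bohr: np.ndarray) -> np.ndarray:
    """Total electrostatic potential (a.u.) of one pseudoatom -- nuclear
    point charge plus continuous electron density -- at global Bohr points."""
    d = points_bohr - atom.position * ANGSTROM_TO_BOHR
    r = np.linalg.norm(d, axis=-1)
    r = np.where(r > 0, r, np.inf)
    return atom.parameters.z / r - electron_potential(atom, points_bohr)


def _electron_density_bohr(atom: Pseudoatom, points_bohr: np.ndarray) -> np.ndarray:
    from .density import evaluate_density
    from .constants import BOHR_TO_ANGSTROM

    return np.asarray(evaluate_density(atom, points_bohr * BOHR_TO_ANGSTROM))


# ---------------------------------------------------------------------------
# exact pair energy


def _covariant_pair_frame(a: Pseudoatom, b: Pseudoatom, r_ab: np.ndarray) -> np.ndarray:
    """Rotation with z along the pair axis and x tied to the atoms' local
    frames, so it co-rotates under rigid motion of the whole system."""
    z = r_ab / np.linalg.norm(r_ab)
    x = None
    for atom in (a, b):
        if atom.frame is None:
            continue
        for k in (0, 1):
            v = np.asarray(atom.frame)[:, k]
            v = v - z * (v @ z)
            if np.linalg.norm(v) > 1e-6:
                x = v / np.linalg.norm(v)
                break
        if x is not None:
            break
    if x is None:
        axis = np.eye(3)[int(np.argmin(np.abs(z)))]
        v = axis - z * (axis @ z)
        x = v / np.linalg.norm(v)
    return np.column_stack([x, np.cross(z, x), z])


def exact_pair_energy(
    a: Pseudoatom, b: Pseudoatom, quad: QuadratureSpec | None = None
) -> float:
    """Full Coulomb interaction (kcal/mol) of two continuous pseudoatom
    charge distributions (electrons + nuclear point charges)."""
    quad = quad or QuadratureSpec()
    ra = np.asarray(a.position, dtype=float) * ANGSTROM_TO_BOHR
    rb = np.asarray(b.position, dtype=float) * ANGSTROM_TO_BOHR
    dist = float(np.linalg.norm(ra - rb))
    if dist == 0.0:
        raise ValueError(f"coincident pseudoatom centers: {a.label!r} / {b.label!r}")
    za, zb = a.parameters.z, b.parameters.z
    # nucleus-nucleus and the two (analytic) nucleus-electron terms
    e_nn = za * zb / dist
    e_ne = -zb * electron_potential(a, rb[None, :])[0]
    e_en = -za * electron_potential(b, ra[None, :])[0]
    # electron-electron term: quadrature of each density against the other's
    # analytic electron potential, averaged over the two atom-centered grids
    # (symmetric in (a, b) by construction; integrand smooth everywhere).
    # Grids are oriented covariantly (z along the pair axis, x from the
    # atoms' local frames) so rigid motion leaves the energy invariant.
    orient = _covariant_pair_frame(a, b, rb - ra)
    e_ee = 0.0
    for src, tgt, center in ((a, b, rb), (b, a, ra)):
        pts, w = atom_grid(tgt.parameters.element, quad.n_radial, quad.n_angular_actual)
        pts_glob = pts @ orient.T + center
        e_ee += 0.5 * np.dot(
            w, _electron_density_bohr(tgt, pts_glob) * electron_potential(src, pts_glob)
        )
    return float((e_nn + e_ne + e_en + e_ee) * HARTREE_TO_KCALMOL)


# ---------------------------------------------------------------------------
# multipole-moment (Buckingham-type) pair energy


@lru_cache(maxsize=None)
def _mm_coupling(l1: int, l2: int) -> np.ndarray:
    """Coefficients g[m] for the pair-frame interaction, m = 0..min(l1,l2)."""
    big_l = l1 + l2
    out = np.zeros(min(l1, l2) + 1)
    for m in range(min(l1, l2) + 1):
        c = sqrt(comb(big_l, l2 + m) * comb(big_l, l2 - m))
        out[m] = (-1.0) ** l2 * (-1.0) ** m * c
    return out


def _pair_frame(r_ab: np.ndarray) -> np.ndarray:
    """Rotation whose z-column is the unit inter-site vector."""
    z = r_ab / np.linalg.norm(r_ab)
    axis = np.eye(3)[int(np.argmin(np.abs(z)))]
    x = axis - z * (axis @ z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def multipole_pair_energy(
    a: Pseudoatom,
    b: Pseudoatom,
    max_l: int = 4,
    moments_a: list[np.ndarray] | None = None,
    moments_b: list[np.ndarray] | None = None,
) -> float:
    """Spherical-tensor multipole interaction energy (kcal/mol), all terms
    with l_a <= max_l and l_b <= max_l.  Exact for non-overlapping densities.

    Precomputed global-frame Racah moments may be passed to avoid
    recomputation in model-level loops.
    """
    ra = np.asarray(a.position, dtype=float) * ANGSTROM_TO_BOHR
    rb = np.asarray(b.position, dtype=float) * ANGSTROM_TO_BOHR
    r_ab = rb - ra
    dist = float(np.linalg.norm(r_ab))
    if dist == 0.0:
        raise ValueError(f"coincident pseudoatom centers: {a.label!r} / {b.label!r}")
    qa = moments_a if moments_a is not None else moments_racah(a, max_l)
    qb = moments_b if moments_b is not None else moments_racah(b, max_l)
    frame = _pair_frame(r_ab)
    # re-express global coefficients in the pair frame
    qa_f = [harmonics.rotate_coeffs(l, frame.T, qa[l]) for l in range(max_l + 1)]
    qb_f = [harmonics.rotate_coeffs(l, frame.T, qb[l]) for l in range(max_l + 1)]
    e = 0.0
    for l1 in range(max_l + 1):
        for l2 in range(max_l + 1):
            g = _mm_coupling(l1, l2)
            rpow = dist ** (l1 + l2 + 1)
            term = g[0] * qa_f[l1][l1] * qb_f[l2][l2]
            for m in range(1, min(l1, l2) + 1):
                term += g[m] * (
                    qa_f[l1][l1 + m] * qb_f[l2][l2 + m]
                    + qa_f[l1][l1 - m] * qb_f[l2][l2 - m]
                )
            e += term / rpow
    return float(e * HARTREE_TO_KCALMOL)


# ---------------------------------------------------------------------------
# model-level EPMM


@dataclass
class InteractionEnergy:
    """(E_MM, E_EPMM, E_pen) with a per-atom-pair breakdown (kcal/mol).

    ``pair_breakdown`` columns: atom_a, atom_b, distance (Angstrom), method
    ("EP" or "MM"), e_mm, e_pair (the EPMM-path contribution).
    """

    e_mm: float
    e_epmm: float
    pair_breakdown: pd.DataFrame

    @property
    def e_pen(self) -> float:
        return self.e_epmm - self.e_mm


def epmm_energy(
    model_a: MolecularDensityModel,
    model_b: MolecularDensityModel,
    quad: QuadratureSpec | None = None,
    max_l: int = 4,
) -> InteractionEnergy:
    """Hybrid electrostatic interaction energy between two density models.

    Pairs closer than ``quad.rcrit`` get the exact Coulomb integral, the
    rest the multipole expansion; ``e_mm`` is the multipole energy over all
    pairs, so E_pen = E_EPMM - E_MM isolates the penetration correction.
    """
    quad = quad or QuadratureSpec()
    labels_a = {id(at) for at in model_a.atoms}
    if any(id(at) in labels_a for at in model_b.atoms):
        raise ValueError("models share pseudoatom objects; they must be disjoint")
    named_a = {at.label for at in model_a.atoms if at.label}
    shared = named_a & {at.label for at in model_b.atoms if at.label}
    if shared:
        raise ValueError(f"models share atom identities: {sorted(shared)[:5]}")
    mom_a = [moments_racah(at, max_l) for at in model_a.atoms]
    mom_b = [moments_racah(at, max_l) for at in model_b.atoms]
    rows = []
    for i, at_a in enumerate(model_a.atoms):
        for j, at_b in enumerate(model_b.atoms):
            d = float(np.linalg.norm(at_a.position - at_b.position))
            e_mm = multipole_pair_energy(
                at_a, at_b, max_l, moments_a=mom_a[i], moments_b=mom_b[j]
            )
            if d <= quad.rcrit:
                e_pair = exact_pair_energy(at_a, at_b, quad)
                method = "EP"
            else:
                e_pair = e_mm
                method = "MM"
            rows.append((at_a.label, at_b.label, d, method, e_mm, e_pair))
    df = pd.DataFrame(
        rows, columns=["atom_a", "atom_b", "distance", "method", "e_mm", "e_pair"]
    )
    return InteractionEnergy(
        e_mm=float(df["e_mm"].sum()), e_epmm=float(df["e_pair"].sum()), pair_breakdown=df
    )


# ---------------------------------------------------------------------------
# point charges


@dataclass
class PointChargeSet:
    """Partial charges (e) at Cartesian positions (Angstrom)."""

    charges: np.ndarray
    positions: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if not (np.all(np.isfinite(self.charges)) and np.all(np.isfinite(self.positions))):
            raise ValueError("non-finite point-charge data")
        if len(self.charges) != len(self.positions):
            raise ValueError("charge/position length mismatch")


def point_charge_energy(a: PointChargeSet, b: PointChargeSet) -> float:
    """Coulomb energy (kcal/mol) between two disjoint point-charge sets."""
    diff = a.positions[:, None, :] - b.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    if np.any(dist == 0.0):
        raise ValueError("zero interatomic distance between the point-charge sets")
    return float(COULOMB_KCAL_A * np.sum(np.outer(a.charges, b.charges) / dist))
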