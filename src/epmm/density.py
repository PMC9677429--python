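"""Hansen-Coppens multipole pseudoatom densities and their moments.

A pseudoatom carries a continuous electron density

    rho(r) = P_core rho_core(r)
           + P_val  kappa^3 rho_val(kappa r)
           + sum_l kappa'^3 R_l(kappa' r) sum_m P_lm d_lm(theta, phi)

with rho_core/rho_val per-electron spherical densities from the packaged
wavefunction table, R_l density-normalized Slater radial functions
(R_l(r) = zeta^(n+3)/(n+2)! r^n exp(-zeta r)), and d_lm density-normalized
real spherical harmonics evaluated in the atom-local frame.  All radial
quantities are in Bohr; positions and public evaluation points in Angstrom.

Atomic net charge convention: q = Z - P_core - P_val - P_00 (fixture
parameter sets use P_00 = 0, so q = Z - P_core - P_val).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

from . import harmonics
from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, atomic_number
from .wavefunctions import AtomicWavefunctionTable, default_wavefunction_table

__all__ = [
    "RadialFunctionSpec",
    "PseudoatomParameters",
    "Pseudoatom",
    "MolecularDensityModel",
    "evaluate_density",
    "atomic_multipole_moments",
    "molecular_charge",
]

MAX_L = 4


@dataclass(frozen=True)
class RadialFunctionSpec:
    """Single-zeta Slater radial functions for the deformation terms.

    ``zeta`` in Bohr^-1; ``n_of_l`` the exponent powers n(l) for l = 0..4.
    """

    zeta: float
    n_of_l: tuple[int, int, int, int, int]

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValueError(f"zeta must be positive, got {self.zeta}")
        for l, n in enumerate(self.n_of_l):
            if n < l:
                raise ValueError(f"n(l={l}) = {n} < l: radial function diverges at origin")

    def normalization(self, l: int) -> float:
        """N with integral N r^n exp(-zeta r) r^2 dr = 1."""
        n = self.n_of_l[l]
        return self.zeta ** (n + 3) / factorial(n + 2)

    def radial(self, l: int, r):
        r = np.asarray(r, dtype=float)
        n = self.n_of_l[l]
        return self.normalization(l) * r**n * np.exp(-self.zeta * r)

    def r_l_expectation(self, l: int, kappa_prime: float = 1.0) -> float:
        """<r^l> of the kappa'-scaled density-normalized radial function (Bohr^l)."""
        n = self.n_of_l[l]
        return factorial(n + l + 2) / (
            factorial(n + 2) * (self.zeta * kappa_prime) ** l
        )


@dataclass
class PseudoatomParameters:
    """The full HCMM parameter set of one atom type."""

    element: str
    p_core: float
    p_val: float
    kappa: float
    kappa_prime: float
    radial: RadialFunctionSpec
    p_lm: dict[tuple[int, int], float] = field(default_factory=dict)
    wavefunction: AtomicWavefunctionTable | None = None

    def __post_init__(self):
        if not (0.5 < self.kappa < 2.0):
            raise ValueError(f"kappa = {self.kappa} outside the sane range (0.5, 2.0)")
        if not (0.5 < self.kappa_prime < 2.0):
            raise ValueError(
                f"kappa_prime = {self.kappa_prime} outside the sane range (0.5, 2.0)"
            )
        for (l, m) in self.p_lm:
            if not (0 <= l <= MAX_L) or abs(m) > l:
                raise ValueError(f"invalid multipole index (l={l}, m={m})")
        if self.wavefunction is None:
            self.wavefunction = default_wavefunction_table()[self.element]
        if abs(self.p_core - self.wavefunction.n_core_electrons) > 1e-9:
            raise ValueError(
                f"P_core = {self.p_core} does not match the {self.element} core "
                f"electron count {self.wavefunction.n_core_electrons}"
            )

    @property
    def z(self) -> int:
        return atomic_number(self.element)

    @property
    def net_charge(self) -> float:
        return self.z - self.p_core - self.p_val - self.p_lm.get((0, 0), 0.0)

    def max_nonzero_l(self) -> int:
        nz = [l for (l, _m), v in self.p_lm.items() if v != 0.0]
        return max(nz) if nz else 0

    def has_aspherical_terms(self) -> bool:
        return any(v != 0.0 for (l, _m), v in self.p_lm.items() if l >= 1)

    def copy(self) -> "PseudoatomParameters":
        return PseudoatomParameters(
            element=self.element,
            p_core=self.p_core,
            p_val=self.p_val,
            kappa=self.kappa,
            kappa_prime=self.kappa_prime,
            radial=self.radial,
            p_lm=dict(self.p_lm),
            wavefunction=self.wavefunction,
        )


@dataclass
class Pseudoatom:
    """A positioned pseudoatom.

    ``position`` in Angstrom; ``frame`` is the local-frame rotation (columns =
    local axes in global coordinates) or None when unresolved — evaluation
    then fails if any aspherical population is present.
    """

    parameters: PseudoatomParameters
    position: np.ndarray
    label: str = ""
    frame: np.ndarray | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.label!r}")

    def _frame_or_raise(self) -> np.ndarray:
        if self.frame is not None:
            return np.asarray(self.frame, dtype=float)
        if self.parameters.has_aspherical_terms():
            raise ValueError(
                f"atom {self.label!r} has aspherical populations but no "
                "resolved local frame"
            )
        return np.eye(3)


@dataclass
class MolecularDensityModel:
    """An ordered collection of pseudoatoms forming a continuous density."""

    atoms: list[Pseudoatom] = field(default_factory=list)
    label: str = ""

    @property
    def total_charge(self) -> float:
        return molecular_charge(self)

    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)


def evaluate_density(atom: Pseudoatom, points) -> np.ndarray | float:
    """Electron density of one pseudoatom (e/Bohr^3) at points given in Angstrom."""
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite evaluation point")
    par = atom.parameters
    d = (pts - atom.position) * ANGSTROM_TO_BOHR
    r = np.linalg.norm(d, axis=-1)

    rho = par.p_core * par.wavefunction.core_density(r)
    rho = rho + par.p_val * par.kappa**3 * par.wavefunction.valence_density(
        par.kappa * r
    )

    by_l: dict[int, dict[int, float]] = {}
    for (l, m), v in par.p_lm.items():
        if v != 0.0:
            by_l.setdefault(l, {})[m] = v
    if by_l:
        frame = atom._frame_or_raise()
        d_loc = d @ frame  # rows: frame^T d
        kp = par.kappa_prime
        for l, ms in by_l.items():
            ang = np.zeros(len(pts))
            for m, v in ms.items():
                ang += v * harmonics.d_lm_xyz(l, m, d_loc)
            rho = rho + kp**3 * par.radial.radial(l, kp * r) * ang
    return float(rho[0]) if scalar else rho


def moments_racah(atom: Pseudoatom, max_l: int = MAX_L) -> list[np.ndarray]:
    """Spherical-tensor (Racah) multipole moments of the *total* charge
    density (nucleus + electrons) in the global frame, e * Bohr^l.

    Returns one array per l with entries ordered m = -l..l.
    """
    if max_l > MAX_L:
        raise ValueError(f"max_l = {max_l} exceeds the supported order {MAX_L}")
    par = atom.parameters
    out = [np.zeros(2 * l + 1) for l in range(max_l + 1)]
    out[0][0] = par.net_charge
    by_l: dict[int, np.ndarray] = {}
    for (l, m), v in par.p_lm.items():
        if 1 <= l <= max_l and v != 0.0:
            by_l.setdefault(l, np.zeros(2 * l + 1))[m + l] = v
    if by_l:
        frame = atom._frame_or_raise()
        for l, plm in by_l.items():
            rl = par.radial.r_l_expectation(l, par.kappa_prime)
            local = np.array(
                [
                    -harmonics.density_normalization(l, m - l)
                    * harmonics.racah_norm(l)
                    * rl
                    * plm[m]
                    for m in range(2 * l + 1)
                ]
            )
            out[l] = harmonics.rotate_coeffs(l, frame, local)
    return out


def atomic_multipole_moments(atom: Pseudoatom, max_l: int = MAX_L) -> dict:
    """Public moments in e * Angstrom^l, keyed by (l, m), global frame."""
    mom = moments_racah(atom, max_l)
    return {
        (l, m - l): mom[l][m] * BOHR_TO_ANGSTROM**l
        for l in range(max_l + 1)
        for m in range(2 * l + 1)
    }


def molecular_charge(model: MolecularDensityModel) -> float:
    """Sum of atomic monopoles (e)."""
    return float(sum(a.parameters.net_charge for a in model.atoms))


# ---------------------------------------------------------------------------
# JSON round trip for transferred (and scaled) models


def model_to_dict(model: MolecularDensityModel) -> dict:
    atoms = []
    for a in model.atoms:
        p = a.parameters
        atoms.append(
            {
                "element": p.element,
                "label": a.label,
                "position": [float(x) for x in a.position],
                "p_core": p.p_core,
                "p_val": p.p_val,
                "kappa": p.kappa,
                "kappa_prime": p.kappa_prime,
                "zeta": p.radial.zeta,
                "n_of_l": list(p.radial.n_of_l),
                "p_lm": [[l, m, v] for (l, m), v in sorted(p.p_lm.items())],
                "frame": None if a.frame is None else [float(x) for x in np.asarray(a.frame).ravel()],
            }
        )
    return {"format": "epmm-model-1", "label": model.label, "atoms": atoms}


def model_from_dict(data: dict) -> MolecularDensityModel:
    if data.get("format") != "epmm-model-1":
        raise ValueError("not an epmm model file (missing format tag)")
    atoms = []
    for rec in data["atoms"]:
        par = PseudoatomParameters(
            element=rec["element"],
            p_core=rec["p_core"],
            p_val=rec["p_val"],
            kappa=rec["kappa"],
            kappa_prime=rec["kappa_prime"],
            radial=RadialFunctionSpec(rec["zeta"], tuple(rec["n_of_l"])),
            p_lm={(l, m): v for l, m, v in rec["p_lm"]},
        )
        frame = None
        if rec["frame"] is not None:
            frame = np.asarray(rec["frame"], dtype=float).reshape(3, 3)
        atoms.append(Pseudoatom(par, np.asarray(rec["position"]), rec["label"], frame))
    return MolecularDensityModel(atoms, label=data.get("label", ""))


def save_model(model: MolecularDensityModel, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_model(path) -> MolecularDensityModel:
    import json

    with open(path) as fh:
        return model_from_dict(json.load(fh))
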