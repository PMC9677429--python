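"""Synthetic fixtures and independent oracles.

Everything here exists so that every pipeline stage can run and be checked
with no external downloads: a fixture parameter databank, analytic Slater
dimers with closed-form electrostatics, coarse toy "protein-RNA" complexes
that mimic the charge topology of a triphosphate-RNA/metal binding site
(a -4 e triphosphate-bearing first nucleotide, a +2 e cation with three
coordinating waters, -1 e nucleotides, charged and neutral residues), and
a brute-force Coulomb oracle that shares no integration code with the
production energy path.

Toy residues are coarse chemical mimics: correct formal charges, bonding
topology and coordination geometry, not full nucleotide atom graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import pi

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL
from .databank import Databank, read_databank
from .density import (
    MolecularDensityModel,
    Pseudoatom,
    PseudoatomParameters,
    RadialFunctionSpec,
    evaluate_density,
)
from .structure import ResidueId, Structure, StructureAtom
from .transfer import FragmentChargeSpec

__all__ = [
    "ToyComplexSpec",
    "make_fixture_databank",
    "make_slater_dimer",
    "make_toy_complex",
    "brute_force_coulomb_oracle",
]


def make_fixture_databank() -> Databank:
    """The packaged fixture databank (H, C, N, O, P, S, Mg and water types)."""
    with resources.as_file(
        resources.files("epmm.data").joinpath("fixture_databank.txt")
    ) as p:
        return read_databank(p)


# ---------------------------------------------------------------------------
# analytic dimers


def slater_pseudoatom(
    zeta: float,
    n_electrons: float,
    position,
    label: str = "",
    p_lm: dict | None = None,
) -> Pseudoatom:
    """A hydrogen-Z pseudoatom with a pure 1s-Slater valence density of
    exponent ``zeta`` (net charge 1 - n_electrons)."""
    from .wavefunctions import AtomicWavefunctionTable, SlaterShell

    wfn = AtomicWavefunctionTable(
        "H", 1, [SlaterShell("1s", 1, zeta, 1, is_core=False)]
    )
    rad = RadialFunctionSpec(zeta=zeta, n_of_l=(0, 1, 2, 3, 4))
    par = PseudoatomParameters(
        element="H",
        p_core=0.0,
        p_val=n_electrons,
        kappa=1.0,
        kappa_prime=1.0,
        radial=rad,
        p_lm=p_lm or {},
        wavefunction=wfn,
    )
    return Pseudoatom(par, np.asarray(position, dtype=float), label, frame=np.eye(3))


def make_slater_dimer(
    zeta_a: float,
    zeta_b: float,
    separation: float,
    n_electrons_a: float = 1.0,
    n_electrons_b: float = 1.0,
) -> tuple[MolecularDensityModel, MolecularDensityModel]:
    """Two single-atom models with 1s-Slater valence clouds, ``separation``
    Angstrom apart along x."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    a = slater_pseudoatom(zeta_a, n_electrons_a, [0.0, 0.0, 0.0], "dimer/A1:X")
    b = slater_pseudoatom(zeta_b, n_electrons_b, [separation, 0.0, 0.0], "dimer/B1:X")
    return MolecularDensityModel([a], "slater_a"), MolecularDensityModel([b], "slater_b")


# ---------------------------------------------------------------------------
# toy protein-RNA complexes


@dataclass(frozen=True)
class ToyComplexSpec:
    """Composition plan for a toy complex (all placement seed-deterministic)."""

    n_positive_residues: int = 3
    n_negative_residues: int = 2
    n_neutral_residues: int = 3
    include_metal: bool = True
    n_extra_waters: int = 0  # distant waters, excluded from the metal shell
    base_variant: int = 0  # tilts the nucleobase mimic: same site, different "sequence"
    seed: int = 0

    @property
    def n_protein_residues(self) -> int:
        return self.n_positive_residues + self.n_negative_residues + self.n_neutral_residues


_T = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)  # tetrahedral unit directions


def _res(atoms, chain, seq, name, het=False):
    rid = ResidueId(chain, seq, "", name)
    return [
        StructureAtom(nm, el, np.asarray(xyz, float), rid, het=het)
        for nm, el, xyz in atoms
    ]


def _phosphate(center, bridge_dir, tag):
    """P + two terminal O + one bridging O along ``bridge_dir``."""
    c = np.asarray(center, float)
    d = np.asarray(bridge_dir, float)
    d = d / np.linalg.norm(d)
    # build an orthonormal triad around the bridge direction
    ax = np.eye(3)[int(np.argmin(np.abs(d)))]
    u = ax - d * (ax @ d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    t1 = -0.47 * d + 0.88 * u
    t2 = -0.47 * d - 0.44 * u + 0.76 * v
    atoms = [
        (f"P{tag}", "P", c),
        (f"O{tag}1", "O", c + 1.50 * t1),
        (f"O{tag}2", "O", c + 1.50 * t2),
    ]
    bridge_o = c + 1.60 * d
    return atoms, bridge_o


def _toy_nucleotide(origin, direction, seq, with_triphosphate, tilt=0.0):
    """Coarse nucleotide mimic: phosphate(s), ester O, C1' + H, base N.

    ``tilt`` (radians) reorients the base nitrogen about the backbone,
    emulating a different nucleobase in an otherwise identical site.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    atoms = []
    if with_triphosphate:
        # gamma phosphate with an extra terminal O (three total), then
        # P-O-P-O-P chain toward the ester oxygen
        atoms_g, bo1 = _phosphate(o, d, "G")
        atoms_g.append(("OG3", "O", o - 1.50 * d))
        atoms_b, bo2 = _phosphate(bo1 + 1.60 * d, d, "B")
        atoms_a, bo3 = _phosphate(bo2 + 1.60 * d, d, "A")
        atoms += atoms_g + [("OGB", "O", bo1)] + atoms_b + [("OBA", "O", bo2)]
        atoms += atoms_a + [("OE", "O", bo3)]
        ester_o = bo3
    else:
        atoms_a, bo = _phosphate(o, d, "A")
        atoms += atoms_a + [("OE", "O", bo)]
        ester_o = bo
    c1 = ester_o + 1.43 * d
    up = np.cos(tilt) * np.array([0.0, 0.0, 1.0]) + np.sin(tilt) * np.cross([0.0, 0.0, 1.0], d)
    n1 = c1 + 1.47 * (0.5 * d + 0.866 * up)
    h1 = c1 + 1.00 * (0.5 * d - 0.866 * np.array([0.0, 0.0, 1.0]))
    atoms += [("C1'", "C", c1), ("H1'", "H", h1), ("N1", "N", n1)]
    name = "NTP" if with_triphosphate else "NMP"
    return _res(atoms, "R", seq, name)


def _toy_residue(kind, center, toward, chain, seq):
    """Coarse amino-acid mimics: LYP (+1 ammonium), ASM (-1 carboxylate),
    SEN (0 hydroxyl)."""
    c = np.asarray(center, float)
    d = np.asarray(toward, float)
    d = d / np.linalg.norm(d)
    ax = np.eye(3)[int(np.argmin(np.abs(d)))]
    u = ax - d * (ax @ d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    if kind == "LYP":
        n = c
        atoms = [
            ("NZ", "N", n),
            ("HZ1", "H", n + 1.03 * (0.33 * d + 0.94 * u)),
            ("HZ2", "H", n + 1.03 * (0.33 * d - 0.47 * u + 0.82 * v)),
            ("HZ3", "H", n + 1.03 * (0.33 * d - 0.47 * u - 0.82 * v)),
            ("CE", "C", n - 1.49 * d),
            ("HE", "H", n - 1.49 * d - 1.00 * u),
        ]
        return _res(atoms, chain, seq, "LYP")
    if kind == "ASM":
        cg = c
        atoms = [
            ("CG", "C", cg),
            ("OD1", "O", cg + 1.25 * (0.50 * d + 0.87 * u)),
            ("OD2", "O", cg + 1.25 * (0.50 * d - 0.87 * u)),
            ("CB", "C", cg - 1.52 * d),
            ("HB", "H", cg - 1.52 * d - 1.00 * v),
        ]
        return _res(atoms, chain, seq, "ASM")
    if kind == "SEN":
        og = c
        atoms = [
            ("OG", "O", og),
            ("HG", "H", og + 0.96 * (0.40 * d + 0.92 * u)),
            ("CB", "C", og - 1.42 * d),
            ("HB", "H", og - 1.42 * d - 1.00 * v),
        ]
        return _res(atoms, chain, seq, "SEN")
    raise ValueError(f"unknown toy residue kind {kind!r}")


def _water(center, away, chain, seq):
    c = np.asarray(center, float)
    d = np.asarray(away, float)
    d = d / np.linalg.norm(d)
    ax = np.eye(3)[int(np.argmin(np.abs(d)))]
    u = ax - d * (ax @ d)
    u /= np.linalg.norm(u)
    h1 = c + 0.96 * (np.cos(0.912) * d + np.sin(0.912) * u)
    h2 = c + 0.96 * (np.cos(0.912) * d - np.sin(0.912) * u)
    return _res([("O", "O", c), ("H1", "H", h1), ("H2", "H", h2)], chain, seq, "HOH", het=True)


def make_toy_complex(
    spec: ToyComplexSpec | None = None,
) -> tuple[Structure, list[FragmentChargeSpec]]:
    """Build a toy protein-RNA complex and its formal-charge plan.

    RNA chain R: residue 1 a triphosphate nucleotide (formal -4 e), residues
    2-3 monophosphate nucleotides (-1 e each); a Mg cation (+2 e) coordinated
    by three waters at 2.1 A sits next to the gamma-phosphate.  Protein
    chain A residues are placed on a 3-12 A shell around the first RNA
    fragment, the first +1 residue closest.  Placement directions come from
    integer-grid draws (seeded) converted to floats, so coordinates are
    platform-independent and bit-reproducible per seed.
    """
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)
    backbone = np.array([1.0, 0.0, 0.0])
    structure = Structure()
    fragments: list[FragmentChargeSpec] = []

    tilt = 0.15 * spec.base_variant
    nt1 = _toy_nucleotide([0.0, 0.0, 0.0], backbone, 1, with_triphosphate=True, tilt=tilt)
    nt2 = _toy_nucleotide([9.5, 2.0, 0.0], backbone, 2, with_triphosphate=False, tilt=tilt)
    nt3 = _toy_nucleotide([16.0, 4.0, 0.0], backbone, 3, with_triphosphate=False, tilt=tilt)
    structure.atoms += nt1 + nt2 + nt3

    frag1_res = {("R", 1, "")}
    if spec.include_metal:
        # Mg near the terminal gamma-phosphate oxygens, waters on the far side
        og1 = next(a.position for a in nt1 if a.name == "OG1")
        og2 = next(a.position for a in nt1 if a.name == "OG2")
        pg = next(a.position for a in nt1 if a.name == "PG")
        mid = 0.5 * (og1 + og2)
        out_dir = mid - pg
        out_dir /= np.linalg.norm(out_dir)
        mg = mid + 1.20 * out_dir
        structure.atoms += _res([("MG", "Mg", mg)], "M", 201, "MG", het=True)
        frag1_res.add(("M", 201, ""))
        water_dirs = [
            out_dir,
            np.cross(out_dir, [0.0, 0.0, 1.0]),
            -np.cross(out_dir, [0.0, 0.0, 1.0]),
        ]
        for k, wd in enumerate(water_dirs):
            wd = np.asarray(wd) / np.linalg.norm(wd)
            structure.atoms += _water(mg + 2.10 * wd, wd, "M", 202 + k)
            frag1_res.add(("M", 202 + k, ""))
        for k in range(spec.n_extra_waters):
            far = mg + np.array([0.0, 0.0, 8.0 + 2.0 * k])
            structure.atoms += _water(far, [0.0, 0.0, 1.0], "M", 210 + k)
    frag1_charge = -4.0 + (2.0 if spec.include_metal else 0.0)
    fragments.append(FragmentChargeSpec("rna_fragment1", frag1_charge, frozenset(frag1_res)))
    fragments.append(FragmentChargeSpec("rna_fragment2", -1.0, frozenset({("R", 2, "")})))
    fragments.append(FragmentChargeSpec("rna_fragment3", -1.0, frozenset({("R", 3, "")})))

    # protein residues on a shell around fragment 1, +1 kinds first (closest)
    frag1_pos = np.array([a.position for a in structure.atoms if a.residue.key() in frag1_res])
    centroid = frag1_pos.mean(axis=0)
    kinds = (
        ["LYP"] * spec.n_positive_residues
        + ["ASM"] * spec.n_negative_residues
        + ["SEN"] * spec.n_neutral_residues
    )
    charges = {"LYP": 1.0, "ASM": -1.0, "SEN": 0.0}
    for i, kind in enumerate(kinds):
        # integer-grid draws: direction from a 24x12 az/el lattice
        az = int(rng.integers(0, 24)) * 2 * pi / 24
        el = (int(rng.integers(1, 12)) - 6) * pi / 13
        d = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
        target = 3.0 + 9.0 * i / max(len(kinds) - 1, 1)  # 3..12 A from the surface
        pos = centroid + d
        step = 0.5 * d
        placed = np.array([a.position for a in structure.atoms])
        while True:
            res_atoms = _toy_residue(kind, pos, -d, "A", 10 + i)
            res_pos = np.array([a.position for a in res_atoms])
            far_enough = np.min(np.linalg.norm(frag1_pos - pos, axis=1)) >= target
            # no atom closer than 2.0 A to anything already placed: keeps
            # bonding topology within residues regardless of the seed
            clash_free = (
                np.min(
                    np.linalg.norm(placed[:, None, :] - res_pos[None, :, :], axis=-1)
                )
                >= 2.0
            )
            if far_enough and clash_free:
                break
            pos = pos + step
        structure.atoms += res_atoms
        fragments.append(
            FragmentChargeSpec(
                f"res_{kind}_{10 + i}", charges[kind], frozenset({("A", 10 + i, "")})
            )
        )
    if spec.n_extra_waters and spec.include_metal:
        for k in range(spec.n_extra_waters):
            fragments.append(
                FragmentChargeSpec(f"water_far_{k}", 0.0, frozenset({("M", 210 + k, "")}))
            )
    total_plan = sum(f.formal_charge for f in fragments)
    expected = frag1_charge - 2.0 + spec.n_positive_residues - spec.n_negative_residues
    if abs(total_plan - expected) > 1e-9:
        raise ValueError("inconsistent toy-complex charge plan")
    return structure, fragments


# ---------------------------------------------------------------------------
# brute-force Coulomb oracle


def _is_spherical(atom: Pseudoatom) -> bool:
    return not atom.parameters.has_aspherical_terms()


def _radial_density(atom: Pseudoatom, r_bohr: np.ndarray) -> np.ndarray:
    probe = atom.position + np.outer(r_bohr * BOHR_TO_ANGSTROM, [0.0, 0.0, 1.0])
    return np.asarray(evaluate_density(atom, probe))


def _oracle_potential_table(atom: Pseudoatom, n_grid: int):
    """Electron potential V(r) of a spherical pseudoatom on a dense log grid,
    by cumulative-trapezoid shell integration (independent of the analytic
    incomplete-gamma route)."""
    r = np.geomspace(1e-6, 80.0, n_grid)
    rho = _radial_density(atom, r)
    inner = cumulative_trapezoid(rho * r * r, r, initial=0.0)
    outer_full = np.trapezoid(rho * r, r)
    outer = outer_full - cumulative_trapezoid(rho * r, r, initial=0.0)
    v = 4.0 * pi * (inner / r + outer)
    return r, v


def _pair_energy_spherical(a: Pseudoatom, b: Pseudoatom, n_grid: int) -> float:
    """Hartree pair energy by spherical-shell averaging on dense grids."""
    ra = a.position * ANGSTROM_TO_BOHR
    rb = b.position * ANGSTROM_TO_BOHR
    big_r = float(np.linalg.norm(ra - rb))
    r_a, v_a = _oracle_potential_table(a, n_grid)
    e_nn = a.parameters.z * b.parameters.z / big_r
    e_ne = -b.parameters.z * np.interp(big_r, r_a, v_a)
    r_b, v_b = _oracle_potential_table(b, n_grid)
    e_en = -a.parameters.z * np.interp(big_r, r_b, v_b)
    # e-e: integrate b's shells against the spherical average of V_a
    rho_b = _radial_density(b, r_b)
    u = np.geomspace(1e-6, 80.0, n_grid)
    vu = np.interp(u, r_a, v_a)
    cum_uv = cumulative_trapezoid(u * vu, u, initial=0.0)

    def avg_va(s):
        lo, hi = np.abs(big_r - s), big_r + s
        seg = np.interp(hi, u, cum_uv) - np.interp(lo, u, cum_uv)
        return seg / (2.0 * s * big_r)

    vbar = avg_va(r_b)
    e_ee = np.trapezoid(4.0 * pi * r_b**2 * rho_b * vbar, r_b)
    return float(e_nn + e_ne + e_en + e_ee)


def _pair_energy_double_grid(a: Pseudoatom, b: Pseudoatom, n_radial, n_angular) -> float:
    """Hartree pair energy by direct double-grid point-pair summation."""
    from .grids import atom_grid

    e = a.parameters.z * b.parameters.z / (
        np.linalg.norm((a.position - b.position)) * ANGSTROM_TO_BOHR
    )
    pts_a, w_a = atom_grid(a.parameters.element, n_radial, n_angular)
    pts_b, w_b = atom_grid(b.parameters.element, n_radial, n_angular)
    xa = pts_a + a.position * ANGSTROM_TO_BOHR
    xb = pts_b + b.position * ANGSTROM_TO_BOHR
    qa = w_a * np.asarray(evaluate_density(a, xa * BOHR_TO_ANGSTROM))
    qb = w_b * np.asarray(evaluate_density(b, xb * BOHR_TO_ANGSTROM))
    # nucleus-electron attractions
    e -= a.parameters.z * np.sum(qb / np.linalg.norm(xb - a.position * ANGSTROM_TO_BOHR, axis=1))
    e -= b.parameters.z * np.sum(qa / np.linalg.norm(xa - b.position * ANGSTROM_TO_BOHR, axis=1))
    from scipy.spatial.distance import cdist

    for chunk in np.array_split(np.arange(len(xa)), max(1, len(xa) // 200)):
        d = cdist(xa[chunk], xb)
        e += np.sum(qa[chunk, None] * qb[None, :] / d)
    return float(e)


def brute_force_coulomb_oracle(
    model_a: MolecularDensityModel,
    model_b: MolecularDensityModel,
    n_grid: int = 20000,
    method: str = "auto",
) -> float:
    """Independent Coulomb interaction energy (kcal/mol) of two small models.

    ``method='spherical'`` (dense-log-grid shell integration, high accuracy)
    requires all atoms spherical; ``'double-grid'`` handles aspherical
    densities by direct point-pair summation (looser accuracy); ``'auto'``
    picks per model pair.  Models are capped at 10 atoms each.
    """
    if len(model_a) > 10 or len(model_b) > 10:
        raise ValueError("oracle models are capped at 10 atoms each")
    spherical = all(_is_spherical(at) for at in model_a) and all(
        _is_spherical(at) for at in model_b
    )
    if method == "auto":
        method = "spherical" if spherical else "double-grid"
    if method == "spherical" and not spherical:
        raise ValueError("spherical oracle requested for an aspherical model")
    e = 0.0
    for at_a in model_a:
        for at_b in model_b:
            if method == "spherical":
                e += _pair_energy_spherical(at_a, at_b, n_grid)
            else:
                n_rad = max(40, n_grid // 400)
                e += _pair_energy_double_grid(at_a, at_b, n_rad, 288)
    return e * HARTREE_TO_KCALMOL
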