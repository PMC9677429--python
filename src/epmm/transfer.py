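"""Databank transfer: bonds, hydrogen extension, atom typing, charge scaling.

Reproduces the two-pass transfer protocol used for macromolecules: a first
bond-detection pass with the Mg covalent radius overridden to 0.01 A (so
Mg-O coordination contacts never count as X-H parents) during which X-H
bonds are extended to neutron distances, and a second pass with the default
Mg radius (1.36 A) for chemical-environment typing and parameter transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .constants import ATOMIC_MASSES, COVALENT_RADII
from .databank import Databank, DatabankEntry
from .density import MolecularDensityModel, Pseudoatom
from .structure import Structure, StructureAtom

__all__ = [
    "CovalentRadiiTable",
    "FragmentChargeSpec",
    "detect_bonds",
    "extend_hydrogens",
    "assign_atom_types",
    "resolve_local_frame",
    "build_density_model",
    "transfer_parameters",
    "scale_fragment_charges",
    "default_neutron_distances",
]

MG_RADIUS_SUPPRESS = 0.01  # Angstrom: removes Mg-O bonds in the H-extension pass
MG_RADIUS_DEFAULT = 1.36  # Angstrom: restores Mg coordination in the typing pass
DEFAULT_BOND_TOLERANCE = 0.4  # Angstrom


@dataclass
class CovalentRadiiTable:
    radii: dict[str, float] = field(default_factory=lambda: dict(COVALENT_RADII))
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for el, r in {**self.radii, **self.overrides}.items():
            if r <= 0:
                raise ValueError(f"non-positive covalent radius for {el}: {r}")

    def radius(self, element: str) -> float:
        if element in self.overrides:
            return self.overrides[element]
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(f"no covalent radius for element {element!r}") from None


@dataclass
class FragmentChargeSpec:
    """A set of residues (or explicit atom indices) with a formal charge."""

    name: str
    formal_charge: float
    residues: frozenset = frozenset()  # of ResidueId.key() tuples
    atom_indices: frozenset = frozenset()

    def selects(self, atom: StructureAtom, index: int) -> bool:
        return index in self.atom_indices or atom.residue.key() in self.residues


def default_neutron_distances() -> dict[str, float]:
    with resources.files("epmm.data").joinpath("neutron_distances.yaml").open() as fh:
        return yaml.safe_load(fh)


def detect_bonds(
    structure: Structure,
    radii: CovalentRadiiTable | None = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> list[tuple[int, int]]:
    """Distance-based bond list: i-j bonded iff d <= r_i + r_j + tolerance."""
    radii = radii or CovalentRadiiTable()
    pos = structure.positions()
    if len(pos) == 0:
        return []
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite coordinates")
    r = np.array([radii.radius(a.element) for a in structure.atoms])
    tree = cKDTree(pos)
    cutoff = 2 * r.max() + tolerance
    bonds = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d == 0.0:
            raise ValueError(
                f"coincident atoms {structure.atoms[i].label} and "
                f"{structure.atoms[j].label}"
            )
        if d <= r[i] + r[j] + tolerance:
            bonds.append((i, j))
    return bonds


def _neighbor_map(n_atoms: int, bonds: list[tuple[int, int]]) -> list[list[int]]:
    nb: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        nb[i].append(j)
        nb[j].append(i)
    return nb


def extend_hydrogens(
    structure: Structure,
    bonds: list[tuple[int, int]],
    distances: dict[str, float] | None = None,
) -> Structure:
    """Move each H along its existing X-H unit vector to the neutron distance."""
    distances = distances or default_neutron_distances()
    nb = _neighbor_map(len(structure), bonds)
    out = structure.copy()
    for i, a in enumerate(structure.atoms):
        if a.element != "H":
            continue
        heavy = [j for j in nb[i] if structure.atoms[j].element != "H"]
        if len(heavy) != 1:
            raise ValueError(
                f"hydrogen {a.label} has {len(heavy)} bonded heavy atoms "
                "(exactly one required)"
            )
        parent = structure.atoms[heavy[0]]
        target = distances.get(parent.element)
        if target is None:
            raise KeyError(
                f"no neutron X-H distance tabulated for element {parent.element!r} "
                f"(hydrogen {a.label})"
            )
        v = a.position - parent.position
        out.atoms[i].position = parent.position + v / np.linalg.norm(v) * target
    return out


def assign_atom_types(
    structure: Structure,
    bonds: list[tuple[int, int]],
    bank: Databank,
) -> list[DatabankEntry]:
    """Per-atom databank entry, most specific match first; errors are collected."""
    nb = _neighbor_map(len(structure), bonds)
    entries = []
    missing = []
    for i, a in enumerate(structure.atoms):
        neighbors = [structure.atoms[j].element for j in nb[i]]
        try:
            entries.append(bank.lookup(a.element, neighbors))
        except KeyError:
            missing.append(f"{a.label} ({a.element}, neighbors {sorted(neighbors)})")
            entries.append(None)
    if missing:
        raise KeyError("atoms without a databank match: " + "; ".join(missing))
    return entries


def _mass(element: str) -> float:
    return ATOMIC_MASSES.get(element, 0.0)


def resolve_local_frame(
    structure: Structure, index: int, neighbors: list[int]
) -> np.ndarray | None:
    """Atom-local axes: z toward the heaviest bonded neighbor, x toward the
    next one (Gram-Schmidt); terminal atoms get a canonical perpendicular,
    isolated atoms no frame.

    Neighbor ranking is (mass desc, distance asc, name) so the frame is
    deterministic and independent of atom input order.
    """
    a = structure.atoms[index]
    if not neighbors:
        return None
    ranked = sorted(
        neighbors,
        key=lambda j: (
            -_mass(structure.atoms[j].element),
            float(np.linalg.norm(structure.atoms[j].position - a.position)),
            structure.atoms[j].name,
        ),
    )
    z = structure.atoms[ranked[0]].position - a.position
    z = z / np.linalg.norm(z)
    x = None
    for j in ranked[1:]:
        v = structure.atoms[j].position - a.position
        v = v - z * (v @ z)
        if np.linalg.norm(v) > 1e-8:
            x = v / np.linalg.norm(v)
            break
    if x is None:
        # canonical rule for terminal atoms: global axis least parallel to z
        axis = np.eye(3)[int(np.argmin(np.abs(z)))]
        v = axis - z * (axis @ z)
        x = v / np.linalg.norm(v)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def build_density_model(
    structure: Structure,
    entries: list[DatabankEntry],
    bonds: list[tuple[int, int]],
    label: str = "",
) -> MolecularDensityModel:
    nb = _neighbor_map(len(structure), bonds)
    atoms = []
    for i, (a, e) in enumerate(zip(structure.atoms, entries)):
        atoms.append(
            Pseudoatom(
                parameters=e.parameters.copy(),
                position=a.position.copy(),
                label=a.label,
                frame=resolve_local_frame(structure, i, nb[i]),
            )
        )
    return MolecularDensityModel(atoms, label=label)


def transfer_parameters(
    structure: Structure,
    bank: Databank,
    *,
    extend_h: bool = True,
    neutron_distances: dict[str, float] | None = None,
    radii: CovalentRadiiTable | None = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> tuple[MolecularDensityModel, Structure]:
    """Two-pass transfer; returns the density model and the (H-extended) structure."""
    base = radii or CovalentRadiiTable()
    if extend_h:
        pass1 = CovalentRadiiTable(dict(base.radii), {**base.overrides, "Mg": MG_RADIUS_SUPPRESS})
        bonds1 = detect_bonds(structure, pass1, tolerance)
        structure = extend_hydrogens(structure, bonds1, neutron_distances)
    pass2 = CovalentRadiiTable(dict(base.radii), {**base.overrides, "Mg": MG_RADIUS_DEFAULT})
    bonds2 = detect_bonds(structure, pass2, tolerance)
    entries = assign_atom_types(structure, bonds2, bank)
    model = build_density_model(structure, entries, bonds2)
    return model, structure


def scale_fragment_charges(
    model: MolecularDensityModel,
    structure: Structure,
    specs: list[FragmentChargeSpec],
    mode: str = "proportional",
) -> MolecularDensityModel:
    """Adjust P_val within each fragment so its modeled charge equals the
    formal one exactly.

    ``mode='proportional'`` distributes the shift proportionally to each
    atom's current P_val (preserving relative valence populations);
    ``'uniform'`` shifts every atom equally.  P_lm, kappa, kappa' untouched.
    """
    if mode not in ("proportional", "uniform"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if len(model.atoms) != len(structure.atoms):
        raise ValueError("model and structure atom counts differ")
    assigned = np.full(len(model.atoms), -1)
    for k, spec in enumerate(specs):
        for i, a in enumerate(structure.atoms):
            if spec.selects(a, i):
                if assigned[i] >= 0:
                    raise ValueError(
                        f"atom {a.label} selected by both fragment "
                        f"{specs[assigned[i]].name!r} and {spec.name!r}"
                    )
                assigned[i] = k
    if np.any(assigned < 0):
        orphans = [structure.atoms[i].label for i in np.where(assigned < 0)[0]]
        raise ValueError("atoms in no fragment: " + ", ".join(orphans[:10]))

    out = MolecularDensityModel([
        Pseudoatom(a.parameters.copy(), a.position.copy(), a.label, a.frame)
        for a in model.atoms
    ], label=model.label)
    for k, spec in enumerate(specs):
        idx = np.where(assigned == k)[0]
        charge = sum(out.atoms[i].parameters.net_charge for i in idx)
        shift = charge - spec.formal_charge  # electrons to add to sum(P_val)
        if abs(shift) < 1e-14:
            continue
        pv = np.array([out.atoms[i].parameters.p_val for i in idx])
        if mode == "proportional":
            total = pv.sum()
            if total == 0:
                raise ValueError(
                    f"fragment {spec.name!r} has zero total P_val; cannot scale "
                    f"to {spec.formal_charge} e proportionally"
                )
            new_pv = pv * (1.0 + shift / total)
        else:
            new_pv = pv + shift / len(pv)
        for i, v in zip(idx, new_pv):
            out.atoms[i].parameters.p_val = float(v)
    return out
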