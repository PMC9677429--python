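"""Macromolecular structure container and PDB I/O (via gemmi).

Only what the transfer/energy pipeline needs is kept per atom; residues are
identified by (chain, residue number, insertion code).  Alternate locations
are resolved at read time (highest occupancy by default, or an explicit
conformer letter for cases like a nucleobase disordered over two
conformations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

WATER_NAMES = {"HOH", "WAT"}


@dataclass(frozen=True)
class ResidueId:
    chain: str
    seqnum: int
    icode: str = ""
    name: str = ""

    def key(self) -> tuple:
        return (self.chain, self.seqnum, self.icode)

    def __str__(self) -> str:
        return f"{self.chain}/{self.name}{self.seqnum}{self.icode}"


@dataclass
class StructureAtom:
    name: str
    element: str
    position: np.ndarray  # Angstrom
    residue: ResidueId
    serial: int = 0
    occupancy: float = 1.0
    altloc: str = ""
    het: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def label(self) -> str:
        return f"{self.residue}:{self.name}"

    def copy(self) -> "StructureAtom":
        return replace(self, position=self.position.copy())


@dataclass
class Structure:
    atoms: list[StructureAtom] = field(default_factory=list)
    title: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def residues(self) -> dict[tuple, list[int]]:
        """Atom indices grouped by residue, in first-appearance order."""
        out: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue.key(), []).append(i)
        return out

    def residue_ids(self) -> list[ResidueId]:
        seen: dict[tuple, ResidueId] = {}
        for a in self.atoms:
            seen.setdefault(a.residue.key(), a.residue)
        return list(seen.values())

    def chains(self) -> list[str]:
        out = []
        for a in self.atoms:
            if a.residue.chain not in out:
                out.append(a.residue.chain)
        return out

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], self.title)


def read_pdb(path, altloc: str | None = None) -> Structure:
    """Read a (protonated) PDB file.

    ``altloc``: None selects the highest-occupancy conformer of each
    disordered atom; a letter selects that conformer where present.
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    out = Structure()
    model = st[0]
    for chain in model:
        for res in chain:
            rid = ResidueId(chain.name, res.seqid.num, res.seqid.icode.strip(), res.name)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, alts in by_name.items():
                if len(alts) == 1:
                    pick = alts[0]
                elif altloc:
                    chosen = [a for a in alts if a.altloc == altloc]
                    pick = chosen[0] if chosen else max(alts, key=lambda a: a.occ)
                else:
                    pick = max(alts, key=lambda a: a.occ)
                out.atoms.append(
                    StructureAtom(
                        name=name,
                        element=pick.element.name,
                        position=np.array([pick.pos.x, pick.pos.y, pick.pos.z]),
                        residue=rid,
                        serial=pick.serial,
                        occupancy=pick.occ,
                        altloc=pick.altloc.strip(),
                        het=res.het_flag == "H",
                    )
                )
    return out


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as a minimal PDB file (deterministic byte layout)."""
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title.upper():<69}"[:80].rstrip())
    serial = 0
    for a in structure.atoms:
        serial += 1
        record = "HETATM" if a.het else "ATOM  "
        name = a.name
        # PDB column rules: element symbols of one letter start in column 14
        if len(name) < 4 and len(a.element) == 1:
            name = f" {name}"
        x, y, z = a.position
        lines.append(
            f"{record}{serial:>5d} {name:<4s}{'':1s}{a.residue.name:>3s} "
            f"{a.residue.chain:1s}{a.residue.seqnum:>4d}{a.residue.icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
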