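"""Per-residue binding-site analysis of a protein-RNA complex.

The workflow mirrors a charge-density study of a triphosphate-RNA
recognition site: partition the first three RNA residues into interaction
fragments (the first one absorbing the metal cation and its coordinating
waters), compute per-residue x per-fragment electrostatic energies with
the EPMM hybrid, then apply three binding-site filters -- a 5 A distance
cutoff, a +/-5 kcal/mol interaction-energy significance filter, and a
penetration-energy filter that flags residues in genuinely short contact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .density import MolecularDensityModel
from .energy import epmm_energy
from .grids import QuadratureSpec
from .structure import ResidueId, Structure, WATER_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentPartition",
    "BindingSiteReport",
    "SequenceComparisonSummary",
    "partition_fragments",
    "select_binding_site",
    "residue_energy_table",
    "compare_sequences",
]

METAL_COORDINATION_CUTOFF = 2.6  # Angstrom, metal-O first coordination shell
DISTANCE_CUTOFF = 5.0
SIGNIFICANCE_THRESHOLD = 5.0  # kcal/mol, strict > in absolute value
PENETRATION_THRESHOLD = 2.0  # kcal/mol, |e_pen| >= threshold


@dataclass
class FragmentPartition:
    """Atom-index partition: three RNA fragments + per-residue protein list."""

    rna_fragments: list[list[int]]
    protein_residues: list[tuple[ResidueId, list[int]]]
    metal_index: int | None = None
    water_residues: list[ResidueId] = field(default_factory=list)

    def rna_atom_indices(self) -> list[int]:
        return [i for frag in self.rna_fragments for i in frag]


def _chain_residues(structure: Structure, chain: str) -> list[tuple[ResidueId, list[int]]]:
    grouped = structure.residues()
    ids = {r.key(): r for r in structure.residue_ids()}
    return [(ids[k], idx) for k, idx in grouped.items() if k[0] == chain]


def _autodetect_chains(structure: Structure, metal_element: str):
    """RNA chain = the one whose first residue carries >= 2 phosphorus atoms;
    protein chain = the non-water, non-metal chain with the most residues."""
    rna = protein = None
    for ch in structure.chains():
        residues = _chain_residues(structure, ch)
        if not residues:
            continue
        if all(r.name in WATER_NAMES or r.name == metal_element.upper() for r, _ in residues):
            continue
        first_p = sum(
            1 for i in residues[0][1] if structure.atoms[i].element == "P"
        )
        if first_p >= 2 and rna is None:
            rna = ch
        elif protein is None or len(residues) > len(_chain_residues(structure, protein)):
            protein = ch
    return rna, protein


def partition_fragments(
    structure: Structure,
    metal_element: str = "Mg",
    n_rna_residues: int = 3,
    rna_chain: str | None = None,
    protein_chain: str | None = None,
    coordination_cutoff: float = METAL_COORDINATION_CUTOFF,
) -> FragmentPartition:
    """Partition a complex into the three RNA interaction fragments and
    protein residues.

    Fragment 1 is the first (triphosphate) nucleotide plus the metal cation
    and the waters in its first coordination shell (metal-O distance <=
    ``coordination_cutoff``); fragments 2-3 are the next nucleotides.
    """
    auto_rna, auto_protein = _autodetect_chains(structure, metal_element)
    rna_chain = rna_chain or auto_rna
    protein_chain = protein_chain or auto_protein
    if rna_chain is None:
        raise ValueError("no RNA chain found (no chain starts with a polyphosphate residue)")
    if protein_chain is None:
        raise ValueError("no protein chain found")
    rna_residues = _chain_residues(structure, rna_chain)
    if len(rna_residues) < n_rna_residues:
        raise ValueError(
            f"RNA chain {rna_chain!r} has {len(rna_residues)} residues; "
            f"{n_rna_residues} required"
        )
    fragments = [list(idx) for _, idx in rna_residues[:n_rna_residues]]

    metal_idx = None
    for i, a in enumerate(structure.atoms):
        if a.element.capitalize() == metal_element.capitalize():
            metal_idx = i
            break
    waters: list[ResidueId] = []
    if metal_idx is None:
        logger.warning("no %s cation present; fragment 1 is the bare first nucleotide",
                       metal_element)
    else:
        fragments[0].append(metal_idx)
        mpos = structure.atoms[metal_idx].position
        candidates = []
        for rid, idx in structure.residues().items():
            res = structure.atoms[idx[0]].residue
            if res.name not in WATER_NAMES:
                continue
            o_dist = min(
                float(np.linalg.norm(structure.atoms[i].position - mpos))
                for i in idx
                if structure.atoms[i].element == "O"
            )
            if o_dist <= coordination_cutoff:
                candidates.append((o_dist, res, idx))
        if len(candidates) > 3:
            listing = ", ".join(
                    f"{r} at {d:.2f} A"
                    for d, r, _ in sorted(candidates, key=lambda c: c[0])
                )
            raise ValueError(
                f"more than three waters coordinate the metal: {listing}"
            )
        for _, res, idx in sorted(candidates, key=lambda c: c[0]):
            fragments[0].extend(idx)
            waters.append(res)

    protein = _chain_residues(structure, protein_chain)
    if not protein:
        raise ValueError(f"protein chain {protein_chain!r} has no residues")
    return FragmentPartition(
        rna_fragments=fragments,
        protein_residues=protein,
        metal_index=metal_idx,
        water_residues=waters,
    )


def select_binding_site(
    structure: Structure,
    partition: FragmentPartition,
    cutoff: float = DISTANCE_CUTOFF,
) -> list[ResidueId]:
    """Protein residues with ANY atom (hydrogens included) within ``cutoff``
    of ANY atom of the three RNA fragments (closed interval)."""
    rna_pos = structure.positions()[partition.rna_atom_indices()]
    tree = cKDTree(rna_pos)
    out = []
    for rid, idx in partition.protein_residues:
        d, _ = tree.query(structure.positions()[idx], k=1)
        if np.min(d) <= cutoff:
            out.append(rid)
    return out


@dataclass
class BindingSiteReport:
    """Per-residue x per-fragment energy table plus the three filters."""

    table: pd.DataFrame  # index residue str, columns (fragment, e_mm|e_epmm|e_pen)
    within_5a: list[str]
    significant: list[str]
    strong_penetration: list[str]
    cutoff: float
    significance_threshold: float
    penetration_threshold: float
    fragment_names: list[str]
    label: str = ""

    def totals(self, residues: list[str] | None = None) -> pd.DataFrame:
        """Per-fragment E_MM / E_EPMM / E_pen totals (kcal/mol) over all
        residues or a subset."""
        t = self.table if residues is None else self.table.loc[residues]
        return t.sum(axis=0).unstack(level="energy")

    def binding_site_totals(self) -> pd.DataFrame:
        return self.totals(self.within_5a)

    def long_table(self) -> pd.DataFrame:
        """Tidy CSV layout: residue_id, fragment_id, e_mm, e_epmm, e_pen."""
        rows = []
        for res in self.table.index:
            for frag in self.fragment_names:
                rows.append(
                    {
                        "residue_id": res,
                        "fragment_id": frag,
                        "e_mm": self.table.loc[res, (frag, "e_mm")],
                        "e_epmm": self.table.loc[res, (frag, "e_epmm")],
                        "e_pen": self.table.loc[res, (frag, "e_pen")],
                    }
                )
        return pd.DataFrame(rows)

    def manifest(self, quad: QuadratureSpec, databank_version: str = "") -> dict:
        from .constants import BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL

        return {
            "label": self.label,
            "n_residues": len(self.table),
            "fragments": self.fragment_names,
            "filters": {
                "distance_cutoff_A": self.cutoff,
                "significance_kcal": self.significance_threshold,
                "penetration_kcal": self.penetration_threshold,
            },
            "counts": {
                "within_5A": len(self.within_5a),
                "significant": len(self.significant),
                "strong_penetration": len(self.strong_penetration),
            },
            "quadrature": {
                "n_radial": quad.n_radial,
                "n_angular": quad.n_angular,
                "n_angular_actual": quad.n_angular_actual,
                "rcrit_A": quad.rcrit,
                "scheme": quad.integration_scheme_id,
            },
            "constants": {
                "bohr_A": BOHR_TO_ANGSTROM,
                "hartree_kcalmol": HARTREE_TO_KCALMOL,
            },
        }

    def write(self, csv_path, manifest_path=None, quad: QuadratureSpec | None = None,
              databank_version: str = "") -> None:
        self.long_table().to_csv(csv_path, index=False)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest(quad or QuadratureSpec(), databank_version),
                          fh, indent=2, sort_keys=True)
                fh.write("\n")


def _check_scaled(model: MolecularDensityModel, partition: FragmentPartition):
    """Refuse to run on an unscaled model: every fragment and residue must
    sit at an integral formal charge after databank transfer + scaling."""
    groups = list(partition.rna_fragments) + [idx for _, idx in partition.protein_residues]
    for idx in groups:
        q = sum(model.atoms[i].parameters.net_charge for i in idx)
        if abs(q - round(q)) > 1e-6:
            raise ValueError(
                f"model appears unscaled: a fragment has non-integral charge {q:.4f} e "
                "(run scale_fragment_charges first)"
            )


def residue_energy_table(
    model: MolecularDensityModel,
    structure: Structure,
    partition: FragmentPartition,
    quad: QuadratureSpec | None = None,
    max_l: int = 4,
    significance_threshold: float = SIGNIFICANCE_THRESHOLD,
    penetration_threshold: float = PENETRATION_THRESHOLD,
    cutoff: float = DISTANCE_CUTOFF,
    label: str = "",
) -> BindingSiteReport:
    """EPMM energies for every (protein residue, RNA fragment) pair.

    Filters: ``significant`` = |E_EPMM| strictly above the +/-5 kcal/mol
    threshold against any fragment; ``strong_penetration`` = |E_pen| >=
    threshold against any fragment, restricted to the distance-selected
    site (penetration vanishes beyond overlap anyway).
    """
    quad = quad or QuadratureSpec()
    if len(model.atoms) != len(structure.atoms):
        raise ValueError("model and structure atom counts differ")
    _check_scaled(model, partition)
    frag_names = [f"fragment{k + 1}" for k in range(len(partition.rna_fragments))]
    frag_models = [
        MolecularDensityModel([model.atoms[i] for i in idx], name)
        for name, idx in zip(frag_names, partition.rna_fragments)
    ]
    records = {}
    for rid, idx in partition.protein_residues:
        res_model = MolecularDensityModel([model.atoms[i] for i in idx], str(rid))
        row = {}
        for name, fmodel in zip(frag_names, frag_models):
            inter = epmm_energy(res_model, fmodel, quad, max_l)
            row[(name, "e_mm")] = inter.e_mm
            row[(name, "e_epmm")] = inter.e_epmm
            row[(name, "e_pen")] = inter.e_pen
        records[str(rid)] = row
    table = pd.DataFrame.from_dict(records, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["fragment", "energy"])

    within = [str(r) for r in select_binding_site(structure, partition, cutoff)]
    epmm_cols = table.xs("e_epmm", axis=1, level=1)
    pen_cols = table.xs("e_pen", axis=1, level=1)
    significant = list(table.index[(epmm_cols.abs() > significance_threshold).any(axis=1)])
    strong_pen = [
        r
        for r in table.index[(pen_cols.abs() >= penetration_threshold).any(axis=1)]
        if r in within
    ]
    return BindingSiteReport(
        table=table,
        within_5a=within,
        significant=significant,
        strong_penetration=strong_pen,
        cutoff=cutoff,
        significance_threshold=significance_threshold,
        penetration_threshold=penetration_threshold,
        fragment_names=frag_names,
        label=label,
    )


@dataclass
class SequenceComparisonSummary:
    """Cross-complex comparison of per-fragment totals."""

    totals: pd.DataFrame  # rows: report label, columns: fragment (e_epmm totals)
    binding_site_totals: pd.DataFrame
    max_relative_discrepancy_pct: float


def compare_sequences(reports: list[BindingSiteReport]) -> SequenceComparisonSummary:
    """Compare >= 2 complexes: per-fragment E_EPMM totals (whole protein and
    binding site) and the maximum pairwise discrepancy of the grand totals,
    as a percentage of the mean magnitude."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    schema = reports[0].fragment_names
    for r in reports[1:]:
        if r.fragment_names != schema:
            raise ValueError(
                f"fragment schemas differ: {schema} vs {r.fragment_names}"
            )
    rows, rows_bs = {}, {}
    for k, r in enumerate(reports):
        name = r.label or f"complex{k + 1}"
        rows[name] = r.totals()["e_epmm"]
        rows_bs[name] = r.binding_site_totals()["e_epmm"]
    totals = pd.DataFrame.from_dict(rows, orient="index")
    totals_bs = pd.DataFrame.from_dict(rows_bs, orient="index")
    grand = totals.sum(axis=1).to_numpy()
    diffs = np.abs(grand[:, None] - grand[None, :])
    mean_mag = np.mean(np.abs(grand))
    pct = float(diffs.max() / mean_mag * 100.0) if mean_mag > 0 else 0.0
    return SequenceComparisonSummary(
        totals=totals, binding_site_totals=totals_bs, max_relative_discrepancy_pct=pct
    )
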