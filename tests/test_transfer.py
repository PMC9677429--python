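"""Bond detection, hydrogen extension, atom typing, and charge scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epmm import (
    CovalentRadiiTable,
    FragmentChargeSpec,
    detect_bonds,
    extend_hydrogens,
    molecular_charge,
    scale_fragment_charges,
    transfer_parameters,
)
from epmm.density import MolecularDensityModel
from epmm.structure import ResidueId, Structure, StructureAtom
from epmm.transfer import (
    MG_RADIUS_DEFAULT,
    MG_RADIUS_SUPPRESS,
    assign_atom_types,
    build_density_model,
    default_neutron_distances,
)


def _st(atoms, chain="X", seq=1, name="RES"):
    rid = ResidueId(chain, seq, "", name)
    return Structure(
        [StructureAtom(n, e, np.asarray(x, float), rid) for n, e, x in atoms]
    )


class TestBonds:
    def test_carbon_pair_bonded(self):
        s = _st([("C1", "C", [0, 0, 0]), ("C2", "C", [1.54, 0, 0])])
        assert detect_bonds(s) == [(0, 1)]

    def test_mg_radius_override_controls_coordination(self):
        s = _st([("MG", "Mg", [0, 0, 0]), ("O", "O", [2.1, 0, 0])])
        suppressed = CovalentRadiiTable(overrides={"Mg": MG_RADIUS_SUPPRESS})
        restored = CovalentRadiiTable(overrides={"Mg": MG_RADIUS_DEFAULT})
        assert detect_bonds(s, suppressed) == []
        assert detect_bonds(s, restored) == [(0, 1)]

    def test_single_atom_no_bonds(self):
        assert detect_bonds(_st([("C1", "C", [0, 0, 0])])) == []

    def test_coincident_atoms_error(self):
        s = _st([("C1", "C", [0, 0, 0]), ("C2", "C", [0, 0, 0])])
        with pytest.raises(ValueError, match="coincident"):
            detect_bonds(s)


class TestHydrogenExtension:
    def test_oh_extended_to_neutron_distance_same_direction(self):
        d = np.array([0.6, 0.5, 0.2])
        d /= np.linalg.norm(d)
        s = _st([("O", "O", [1, 1, 1]), ("H", "H", np.array([1, 1, 1]) + 0.82 * d)])
        out = extend_hydrogens(s, detect_bonds(s))
        v = out.atoms[1].position - out.atoms[0].position
        assert np.linalg.norm(v) == pytest.approx(0.983, abs=1e-10)
        np.testing.assert_allclose(v / np.linalg.norm(v), d, atol=1e-12)
        np.testing.assert_allclose(out.atoms[0].position, [1, 1, 1])  # heavy unmoved

    def test_h_already_at_distance_unchanged(self):
        s = _st([("O", "O", [0, 0, 0]), ("H", "H", [0.983, 0, 0])])
        out = extend_hydrogens(s, detect_bonds(s))
        np.testing.assert_allclose(out.atoms[1].position, [0.983, 0, 0], atol=1e-10)

    def test_water_angle_preserved(self):
        ang = np.deg2rad(104.5)
        h1 = 0.82 * np.array([1.0, 0, 0])
        h2 = 0.82 * np.array([np.cos(ang), np.sin(ang), 0])
        s = _st([("O", "O", [0, 0, 0]), ("H1", "H", h1), ("H2", "H", h2)])
        out = extend_hydrogens(s, detect_bonds(s))

        def angle(st):
            v1 = st.atoms[1].position - st.atoms[0].position
            v2 = st.atoms[2].position - st.atoms[0].position
            return np.arccos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))

        assert angle(out) == pytest.approx(angle(s), abs=1e-12)
        assert np.linalg.norm(out.atoms[1].position) == pytest.approx(0.983)

    def test_ill_bonded_hydrogen_errors(self):
        lone = _st([("H", "H", [0, 0, 0])])
        with pytest.raises(ValueError, match="0 bonded heavy"):
            extend_hydrogens(lone, [])
        bridged = _st(
            [("O1", "O", [0, 0, 0]), ("H", "H", [1.0, 0, 0]), ("O2", "O", [2.0, 0, 0])]
        )
        with pytest.raises(ValueError, match="2 bonded heavy"):
            extend_hydrogens(bridged, detect_bonds(bridged))

    def test_default_table_contents(self):
        d = default_neutron_distances()
        assert d["O"] == pytest.approx(0.983)
        assert d["S"] == pytest.approx(1.338)


class TestAtomTyping:
    def test_water_oxygen_matches_water_entry(self, databank):
        s = _st(
            [("O", "O", [0, 0, 0]), ("H1", "H", [0.96, 0, 0]),
             ("H2", "H", [-0.24, 0.93, 0])], name="HOH",
        )
        entries = assign_atom_types(s, detect_bonds(s), databank)
        assert entries[0].name == "O_water"
        assert entries[1].name == "H_on_O"

    def test_unknown_element_errors(self, databank):
        s = _st([("CL", "Cl", [0, 0, 0])])
        with pytest.raises(KeyError, match="without a databank match"):
            assign_atom_types(s, [], databank)

    def test_assignment_invariant_under_atom_reordering(self, toy, databank):
        structure, _ = toy
        bonds = detect_bonds(structure)
        base = {
            a.label: e.name
            for a, e in zip(structure.atoms, assign_atom_types(structure, bonds, databank))
        }
        perm = np.random.default_rng(3).permutation(len(structure.atoms))
        shuffled = Structure([structure.atoms[i].copy() for i in perm])
        bonds2 = detect_bonds(shuffled)
        again = {
            a.label: e.name
            for a, e in zip(shuffled.atoms, assign_atom_types(shuffled, bonds2, databank))
        }
        assert base == again


class TestChargeScaling:
    def test_fragment_already_at_formal_charge_unchanged(self, databank):
        s = _st(
            [("O", "O", [0, 0, 0]), ("H1", "H", [0.96, 0, 0]),
             ("H2", "H", [-0.24, 0.93, 0])], name="HOH",
        )
        model, s2 = transfer_parameters(s, databank, extend_h=False)
        before = [a.parameters.p_val for a in model.atoms]
        out = scale_fragment_charges(
            model, s2, [FragmentChargeSpec("w", 0.0, frozenset({("X", 1, "")}))]
        )
        after = [a.parameters.p_val for a in out.atoms]
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_proportional_scaling_hand_linear_algebra(self, databank):
        """Two-atom fragment from +0.4 e to 0: shifts proportional to P_val."""
        s = _st([("C1", "C", [0, 0, 0]), ("C2", "C", [1.54, 0, 0])])
        model, s2 = transfer_parameters(s, databank, extend_h=False)
        for atom, pv in zip(model.atoms, (3.8, 3.8)):  # net +0.4 e total
            atom.parameters.p_val = pv
        out = scale_fragment_charges(
            model, s2, [FragmentChargeSpec("cc", 0.0, frozenset({("X", 1, "")}))]
        )
        # shift = +0.4 e spread as pv * (1 + 0.4/7.6)
        for a in out.atoms:
            assert a.parameters.p_val == pytest.approx(3.8 * (1 + 0.4 / 7.6), abs=1e-12)
        assert molecular_charge(out) == pytest.approx(0.0, abs=1e-12)

    def test_zero_valence_fragment_errors(self, databank):
        s = _st([("MG", "Mg", [0, 0, 0])], name="MG")
        model, s2 = transfer_parameters(s, databank, extend_h=False)
        model.atoms[0].parameters.p_val = 0.0
        with pytest.raises(ValueError, match="zero total P_val"):
            scale_fragment_charges(
                model, s2, [FragmentChargeSpec("m", 0.0, frozenset({("X", 1, "")}))]
            )

    def test_grouped_fragment_scales_to_minus_three(self, toy, databank):
        """A metal/triphosphate/carboxylate grouped fragment lands exactly on
        its formal -3 e (the modeled-vs-formal total identity)."""
        structure, plan = toy
        model, extended = transfer_parameters(structure, databank)
        grouped_res = plan[0].residues | {("A", 13, "")}  # frag1 + an anionic residue
        specs = [FragmentChargeSpec("grouped", -3.0, grouped_res)] + [
            f for f in plan if f.name not in ("rna_fragment1", "res_ASM_13")
        ]
        out = scale_fragment_charges(model, extended, specs)
        idx = [i for i, a in enumerate(extended.atoms) if a.residue.key() in grouped_res]
        sub = MolecularDensityModel([out.atoms[i] for i in idx])
        assert molecular_charge(sub) == pytest.approx(-3.0, abs=1e-8)

    @given(st.floats(-3, 3).filter(lambda q: abs(q) > 1e-3))
    def test_scaling_hits_any_target_exactly(self, databank, q):
        s = _st(
            [("O", "O", [0, 0, 0]), ("H1", "H", [0.96, 0, 0]),
             ("H2", "H", [-0.24, 0.93, 0])], name="HOH",
        )
        model, s2 = transfer_parameters(s, databank, extend_h=False)
        out = scale_fragment_charges(
            model, s2, [FragmentChargeSpec("w", q, frozenset({("X", 1, "")}))]
        )
        assert molecular_charge(out) == pytest.approx(q, abs=1e-8)

    def test_overlapping_fragments_error(self, databank):
        s = _st([("C1", "C", [0, 0, 0]), ("C2", "C", [1.54, 0, 0])])
        model, s2 = transfer_parameters(s, databank, extend_h=False)
        with pytest.raises(ValueError, match="both fragment"):
            scale_fragment_charges(
                model, s2,
                [FragmentChargeSpec("a", 0.0, frozenset({("X", 1, "")})),
                 FragmentChargeSpec("b", 0.0, atom_indices=frozenset({1}))],
            )


class TestTwoPassTransfer:
    def test_matches_scripted_reference_run(self, toy, databank):
        """The packaged two-pass protocol equals an explicit scripted
        suppress-Mg/extend-H then default-Mg/type sequence."""
        structure, _ = toy
        model, extended = transfer_parameters(structure, databank)

        r1 = CovalentRadiiTable(overrides={"Mg": MG_RADIUS_SUPPRESS})
        ext = extend_hydrogens(structure, detect_bonds(structure, r1))
        r2 = CovalentRadiiTable(overrides={"Mg": MG_RADIUS_DEFAULT})
        bonds = detect_bonds(ext, r2)
        entries = assign_atom_types(ext, bonds, databank)
        ref = build_density_model(ext, entries, bonds)

        assert len(model) == len(ref)
        for a, b in zip(model.atoms, ref.atoms):
            np.testing.assert_allclose(a.position, b.position, atol=1e-12)
            assert a.parameters.p_val == b.parameters.p_val
            assert a.parameters.p_lm == b.parameters.p_lm

    def test_transfer_order_independent(self, toy, databank):
        structure, plan = toy
        m1, e1 = transfer_parameters(structure, databank)
        s1 = scale_fragment_charges(m1, e1, plan)
        perm = np.random.default_rng(9).permutation(len(structure.atoms))
        shuffled = Structure([structure.atoms[i].copy() for i in perm])
        m2, e2 = transfer_parameters(shuffled, databank)
        s2 = scale_fragment_charges(m2, e2, plan)
        by_label_1 = {a.label: a for a in s1.atoms}
        by_label_2 = {a.label: a for a in s2.atoms}
        assert set(by_label_1) == set(by_label_2)
        for label, a in by_label_1.items():
            b = by_label_2[label]
            assert a.parameters.p_val == pytest.approx(b.parameters.p_val, abs=1e-12)
            np.testing.assert_allclose(a.position, b.position, atol=1e-12)
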