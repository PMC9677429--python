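"""Multipole, exact-potential, EPMM hybrid, and point-charge energies."""

import numpy as np
import pytest

from epmm import (
    MolecularDensityModel,
    PointChargeSet,
    QuadratureSpec,
    epmm_energy,
    exact_pair_energy,
    make_slater_dimer,
    multipole_pair_energy,
    point_charge_energy,
)
from epmm.constants import ANGSTROM_TO_BOHR, COULOMB_KCAL_A, HARTREE_TO_KCALMOL
from epmm.density import moments_racah
from epmm.synthetic import brute_force_coulomb_oracle, slater_pseudoatom

#: contracted enough that two clouds 3 A apart behave as point charges
TIGHT = 6.0


class TestMultipoleEnergy:
    def test_monopole_pair_is_coulomb_law(self):
        a = slater_pseudoatom(TIGHT, 0.0, [0, 0, 0], "a")  # +1 e
        b = slater_pseudoatom(TIGHT, 2.0, [3.0, 0, 0], "b")  # -1 e
        assert multipole_pair_energy(a, b) == pytest.approx(-COULOMB_KCAL_A / 3.0)

    def test_neutral_zero_multipole_atoms_do_not_interact(self):
        a = slater_pseudoatom(1.5, 1.0, [0, 0, 0], "a")
        b = slater_pseudoatom(1.5, 1.0, [4.0, 0, 0], "b")
        assert multipole_pair_energy(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_point_dipoles(self):
        p10 = 0.2
        a = slater_pseudoatom(2.0, 1.0, [0, 0, 0], "a", p_lm={(1, 0): p10})
        b = slater_pseudoatom(2.0, 1.0, [0, 0, 4.0], "b", p_lm={(1, 0): p10})
        mu = abs(moments_racah(a, 1)[1][1])  # e Bohr
        r = 4.0 * ANGSTROM_TO_BOHR
        expected = -2 * mu * mu / r**3 * HARTREE_TO_KCALMOL
        assert multipole_pair_energy(a, b) == pytest.approx(expected, rel=1e-10)

    def test_coincident_centers_error(self):
        a = slater_pseudoatom(1.0, 1.0, [0, 0, 0], "a")
        b = slater_pseudoatom(1.0, 1.0, [0, 0, 0], "b")
        with pytest.raises(ValueError, match="coincident"):
            multipole_pair_energy(a, b)


class TestExactEnergy:
    def test_agrees_with_multipoles_when_far(self):
        a = slater_pseudoatom(1.3, 0.5, [0, 0, 0], "a", p_lm={(1, 0): 0.1})
        b = slater_pseudoatom(1.9, 1.5, [20.0, 0, 0], "b")
        assert exact_pair_energy(a, b) == pytest.approx(
            multipole_pair_energy(a, b), abs=1e-3
        )

    def test_two_slater_clouds_match_symbolic_closed_form(self):
        """Equal-exponent neutral 1s clouds vs the sympy-derived two-
        exponential Coulomb integral."""
        import sympy as sp

        zs, rs, s, u, r = sp.symbols("zeta R s u r", positive=True)
        rho = zs**3 / sp.pi * sp.exp(-2 * zs * s)
        v = 4 * sp.pi * (
            sp.integrate(rho.subs(s, u) * u**2, (u, 0, r)) / r
            + sp.integrate(rho.subs(s, u) * u, (u, r, sp.oo))
        )
        vbar_in = sp.integrate(u * v.subs(r, u), (u, rs - s, rs + s)) / (2 * s * rs)
        vbar_out = sp.integrate(u * v.subs(r, u), (u, s - rs, rs + s)) / (2 * s * rs)
        e_ee = sp.integrate(4 * sp.pi * s**2 * rho * vbar_in, (s, 0, rs)) + sp.integrate(
            4 * sp.pi * s**2 * rho * vbar_out, (s, rs, sp.oo)
        )
        # neutral-atom total: nn + 2*ne + ee with V_cloud(R) = 1/R - e^-2zR (z + 1/R)
        v_cloud = 1 / rs - sp.exp(-2 * zs * rs) * (zs + 1 / rs)
        e_total = sp.simplify(1 / rs - 2 * v_cloud + e_ee)
        zeta, r_ang = 1.2, 1.1
        r_bohr = r_ang * ANGSTROM_TO_BOHR
        expected = float(e_total.subs({zs: zeta, rs: r_bohr})) * HARTREE_TO_KCALMOL
        a = slater_pseudoatom(zeta, 1.0, [0, 0, 0], "a")
        b = slater_pseudoatom(zeta, 1.0, [r_ang, 0, 0], "b")
        assert exact_pair_energy(a, b) == pytest.approx(expected, abs=5e-4)

    def test_symmetric_in_pair_order(self):
        a = slater_pseudoatom(1.8, 1.3, [0, 0, 0], "a", p_lm={(1, 0): 0.1, (2, 1): 0.05})
        b = slater_pseudoatom(1.6, 0.7, [1.2, 1.2, 0.8], "b", p_lm={(1, -1): 0.08})
        assert abs(exact_pair_energy(a, b) - exact_pair_energy(b, a)) < 1e-4

    def test_grid_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="n_radial"):
            QuadratureSpec(n_radial=10)
        with pytest.raises(ValueError, match="n_angular"):
            QuadratureSpec(n_angular=8)

    def test_oracle_equivalence_on_dimers(self):
        """Implementation vs the independent dense-grid oracle, 1.5-6 A."""
        cases = [
            (1.0, 1.0, 1.5, 1.0, 1.0),
            (1.5, 2.0, 2.0, 0.5, 1.5),
            (2.5, 1.2, 3.0, 2.0, 0.0),
            (1.8, 1.8, 4.5, 1.0, 1.0),
            (1.1, 2.8, 6.0, 1.3, 0.7),
        ]
        for za, zb, sep, na, nb in cases:
            ma, mb = make_slater_dimer(za, zb, sep, na, nb)
            e = exact_pair_energy(ma.atoms[0], mb.atoms[0])
            ref = brute_force_coulomb_oracle(ma, mb)
            assert e == pytest.approx(ref, abs=0.1), (za, zb, sep)


class TestEpmmHybrid:
    def _dimer_models(self, sep):
        a = slater_pseudoatom(1.4, 1.2, [0, 0, 0], "A/R1:X", p_lm={(1, 0): 0.08})
        b = slater_pseudoatom(1.7, 0.8, [sep, 0, 0], "B/R1:Y")
        return MolecularDensityModel([a], "ma"), MolecularDensityModel([b], "mb")

    def test_pen_identity_and_zero_outside_rcrit(self):
        ma, mb = self._dimer_models(7.0)
        res = epmm_energy(ma, mb, QuadratureSpec(rcrit=5.0))
        assert res.e_pen == 0.0  # no EP pairs: e_epmm is e_mm by construction
        assert (res.pair_breakdown["method"] == "MM").all()
        near = epmm_energy(ma, mb, QuadratureSpec(rcrit=8.0))
        assert near.e_pen == near.e_epmm - near.e_mm  # identity, exact

    def test_penetration_negative_at_hbond_overlap(self):
        ma, mb = self._dimer_models(1.8)
        res = epmm_energy(ma, mb, QuadratureSpec())
        assert res.e_pen < 0

    def test_penetration_decays_monotonically(self):
        pens = []
        for sep in (2.0, 2.5, 3.0, 4.0, 10.0):
            ma, mb = self._dimer_models(sep)
            pens.append(abs(epmm_energy(ma, mb, QuadratureSpec()).e_pen))
        assert all(x > y for x, y in zip(pens, pens[1:]))
        assert pens[-1] < 1e-3

    def test_rcrit_doubling_barely_moves_the_hybrid_energy(self):
        ma, mb = self._dimer_models(2.5)
        e5 = epmm_energy(ma, mb, QuadratureSpec(rcrit=5.0)).e_epmm
        e10 = epmm_energy(ma, mb, QuadratureSpec(rcrit=10.0)).e_epmm
        assert abs(e5 - e10) < 0.05

    def test_rigid_motion_invariance(self, rng):
        ma, mb = self._dimer_models(2.2)
        base = epmm_energy(ma, mb, QuadratureSpec())
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([3.0, -2.0, 5.0])

        def move(model):
            atoms = []
            for at in model.atoms:
                new = slater_pseudoatom(
                    at.parameters.radial.zeta, at.parameters.p_val,
                    q @ at.position + shift, at.label, p_lm=dict(at.parameters.p_lm),
                )
                new.frame = q @ at.frame
                atoms.append(new)
            return MolecularDensityModel(atoms, model.label)

        moved = epmm_energy(move(ma), move(mb), QuadratureSpec())
        assert moved.e_mm == pytest.approx(base.e_mm, abs=1e-6)
        assert moved.e_epmm == pytest.approx(base.e_epmm, abs=1e-6)

    def test_pair_breakdown_sums_to_totals(self):
        ma, mb = self._dimer_models(2.0)
        ma.atoms.append(slater_pseudoatom(1.2, 1.0, [0, 0, 1.1], "A/R1:X2"))
        res = epmm_energy(ma, mb, QuadratureSpec())
        assert res.pair_breakdown["e_mm"].sum() == pytest.approx(res.e_mm, abs=1e-9)
        assert res.pair_breakdown["e_pair"].sum() == pytest.approx(res.e_epmm, abs=1e-9)

    def test_shared_atom_identity_rejected(self):
        ma, _ = self._dimer_models(2.0)
        mb = MolecularDensityModel(
            [slater_pseudoatom(1.0, 1.0, [5, 0, 0], "A/R1:X")], "mb"
        )
        with pytest.raises(ValueError, match="share"):
            epmm_energy(ma, mb)

    def test_grid_convergence(self):
        """Refining 99->199 radial and 590->974 angular moves EP energies
        by less than 0.01 kcal/mol."""
        coarse = QuadratureSpec(99, 590)
        fine = QuadratureSpec(199, 974)
        for sep in (1.5, 2.5, 4.0):
            ma, mb = self._dimer_models(sep)
            e1 = exact_pair_energy(ma.atoms[0], mb.atoms[0], coarse)
            e2 = exact_pair_energy(ma.atoms[0], mb.atoms[0], fine)
            assert abs(e1 - e2) < 0.01


class TestPointCharges:
    def test_unit_charges_at_three_angstrom(self):
        a = PointChargeSet([1.0], [[0, 0, 0]])
        b = PointChargeSet([-1.0], [[3.0, 0, 0]])
        assert point_charge_energy(a, b) == pytest.approx(-COULOMB_KCAL_A / 3)

    def test_neutral_set_decays(self):
        a = PointChargeSet([0.3, -0.3], [[0, 0, 0], [1.0, 0, 0]])
        b = PointChargeSet([1.0], [[2000.0, 0, 0]])
        assert abs(point_charge_energy(a, b)) < 1e-3

    def test_zero_distance_error(self):
        a = PointChargeSet([1.0], [[0, 0, 0]])
        with pytest.raises(ValueError, match="zero"):
            point_charge_energy(a, a)

    def test_matches_monopole_only_multipole_energy(self, toy_model):
        """With all higher moments dropped, the multipole energy is exactly
        the point-charge Coulomb sum of the atomic net charges."""
        scaled, extended, _ = toy_model
        g1 = [a for a in scaled.atoms[:6]]
        g2 = [a for a in scaled.atoms[40:46]]
        mm0 = sum(
            multipole_pair_energy(a, b, max_l=0) for a in g1 for b in g2
        )
        pc = point_charge_energy(
            PointChargeSet([a.parameters.net_charge for a in g1],
                           [a.position for a in g1]),
            PointChargeSet([b.parameters.net_charge for b in g2],
                           [b.position for b in g2]),
        )
        assert mm0 == pytest.approx(pc, rel=1e-10)
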