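import math

import numpy as np
import pytest

from _oracles import brute_coulomb, brute_lj
from npbind.energetics import (BondedTerms, EnergeticsError,
                               EnergyBreakdown, EnergyModelConfig,
                               alanine_scan, bonded_energy, coulomb_energy,
                               lj_energy, mmpbsa, mutate_to_alanine,
                               nonpolar_energy, pb_polar_energy, sasa,
                               substructure)
from npbind.io_model import Atom, Structure
from npbind.units import COULOMB_CONSTANT


def _atoms(positions, charges=None, sigma=3.5, epsilon=0.1, radius=1.8):
    out = []
    for i, p in enumerate(positions):
        out.append(Atom(name=f"X{i}", element="C", residue_id=i + 1,
                        residue_name="UNK", chain="A", position=p,
                        charge=None if charges is None else charges[i],
                        lj_sigma=sigma, lj_epsilon=epsilon, radius=radius))
    return Structure(out)


@pytest.fixture
def cfg_eps1():
    return EnergyModelConfig(solute_dielectric=1.0)


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self, cfg_eps1):
        s = _atoms([[0, 0, 0], [1, 0, 0]], charges=[1.0, 1.0])
        assert coulomb_energy(s, cfg_eps1, [0, 1], [0, 1]) == \
            pytest.approx(COULOMB_CONSTANT, rel=1e-12)

    def test_opposite_charges_screened(self):
        cfg = EnergyModelConfig(solute_dielectric=2.0)
        s = _atoms([[0, 0, 0], [2, 0, 0]], charges=[1.0, -1.0])
        assert coulomb_energy(s, cfg, [0, 1], [0, 1]) == \
            pytest.approx(-83.0159, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_pair_sum(self, cfg_eps1, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 12, size=(20, 3))
        q = rng.uniform(-1, 1, 20)
        s = _atoms(pos, charges=q)
        got = coulomb_energy(s, cfg_eps1, list(range(20)), list(range(20)))
        assert got == pytest.approx(brute_coulomb(pos, q, 1.0), abs=1e-10)
        # cross-group layout
        ga, gb = list(range(8)), list(range(8, 20))
        pairs = [(i, j) for i in ga for j in gb]
        got_x = coulomb_energy(s, cfg_eps1, ga, gb)
        assert got_x == pytest.approx(
            brute_coulomb(pos, q, 1.0, pairs=pairs), abs=1e-10)

    def test_uncharged_atom_named_in_error(self, cfg_eps1):
        s = _atoms([[0, 0, 0], [1, 0, 0]], charges=[1.0, 1.0])
        s.atoms[1].charge = None
        with pytest.raises(EnergeticsError, match="A:2:X1"):
            coulomb_energy(s, cfg_eps1, [0, 1], [0, 1])

    def test_coincident_atoms_rejected(self, cfg_eps1):
        s = _atoms([[0, 0, 0], [0, 0, 0]], charges=[1.0, 1.0])
        with pytest.raises(EnergeticsError, match="zero"):
            coulomb_energy(s, cfg_eps1, [0, 1], [0, 1])

    def test_partially_overlapping_groups_rejected(self, cfg_eps1):
        s = _atoms(np.eye(3) * 3.0, charges=[1, 1, 1])
        with pytest.raises(EnergeticsError, match="overlap"):
            coulomb_energy(s, cfg_eps1, [0, 1], [1, 2])


class TestLennardJones:
    def test_zero_at_sigma_and_minimum_at_r_min(self, cfg_eps1):
        s = _atoms([[0, 0, 0], [3.5, 0, 0]])
        assert lj_energy(s, cfg_eps1, [0, 1], [0, 1]) == \
            pytest.approx(0.0, abs=1e-12)
        r_min = 2 ** (1 / 6) * 3.5
        s2 = _atoms([[0, 0, 0], [r_min, 0, 0]])
        assert lj_energy(s2, cfg_eps1, [0, 1], [0, 1]) == \
            pytest.approx(-0.1, rel=1e-10)

    def test_lorentz_berthelot_combination(self, cfg_eps1):
        s = _atoms([[0, 0, 0], [3.0, 0, 0]])
        s.atoms[0].lj_sigma, s.atoms[0].lj_epsilon = 3.0, 0.2
        s.atoms[1].lj_sigma, s.atoms[1].lj_epsilon = 3.4, 0.05
        sig = 3.2
        eps = math.sqrt(0.2 * 0.05)
        sr6 = (sig / 3.0) ** 6
        assert lj_energy(s, cfg_eps1, [0, 1], [0, 1]) == \
            pytest.approx(4 * eps * (sr6 ** 2 - sr6), rel=1e-12)

    def test_matches_brute_force(self, cfg_eps1):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 15, size=(15, 3))
        s = _atoms(pos)
        sig = rng.uniform(3, 4, 15)
        eps = rng.uniform(0.05, 0.3, 15)
        for i, a in enumerate(s.atoms):
            a.lj_sigma, a.lj_epsilon = sig[i], eps[i]
        got = lj_energy(s, cfg_eps1, list(range(15)), list(range(15)))
        assert got == pytest.approx(brute_lj(pos, sig, eps), abs=1e-10)

    def test_missing_parameters_rejected(self, cfg_eps1):
        s = _atoms([[0, 0, 0], [3, 0, 0]])
        s.atoms[0].lj_sigma = None
        with pytest.raises(EnergeticsError, match="LJ"):
            lj_energy(s, cfg_eps1, [0, 1], [0, 1])


class TestBonded:
    def test_terms_at_equilibrium_are_zero(self):
        s = _atoms([[0, 0, 0], [1.5, 0, 0], [1.5, 1.2, 0], [0.3, 1.2, 1.0]])
        terms = BondedTerms(
            bonds=[(0, 1, 300.0, 1.5)],
            angles=[(0, 1, 2, 50.0, math.pi / 2)],
            dihedrals=[(0, 1, 2, 3, 0.0, 3, 0.0)],
        )
        assert bonded_energy(s, terms) == pytest.approx(0.0, abs=1e-10)

    def test_direct_evaluation_of_each_term(self):
        s = _atoms([[0, 0, 0], [1.8, 0, 0], [1.8, 1.0, 0], [1.8, 1.0, 1.3]])
        x = s.coords
        terms = BondedTerms(
            bonds=[(0, 1, 100.0, 1.5)],
            angles=[(0, 1, 2, 40.0, 1.6)],
            dihedrals=[(0, 1, 2, 3, 2.5, 2, 0.3)],
        )
        r = np.linalg.norm(x[1] - x[0])
        e_bond = 100.0 * (r - 1.5) ** 2
        v1, v2 = x[0] - x[1], x[2] - x[1]
        theta = math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        e_angle = 40.0 * (theta - 1.6) ** 2
        b0, b1, b2 = x[1] - x[0], x[2] - x[1], x[3] - x[2]
        n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
        phi = math.atan2(np.cross(n1, n2) @ b1 / np.linalg.norm(b1), n1 @ n2)
        e_dih = 2.5 * (1 + math.cos(2 * phi - 0.3))
        assert bonded_energy(s, terms) == \
            pytest.approx(e_bond + e_angle + e_dih, rel=1e-12)

    def test_none_terms_give_zero_and_degenerate_geometry_raises(self):
        s = _atoms([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        assert bonded_energy(s, None) == 0.0
        with pytest.raises(EnergeticsError, match="degenerate"):
            bonded_energy(s, BondedTerms(angles=[(0, 1, 2, 10.0, 1.0)]))

    def test_invalid_indices_rejected(self):
        s = _atoms([[0, 0, 0], [1.5, 0, 0]])
        with pytest.raises(EnergeticsError, match="missing atom"):
            bonded_energy(s, BondedTerms(bonds=[(0, 5, 100.0, 1.5)]))


class TestSASA:
    def test_isolated_atom_matches_closed_form(self):
        cfg = EnergyModelConfig()
        s = _atoms([[0, 0, 0]], radius=1.8)
        _, total = sasa(s, cfg)
        expect = 4 * math.pi * (1.8 + cfg.sasa_probe) ** 2
        assert total == pytest.approx(expect, rel=5e-3)

    def test_distant_atoms_are_additive(self):
        cfg = EnergyModelConfig()
        s = _atoms([[0, 0, 0], [50, 0, 0]], radius=1.8)
        per_atom, total = sasa(s, cfg)
        single = 4 * math.pi * (1.8 + cfg.sasa_probe) ** 2
        np.testing.assert_allclose(per_atom, single, rtol=5e-3)
        assert total == pytest.approx(2 * single, rel=5e-3)

    def test_fused_dimer_agrees_with_denser_point_oracle(self):
        cfg = EnergyModelConfig()
        dense = EnergyModelConfig(sasa_points=9600)
        s = _atoms([[0, 0, 0], [2.0, 0, 0]], radius=1.8)
        _, got = sasa(s, cfg)
        _, oracle = sasa(s, dense)
        assert got == pytest.approx(oracle, rel=1e-2)

    def test_total_decreases_monotonically_on_approach(self):
        cfg = EnergyModelConfig()
        totals = []
        for d in (8.0, 5.0, 3.0, 2.0):
            _, t = sasa(_atoms([[0, 0, 0], [d, 0, 0]], radius=1.8), cfg)
            totals.append(t)
        assert all(b < a for a, b in zip(totals, totals[1:]))

    def test_missing_radius_rejected(self):
        s = _atoms([[0, 0, 0]])
        s.atoms[0].radius = None
        with pytest.raises(EnergeticsError, match="radius"):
            sasa(s, EnergyModelConfig())

    def test_nonpolar_term_is_affine_in_area(self):
        cfg = EnergyModelConfig()
        assert nonpolar_energy(0.0, cfg) == pytest.approx(cfg.sasa_offset)
        assert nonpolar_energy(100.0, cfg) == \
            pytest.approx(cfg.sasa_gamma * 100.0 + cfg.sasa_offset)


class TestPoissonBoltzmann:
    def test_zero_charges_give_zero(self):
        s = _atoms([[0, 0, 0], [4, 0, 0]], charges=[0.0, 0.0], radius=2.0)
        assert pb_polar_energy(s, EnergyModelConfig()) == 0.0

    def test_born_ion_within_five_percent(self):
        ion = _atoms([[0, 0, 0]], charges=[1.0], radius=2.0)
        cfg = EnergyModelConfig(solute_dielectric=1.0, ionic_strength_mM=0.0)
        born = -(COULOMB_CONSTANT / 2) * (1 / 2.0) * (1 - 1 / 80.0)
        got = pb_polar_energy(ion, cfg, spacing=0.5)
        assert got == pytest.approx(born, rel=0.05)

    def test_salt_strengthens_screening(self):
        ion = _atoms([[0, 0, 0]], charges=[1.0], radius=2.0)
        no_salt = EnergyModelConfig(solute_dielectric=1.0,
                                    ionic_strength_mM=0.0)
        salty = EnergyModelConfig(solute_dielectric=1.0,
                                  ionic_strength_mM=1000.0)
        g0 = pb_polar_energy(ion, no_salt, spacing=1.0)
        g1 = pb_polar_energy(ion, salty, spacing=1.0)
        assert g1 < g0 < 0.0     # salt makes solvation more favorable

    def test_atom_outside_grid_rejected(self):
        ion = _atoms([[0, 0, 0]], charges=[1.0], radius=2.0)
        cfg = EnergyModelConfig(pb_padding=0.0, pb_stern=0.0)
        with pytest.raises(EnergeticsError, match="grid"):
            pb_polar_energy(ion, cfg, spacing=5.0)


class TestMMPBSA:
    def test_delta_terms_are_exact_differences(self, wt_binding):
        for term in ("e_bonded", "e_vdw", "e_elec", "g_polar", "g_nonpolar"):
            d = getattr(wt_binding.delta, term)
            c = getattr(wt_binding.complex, term)
            p = getattr(wt_binding.protein, term)
            l = getattr(wt_binding.ligand, term)
            assert d == c - (p + l)
        assert wt_binding.delta.e_bonded == 0.0    # single-trajectory protocol

    def test_breakdown_total_is_component_sum(self):
        bd = EnergyBreakdown(e_bonded=1.0, e_vdw=-2.0, e_elec=3.0,
                             g_polar=-4.0, g_nonpolar=0.5)
        assert bd.g_total == pytest.approx(-1.5)
        with_s = EnergyBreakdown(e_vdw=1.0, ts=0.7, include_entropy=True)
        assert with_s.g_total == pytest.approx(0.3)

    def test_per_residue_decomposition_closes_to_delta_g(self, wt_binding):
        assert wt_binding.per_residue.sum() == \
            pytest.approx(wt_binding.delta.g_total, abs=1e-6)
        assert wt_binding.per_atom.sum() == \
            pytest.approx(wt_binding.delta.g_total, abs=1e-6)

    def test_delta_elec_equals_independent_cross_coulomb(
            self, complex_fixture, coarse_cfg, wt_binding):
        _, _, _, comp = complex_fixture
        cross = coulomb_energy(comp, coarse_cfg, "chain:A", "chain:X")
        assert wt_binding.delta.e_elec == pytest.approx(cross, abs=1e-9)

    def test_swapping_group_labels_leaves_delta_unchanged(
            self, complex_fixture, coarse_cfg, wt_binding):
        _, _, _, comp = complex_fixture
        swapped = mmpbsa(comp, "chain:X", "chain:A", cfg=coarse_cfg)
        assert swapped.delta.g_total == \
            pytest.approx(wt_binding.delta.g_total, abs=1e-9)

    def test_noninteracting_limit(self, complex_fixture, coarse_cfg):
        """At 500 A separation the LJ cross term vanishes and the Coulomb
        cross term collapses to the monopole-monopole tail (exactly zero for
        a neutralized partner)."""
        protein, particle, _, comp = complex_fixture
        coords = comp.coords
        coords[len(protein):, 0] += 500.0
        far = comp.with_coords(coords)
        assert lj_energy(far, coarse_cfg, "chain:A", "chain:X") == \
            pytest.approx(0.0, abs=1e-3)
        q_prot = protein.total_charge()
        q_lig = particle.total_charge
        monopole = COULOMB_CONSTANT * q_prot * q_lig / \
            (coarse_cfg.solute_dielectric * 500.0)
        assert coulomb_energy(far, coarse_cfg, "chain:A", "chain:X") == \
            pytest.approx(monopole, rel=0.05)
        # neutral ligand: the electrostatic cross term itself goes to zero
        neutral = far.copy()
        for a in neutral.atoms:
            if a.chain == "X":
                a.charge = 0.0
        assert coulomb_energy(neutral, coarse_cfg, "chain:A", "chain:X") == \
            pytest.approx(0.0, abs=1e-3)

    def test_overlapping_or_incomplete_selections_rejected(
            self, complex_fixture, coarse_cfg):
        _, _, _, comp = complex_fixture
        with pytest.raises(EnergeticsError, match="overlap"):
            mmpbsa(comp, "chain:A,X", "chain:X", cfg=coarse_cfg)
        with pytest.raises(EnergeticsError, match="cover"):
            mmpbsa(comp, list(range(10)), "chain:X", cfg=coarse_cfg)


class TestAlanineScan:
    def test_mutating_an_alanine_is_a_noop(self, complex_fixture, coarse_cfg,
                                           wt_binding):
        _, _, _, comp = complex_fixture
        res = alanine_scan(comp, [("A", 5)], "chain:A", "chain:X",
                           cfg=coarse_cfg)
        assert res.delta.g_total == wt_binding.delta.g_total
        assert len(mutate_to_alanine(comp, [("A", 5)])) == len(comp)

    def test_charged_residue_truncation_matches_charge_removal_oracle(
            self, complex_fixture, coarse_cfg, wt_binding):
        """The change in the electrostatic cross term equals the cross-
        Coulomb contribution of the deleted/neutralized charges, computed
        independently on the coordinates."""
        _, _, _, comp = complex_fixture
        res = alanine_scan(comp, [("A", 6)], "chain:A", "chain:X",
                           cfg=coarse_cfg)     # LYS6, +1 tip
        mutant = mutate_to_alanine(comp, [("A", 6)])

        def cross_oracle(s):
            prot = [i for i, a in enumerate(s.atoms) if a.chain == "A"]
            lig = [i for i, a in enumerate(s.atoms) if a.chain == "X"]
            pos = s.coords
            q = np.array([a.charge for a in s.atoms])
            pairs = [(i, j) for i in prot for j in lig]
            return brute_coulomb(pos, q, coarse_cfg.solute_dielectric,
                                 pairs=pairs)

        expect_change = cross_oracle(mutant) - cross_oracle(comp)
        got_change = res.delta.e_elec - wt_binding.delta.e_elec
        assert got_change == pytest.approx(expect_change, abs=1e-9)
        assert abs(got_change) > 0.1     # the +1 tip really interacted

    def test_mutated_residue_is_net_neutral(self, complex_fixture):
        _, _, _, comp = complex_fixture
        mutant = mutate_to_alanine(comp, [("A", 2)])     # ASP2
        resq = sum(a.charge for a in mutant.atoms
                   if a.chain == "A" and a.residue_id == 2)
        assert resq == pytest.approx(0.0, abs=1e-12)
        names = {a.name for a in mutant.atoms
                 if a.chain == "A" and a.residue_id == 2}
        assert names == {"N", "CA", "C", "O", "CB"}

    def test_quadruple_mutant_is_single_simultaneous_operation(
            self, complex_fixture):
        _, _, _, comp = complex_fixture
        residues = [("A", 1), ("A", 2), ("A", 6), ("A", 7)]
        together = mutate_to_alanine(comp, residues)
        stepwise = comp
        for r in residues:
            stepwise = mutate_to_alanine(stepwise, [r])
        assert together.atom_identity() == stepwise.atom_identity()
        np.testing.assert_array_equal(together.coords, stepwise.coords)
        assert [a.charge for a in together.atoms] == \
            [a.charge for a in stepwise.atoms]

    def test_glycine_and_missing_residues_rejected(self, complex_fixture):
        _, _, _, comp = complex_fixture
        gly = comp.copy()
        for a in gly.atoms:
            if a.chain == "A" and a.residue_id == 4:
                a.residue_name = "GLY"
        with pytest.raises(EnergeticsError, match="glycine"):
            mutate_to_alanine(gly, [("A", 4)])
        with pytest.raises(EnergeticsError, match="not found"):
            mutate_to_alanine(comp, [("A", 99)])
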