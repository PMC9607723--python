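"""Hybrid potential physics, clash filtering, pose refinement and metrics."""

import logging

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from growkit import fixtures as fx
from growkit.constants import COULOMB_CONSTANT
from growkit.errors import GrowkitError
from growkit.mol_build import Conformer, ConformerEnsemble, RGroup, attach
from growkit.pocket import (HybridPotential, RDKitForceFieldTerm,
                            ScalingParams, ZeroLigandTerm, backend_select,
                            build_hybrid_potential, clash_filter, dihedral,
                            minimise_in_pocket, register_ml_backend,
                            rgroup_rmsd, select_low_energy)
from growkit.receptor import Receptor


def single_pair_potential(lj_scale=0.8, epsilon=4.0, q=0.0, rmin=3.5,
                          eps_lj=0.1):
    """One fixed receptor atom vs one mobile ligand atom."""
    return HybridPotential(
        receptor_coords=np.zeros((1, 3)),
        receptor_charges=np.array([q]), receptor_rmin=np.array([rmin]),
        receptor_eps=np.array([eps_lj]),
        ligand_charges=np.array([q]), ligand_rmin=np.array([rmin]),
        ligand_eps=np.array([eps_lj]), ligand_term=ZeroLigandTerm(),
        scaling=ScalingParams(lj_scale=lj_scale, epsilon=epsilon),
        include_receptor_term=False)


class TestScalingParams:
    def test_charge_scale_is_inverse_sqrt_epsilon(self):
        assert ScalingParams(epsilon=4.0).charge_scale == 4.0 ** -0.5
        assert ScalingParams(epsilon=1.0).charge_scale == 1.0

    @pytest.mark.parametrize("kwargs", [{"lj_scale": 0.0}, {"lj_scale": 1.5},
                                        {"epsilon": 0.5}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(GrowkitError):
            ScalingParams(**kwargs)


class TestCoulombScaling:
    def test_unit_charges_at_10A_dielectric_4(self):
        """Two +1 e charges at 10 Å under ε = 4: k_C·(0.5·0.5)/10."""
        pot = single_pair_potential(q=1.0, eps_lj=0.0, epsilon=4.0)
        e = pot.coupling_energy(np.array([[10.0, 0.0, 0.0]]))
        assert e == pytest.approx(COULOMB_CONSTANT * 0.25 / 10.0, abs=1e-10)
        assert e == pytest.approx(8.3016, abs=1e-4)

    def test_dielectric_law_exact_quarter(self):
        """ε = 4 scales every pair Coulomb energy by exactly 1/4."""
        rng = np.random.default_rng(42)
        lig = rng.normal(scale=5, size=(4, 3)) + np.array([12.0, 0, 0])
        rec = rng.normal(scale=5, size=(6, 3))
        ql, qr = rng.uniform(-1, 1, 4), rng.uniform(-1, 1, 6)
        def make(epsilon):
            return HybridPotential(
                receptor_coords=rec, receptor_charges=qr,
                receptor_rmin=np.zeros(6), receptor_eps=np.zeros(6),
                ligand_charges=ql, ligand_rmin=np.zeros(4),
                ligand_eps=np.zeros(4), ligand_term=ZeroLigandTerm(),
                scaling=ScalingParams(lj_scale=1.0, epsilon=epsilon),
                include_receptor_term=False)
        e1 = make(1.0).coupling_energy(lig)
        e4 = make(4.0).coupling_energy(lig)
        assert e4 == pytest.approx(e1 / 4.0, rel=1e-12)


class TestLJScaling:
    def test_scaled_minimum_by_1d_scan(self):
        """Scan oracle: argmin of the scaled 12-6 term sits at
        lj_scale × unscaled argmin (combined r_min 4.0 → 3.2 Å)."""
        pot = single_pair_potential(lj_scale=0.8, rmin=4.0, q=0.0)
        r = np.linspace(2.0, 6.0, 4001)
        energies = [pot.coupling_energy(np.array([[x, 0, 0]])) for x in r]
        assert r[int(np.argmin(energies))] == pytest.approx(3.2, abs=1e-3)

    def test_minimisation_converges_to_scaled_minimum(self):
        """Single LJ pair, combined r_min 3.5 Å, lj_scale 0.8 → 2.80 Å."""
        pot = single_pair_potential(lj_scale=0.8, rmin=3.5)
        ens = ConformerEnsemble([Conformer(np.array([[4.0, 0.0, 0.0]]))])
        out = minimise_in_pocket(ens, pot, core_restraints=False)
        assert np.linalg.norm(out[0].coords[0]) == pytest.approx(2.80, abs=0.01)

    def test_identity_scaling_recovers_plain_minimum(self):
        pot = single_pair_potential(lj_scale=1.0, epsilon=1.0, rmin=3.5)
        ens = ConformerEnsemble([Conformer(np.array([[4.0, 0.0, 0.0]]))])
        out = minimise_in_pocket(ens, pot, core_restraints=False)
        assert np.linalg.norm(out[0].coords[0]) == pytest.approx(3.5, abs=0.01)


class TestClashFilter:
    def _ensemble_at(self, *dists):
        return ConformerEnsemble(
            [Conformer(np.array([[d, 0.0, 0.0]])) for d in dists])

    def _point_receptor(self):
        return Receptor(atoms=[], charges=np.array([0.0]))

    def test_boundary_strict_less_than(self, toy_pocket):
        rec = Receptor(atoms=toy_pocket.receptor.atoms[:1])
        origin = rec.coords[0]
        near = Conformer(origin[None, :] + [0.9, 0, 0])
        edge = Conformer(origin[None, :] + [1.0, 0, 0])
        out = clash_filter(ConformerEnsemble([near, edge]), rec, cutoff=1.0)
        assert len(out) == 1
        assert "clash_rejected" in near.flags
        assert "clash_rejected" not in edge.flags

    def test_empty_receptor_keeps_everything(self):
        rec = Receptor(atoms=[])
        ens = self._ensemble_at(0.1, 0.5, 2.0)
        assert len(clash_filter(ens, rec)) == 3

    def test_agrees_with_brute_force_oracle(self, toy_pocket):
        """100 random ligand/receptor point sets: identical decisions."""
        rng = np.random.default_rng(7)
        rec = toy_pocket.receptor
        for _ in range(100):
            coords = rng.uniform(-9, 9, size=(rng.integers(1, 8), 3))
            conf = Conformer(coords)
            fast = len(clash_filter(ConformerEnsemble([conf]), rec, 1.0)) == 1
            oracle = fx.oracle_pairwise_min_distance(coords, rec.coords) >= 1.0
            assert fast == oracle


class TestBackendSelect:
    def test_covered_elements_use_ml(self, methyl_ligand):
        assert backend_select(methyl_ligand, want_ml=True) == "ani"

    def test_bromine_falls_back_to_mm_with_warning(self, benzene_template,
                                                   caplog):
        ligand = attach(benzene_template, RGroup.from_smiles("[*]Br", "bromo"))
        with caplog.at_level(logging.WARNING, logger="growkit.pocket"):
            backend = backend_select(ligand, want_ml=True)
        assert backend == "uff"
        assert "Br" in caplog.text

    def test_ml_not_requested(self, methyl_ligand):
        assert backend_select(methyl_ligand, want_ml=False) == "uff"


class TestMechanicalEmbedding:
    def test_decomposition_closure(self, methyl_ligand, toy_pocket):
        pot = build_hybrid_potential(methyl_ligand, toy_pocket.receptor, "uff")
        x = methyl_ligand.ensemble[0].coords
        terms = pot.decomposition(x)
        assert pot.total_energy(x) == pytest.approx(sum(terms.values()),
                                                    abs=1e-6)

    def test_mm_in_ml_slot_reproduces_full_mm(self, methyl_ligand, toy_pocket):
        """Mechanical embedding is a strict partition: an 'ML' backend that
        is the same MM force field gives the identical total energy."""
        register_ml_backend("mm-as-ml",
                            lambda mol: RDKitForceFieldTerm(mol, "uff"))
        scaling = ScalingParams(lj_scale=1.0, epsilon=1.0)
        pot_mm = build_hybrid_potential(methyl_ligand, toy_pocket.receptor,
                                        "uff", scaling)
        pot_ml = build_hybrid_potential(methyl_ligand, toy_pocket.receptor,
                                        "mm-as-ml", scaling)
        x = methyl_ligand.ensemble[0].coords
        assert abs(pot_mm.total_energy(x) - pot_ml.total_energy(x)) < 1e-6

    def test_identity_scaling_is_plain_complex_energy(self, methyl_ligand,
                                                      toy_pocket):
        """With lj_scale=1, ε=1 the coupling term equals an independent
        unscaled pairwise Coulomb + LJ sum over all complex pairs."""
        scaling = ScalingParams(lj_scale=1.0, epsilon=1.0)
        pot = build_hybrid_potential(methyl_ligand, toy_pocket.receptor,
                                     "uff", scaling)
        x = methyl_ligand.ensemble[0].coords
        rec = toy_pocket.receptor
        expected = 0.0
        for i in range(len(x)):
            for j in range(rec.n_atoms):
                r = np.linalg.norm(x[i] - rec.coords[j])
                qq = (COULOMB_CONSTANT * pot.ligand_charges[i]
                      * rec.charges[j])
                rmin = 0.5 * (pot.ligand_rmin[i] + rec.lj_rmin[j])
                eps = np.sqrt(pot.ligand_eps[i] * rec.lj_eps[j])
                expected += qq / r + eps * ((rmin / r) ** 12
                                            - 2 * (rmin / r) ** 6)
        assert pot.coupling_energy(x) == pytest.approx(expected, abs=1e-8)

    def test_unparameterised_receptor_rejected(self, methyl_ligand):
        with pytest.raises(GrowkitError, match="parameterised"):
            build_hybrid_potential(methyl_ligand, Receptor(atoms=[]), "uff")


class TestMinimiseInPocket:
    def test_energy_never_increases(self, methyl_ligand, toy_pocket):
        pot = build_hybrid_potential(methyl_ligand, toy_pocket.receptor, "uff",
                                     include_receptor_term=False)
        ens = clash_filter(methyl_ligand.ensemble, toy_pocket.receptor)
        before = [pot.total_energy(c.coords) for c in ens]
        out = minimise_in_pocket(ens, pot)
        for e0, conf in zip(before, out):
            assert conf.energy <= e0 + 1e-9
            assert "pocket_minimised" in conf.flags

    def test_receptor_coordinates_untouched(self, methyl_ligand, toy_pocket):
        rec_before = toy_pocket.receptor.coords.copy()
        pot = build_hybrid_potential(methyl_ligand, toy_pocket.receptor, "uff",
                                     include_receptor_term=False)
        minimise_in_pocket(clash_filter(methyl_ligand.ensemble,
                                        toy_pocket.receptor), pot)
        assert np.array_equal(toy_pocket.receptor.coords, rec_before)

    def test_reminimise_is_stationary(self, ethyl_ligand, toy_pocket):
        pot = build_hybrid_potential(ethyl_ligand, toy_pocket.receptor, "uff",
                                     include_receptor_term=False)
        ens = clash_filter(ethyl_ligand.ensemble, toy_pocket.receptor)
        once = minimise_in_pocket(ens, pot)
        e_first = [c.energy for c in once]
        twice = minimise_in_pocket(once, pot)
        for e0, conf in zip(e_first, twice):
            assert e0 - conf.energy <= 1e-4

    def test_core_restraints_hold_template_pose(self, methyl_ligand,
                                                toy_pocket):
        pot = build_hybrid_potential(methyl_ligand, toy_pocket.receptor, "uff",
                                     include_receptor_term=False)
        ens = clash_filter(methyl_ligand.ensemble, toy_pocket.receptor)
        out = minimise_in_pocket(ens, pot, core_restraints=True)
        ref = methyl_ligand.core_reference_coords()
        restrained = methyl_ligand.restrained_atoms
        target = np.array([ref[m] for m in restrained])
        for conf in out:
            d = conf.coords[restrained] - target
            assert np.sqrt(np.mean(np.sum(d * d, axis=1))) <= 0.1


class TestSelectLowEnergy:
    def _ens(self, energies):
        return ConformerEnsemble([Conformer(np.zeros((1, 3)), energy=e)
                                  for e in energies])

    def test_five_kcal_window_selects_three(self):
        out = select_low_energy(self._ens([0.0, 3.2, 4.9, 5.1]), window=5.0)
        assert [c.energy for c in out] == [0.0, 3.2, 4.9]

    def test_single_conformer_selected(self):
        out = select_low_energy(self._ens([7.3]))
        assert len(out) == 1 and "selected" in out[0].flags

    def test_boundary_is_inclusive(self):
        out = select_low_energy(self._ens([0.0, 5.0]), window=5.0)
        assert len(out) == 2

    def test_missing_energies_rejected(self):
        with pytest.raises(GrowkitError):
            select_low_energy(ConformerEnsemble([Conformer(np.zeros((1, 3)))]))

    def test_count_monotone_in_window(self):
        energies = [0.0, 1.1, 2.7, 4.4, 5.0, 6.8, 9.9]
        counts = [len(select_low_energy(self._ens(energies), w))
                  for w in (10.0, 5.0, 2.0, 0.5, 0.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] >= 1


class TestPoseMeasurements:
    def test_identical_poses_zero_rmsd(self, ethyl_ligand):
        a = ethyl_ligand.ensemble[0].coords
        assert rgroup_rmsd(a, a, ethyl_ligand.rgroup_heavy_atoms) == 0.0

    def test_uniform_translation(self, ethyl_ligand):
        a = ethyl_ligand.ensemble[0].coords
        b = a + np.array([0.0, 0.0, 1.0])
        assert rgroup_rmsd(a, b, ethyl_ligand.rgroup_heavy_atoms) == \
            pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_argument_order(self, ethyl_ligand):
        a = ethyl_ligand.ensemble[0].coords
        b = a + np.random.default_rng(0).normal(size=a.shape)
        atoms = ethyl_ligand.rgroup_heavy_atoms
        assert rgroup_rmsd(a, b, atoms) == pytest.approx(
            rgroup_rmsd(b, a, atoms), abs=1e-12)

    def test_para_phenyl_flip_is_symmetry_equivalent(self, benzene_template):
        """A 180° flip of a para-substituted phenyl is topologically
        invisible: symmetry-aware RMSD must be 0."""
        ligand = attach(benzene_template,
                        RGroup.from_smiles("[*]c1ccc(F)cc1", "4F-phenyl"))
        from growkit.mol_build import EmbedConfig, enumerate_conformers
        enumerate_conformers(ligand, EmbedConfig(n_conformers=5, seed=2))
        a = ligand.ensemble[0].coords
        rset = set(ligand.rgroup_atoms)
        flip = next(
            m for m in ligand.mol.GetSubstructMatches(
                ligand.mol, uniquify=False, maxMatches=10000)
            if all(m[i] == i for i in range(len(m)) if i not in rset)
            and any(m[i] != i for i in rset))
        b = a[list(flip)]
        atoms = ligand.rgroup_heavy_atoms
        assert rgroup_rmsd(a, b, atoms, symmetry=False) > 0.5
        assert rgroup_rmsd(a, b, atoms, symmetry=True,
                           mol=ligand.mol) == pytest.approx(0.0, abs=1e-9)

    def test_empty_rgroup_rejected(self):
        with pytest.raises(GrowkitError):
            rgroup_rmsd(np.zeros((2, 3)), np.zeros((2, 3)), [])


class TestDihedral:
    anti = np.array([[0.0, 1.0, 0], [0, 0, 0], [1.5, 0, 0], [1.5, -1.0, 0]])

    def test_anti_is_180(self):
        assert dihedral(self.anti, (0, 1, 2, 3)) == pytest.approx(180.0)

    def test_cis_is_0(self):
        cis = self.anti.copy()
        cis[3] = [1.5, 1.0, 0.0]
        assert dihedral(cis, (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(5)
        pose = rng.normal(size=(4, 3)) * 2.0
        ref = dihedral(pose, (0, 1, 2, 3))
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed))
            rotated = pose @ rot.as_matrix().T + [1.0, -2.0, 0.5]
            assert dihedral(rotated, (0, 1, 2, 3)) == pytest.approx(
                ref, abs=1e-6)

    def test_collinear_atoms_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        with pytest.raises(GrowkitError, match="collinear"):
            dihedral(line, (0, 1, 2, 3))

    def test_duplicate_atoms_rejected(self):
        with pytest.raises(GrowkitError):
            dihedral(self.anti, (0, 1, 1, 3))
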