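"""Core loading, R-group attachment and constrained conformer enumeration."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

from growkit.errors import AttachmentError, CoreMismatchError, GrowkitError
from growkit.mol_build import (EmbedConfig, LigandTemplate, RGroup, attach,
                               core_mapping, dedup_ensemble,
                               enumerate_conformers, extend_flexible,
                               load_core)

from conftest import first_hydrogen, make_mol_3d


class TestLoadCore:
    def test_benzene_sdf_valid_template(self, benzene_sdf, benzene):
        h = first_hydrogen(benzene)
        template = load_core(benzene_sdf, h)
        assert template.mol.GetNumAtoms() == 12
        assert template.attachment_h == h
        assert template.flexible_atoms == set()

    def test_carbon_attachment_rejected(self, benzene_sdf):
        with pytest.raises(AttachmentError, match="hydrogen"):
            load_core(benzene_sdf, 0)  # atom 0 is an aromatic carbon

    def test_index_out_of_range(self, benzene_sdf):
        with pytest.raises(AttachmentError, match="out of range"):
            load_core(benzene_sdf, 99)

    def test_flat_2d_coordinates_rejected(self, tmp_path):
        mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
        AllChem.Compute2DCoords(mol)
        path = tmp_path / "flat.sdf"
        writer = Chem.SDWriter(str(path))
        writer.write(mol)
        writer.close()
        with pytest.raises(GrowkitError, match="3D|coordinates"):
            load_core(str(path), first_hydrogen(mol))

    def test_unparseable_file(self, tmp_path):
        bad = tmp_path / "bad.sdf"
        bad.write_text("this is not a molecule\n")
        with pytest.raises(GrowkitError):
            load_core(str(bad), 0)


class TestAttach:
    def test_methyl_growth_gives_toluene(self, benzene_template):
        grown = attach(benzene_template, RGroup.from_smiles("[*]C", "methyl"))
        assert rdMolDescriptors.CalcMolFormula(grown.mol) == "C7H8"

    def test_hydrogen_rgroup_is_identity(self, benzene_template):
        grown = attach(benzene_template, RGroup.from_smiles("[*][H]", "H"))
        assert rdMolDescriptors.CalcMolFormula(grown.mol) == "C6H6"
        assert set(grown.core_map) == (
            set(range(12)) - {benzene_template.attachment_h})

    def test_full_valence_rgroup_rejected(self):
        # attachment atom with four explicit bonds and no H to consume
        with pytest.raises(AttachmentError):
            RGroup.from_smiles("FC(F)(F)F", label="no-vector")

    @pytest.mark.parametrize("smiles", ["[*]C", "[*]CC", "[*]O", "[*]N(C)C",
                                        "[*]c1ccccc1", "[*]C(F)(F)F"])
    def test_atom_count_conservation(self, benzene_template, smiles):
        """Merged atom count = template - 1 (lost H) + fragment - 1 (dummy)."""
        rgroup = RGroup.from_smiles(smiles, "x")
        grown = attach(benzene_template, rgroup)
        expected = (benzene_template.mol.GetNumAtoms() - 1
                    + rgroup.mol.GetNumAtoms() - 1)
        assert grown.mol.GetNumAtoms() == expected

    def test_core_map_injective_and_disjoint_from_rgroup(self, methyl_ligand):
        image = set(methyl_ligand.core_map.values())
        assert len(image) == len(methyl_ligand.core_map)
        assert image.isdisjoint(methyl_ligand.rgroup_atoms)

    def test_formal_charge_conserved(self, benzene_template):
        grown = attach(benzene_template,
                       RGroup.from_smiles("[*]CC(=O)[O-]", "acetate"))
        assert Chem.GetFormalCharge(grown.mol) == -1


class TestExtendFlexible:
    def test_listed_core_atoms_lose_restraints(self, benzene_template):
        grown = attach(benzene_template, RGroup.from_smiles("[*]CC", "ethyl"))
        anchor = sorted(grown.core_map.values())[0]
        before = set(grown.restrained_atoms)
        extend_flexible(grown, {anchor})
        assert anchor in before
        assert anchor not in grown.restrained_atoms

    def test_empty_set_is_noop(self, benzene_template):
        grown = attach(benzene_template, RGroup.from_smiles("[*]C", "methyl"))
        before = list(grown.restrained_atoms)
        extend_flexible(grown, set())
        assert grown.restrained_atoms == before

    def test_rgroup_atom_rejected(self, benzene_template):
        grown = attach(benzene_template, RGroup.from_smiles("[*]C", "methyl"))
        rg_atom = next(iter(grown.rgroup_atoms))
        with pytest.raises(GrowkitError, match="already flexible"):
            extend_flexible(grown, {rg_atom})


class TestEnumerateConformers:
    def test_restrained_core_stays_on_template(self, methyl_ligand):
        """With k = 1e4 kcal/mol/Å² the core cannot drift measurably."""
        ref = methyl_ligand.core_reference_coords()
        restrained = methyl_ligand.restrained_atoms
        target = np.array([ref[m] for m in restrained])
        for conf in methyl_ligand.ensemble:
            d = conf.coords[restrained] - target
            rmsd = np.sqrt(np.mean(np.sum(d * d, axis=1)))
            assert rmsd <= 0.1

    def test_rigid_growth_yields_single_conformer(self, benzene_template):
        grown = attach(benzene_template, RGroup.from_smiles("[*]F", "fluoro"))
        ensemble = enumerate_conformers(grown,
                                        EmbedConfig(n_conformers=10, seed=3))
        assert len(ensemble) == 1

    def test_zero_conformers_rejected(self):
        with pytest.raises(ValueError):
            EmbedConfig(n_conformers=0)

    def test_determinism_bit_identical(self, benzene_template):
        cfg = EmbedConfig(n_conformers=10, seed=11)
        runs = []
        for _ in range(2):
            grown = attach(benzene_template,
                           RGroup.from_smiles("[*]CCC", "propyl"))
            runs.append(enumerate_conformers(grown, cfg))
        assert len(runs[0]) == len(runs[1])
        for a, b in zip(runs[0], runs[1]):
            assert np.array_equal(a.coords, b.coords)

    def test_dedup_is_idempotent(self, ethyl_ligand):
        heavy = ethyl_ligand.rgroup_heavy_atoms
        once = dedup_ensemble(ethyl_ligand.ensemble, heavy, 0.5)
        twice = dedup_ensemble(once, heavy, 0.5)
        assert len(once) == len(twice)
        for a, b in zip(once, twice):
            assert np.array_equal(a.coords, b.coords)

    def test_energies_finite_and_flagged(self, methyl_ligand):
        for conf in methyl_ligand.ensemble:
            assert np.isfinite(conf.energy)
            assert "vacuum_minimised" in conf.flags


def _mol_graph(mol):
    import networkx as nx
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1:
            g.add_node(atom.GetIdx(), el=atom.GetSymbol())
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in g and j in g:
            g.add_edge(i, j, order=bond.GetBondTypeAsDouble())
    return g


def _max_common_size(mol_a, mol_b) -> int:
    """Exhaustive max common connected subgraph size via networkx
    subgraph-isomorphism over connected node subsets (small graphs only)."""
    import itertools

    import networkx as nx
    from networkx.algorithms import isomorphism

    ga, gb = _mol_graph(mol_a), _mol_graph(mol_b)
    nodes = list(ga.nodes)
    nm = isomorphism.categorical_node_match("el", None)
    em = isomorphism.categorical_edge_match("order", None)
    for size in range(len(nodes), 0, -1):
        for subset in itertools.combinations(nodes, size):
            sub = ga.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = isomorphism.GraphMatcher(gb, sub, node_match=nm,
                                          edge_match=em)
            if gm.subgraph_is_isomorphic():
                return size
    return 0


class TestCoreMapping:
    def test_toluene_maps_all_ring_carbons(self, benzene_template,
                                           methyl_ligand):
        mapping = core_mapping(methyl_ligand.mol, benzene_template)
        assert len(mapping) == 6
        for t, m in mapping.items():
            assert (benzene_template.mol.GetAtomWithIdx(t).GetSymbol()
                    == methyl_ligand.mol.GetAtomWithIdx(m).GetSymbol())

    def test_identity_molecule_identity_mapping(self, benzene_template):
        mapping = core_mapping(benzene_template.mol, benzene_template)
        heavy = set(benzene_template.heavy_atoms)
        assert set(mapping) == heavy
        # benzene is fully symmetric; lowest-index tie-break picks identity
        assert all(t == m for t, m in mapping.items())

    def test_disjoint_molecule_raises_core_mismatch(self, benzene_template):
        ethane = make_mol_3d("CC", centre=False)
        with pytest.raises(CoreMismatchError):
            core_mapping(ethane, benzene_template)

    @pytest.mark.parametrize("core_smi,lig_smi", [
        ("c1ccccc1", "Cc1ccccc1"),
        ("CCO", "CCCO"),
        ("c1ccncc1", "Cc1ccncc1"),
        ("CC(C)O", "CC(C)OC"),
    ])
    def test_mcs_size_matches_exhaustive_oracle(self, core_smi, lig_smi):
        """The MCS size agrees with brute-force subgraph enumeration."""
        core = make_mol_3d(core_smi, centre=False)
        lig = make_mol_3d(lig_smi, centre=False)
        template = LigandTemplate(core, first_hydrogen(core))
        mapping = core_mapping(lig, template)
        assert len(mapping) == _max_common_size(core, lig)
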