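"""Shared fixtures: a centred benzene core, toy pockets, grown ligands."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from growkit import fixtures as fx
from growkit.mol_build import (EmbedConfig, LigandTemplate, RGroup, attach,
                               enumerate_conformers)


def make_mol_3d(smiles: str, seed: int = 1, centre: bool = True) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    AllChem.UFFOptimizeMolecule(mol)
    if centre:
        conf = mol.GetConformer()
        pos = np.array(conf.GetPositions())
        pos -= pos.mean(axis=0)
        for i, p in enumerate(pos):
            conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
    return mol


def first_hydrogen(mol: Chem.Mol) -> int:
    return next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 1)


@pytest.fixture(scope="session")
def benzene() -> Chem.Mol:
    return make_mol_3d("c1ccccc1")


@pytest.fixture(scope="session")
def benzene_template(benzene) -> LigandTemplate:
    return LigandTemplate(mol=benzene, attachment_h=first_hydrogen(benzene))


@pytest.fixture(scope="session")
def benzene_sdf(tmp_path_factory, benzene) -> str:
    path = tmp_path_factory.mktemp("core") / "benzene.sdf"
    writer = Chem.SDWriter(str(path))
    writer.write(benzene)
    writer.close()
    return str(path)


@pytest.fixture(scope="session")
def toy_pocket():
    """Pocket wide enough (7 Å cavity) to host small grown R-groups."""
    return fx.make_toy_pocket(seed=3, cavity_radius=7.0)


@pytest.fixture(scope="session")
def methyl_ligand(benzene_template):
    ligand = attach(benzene_template, RGroup.from_smiles("[*]C", "methyl"))
    enumerate_conformers(ligand, EmbedConfig(n_conformers=20, seed=7))
    return ligand


@pytest.fixture(scope="session")
def ethyl_ligand(benzene_template):
    ligand = attach(benzene_template, RGroup.from_smiles("[*]CC", "ethyl"))
    enumerate_conformers(ligand, EmbedConfig(n_conformers=20, seed=7))
    return ligand
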