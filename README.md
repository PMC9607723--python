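# growkit

Grow user-chosen R-groups from a fixed ligand core inside a rigid protein
pocket, refine the resulting bioactive conformers under a hybrid
ML/MM-style potential, filter and score the designs, and emit structures
ready for relative binding free energy (FEP) calculations.

The intended user is a computational medicinal chemist building a
congeneric series: a crystallographic ligand pose supplies the core, a
library of substituents supplies the chemistry, and the package produces
low-energy, clash-free binding poses plus drug-likeness reports and the
atom maps an alchemical setup tool needs.

## The model

A core with a known 3D pose and a marked attachment hydrogen is merged
with an R-group fragment (the hydrogen is replaced by a single bond).
Conformers of the grown molecule are embedded by distance geometry
(ETKDG), aligned onto the core pose, and relaxed with UFF under stiff
harmonic positional restraints (k = 10⁴ kcal·mol⁻¹·Å⁻²) on the core heavy
atoms, so only the grown region moves. Conformers placing any atom within
1 Å of a receptor atom are discarded, and the survivors are minimised in
the rigid pocket under a mechanical-embedding energy

    E_tot = E_MM(R) + E_MM(RL) + E_lig(L)

where E_MM(R) is the constant receptor term, E_MM(RL) the receptor–ligand
Coulomb + Lennard-Jones 12-6 coupling, and E_lig(L) the ligand
intramolecular term from a pluggable backend — a classical force field, or
an ANI-style ML potential when every element is in {H, C, N, O, F, S, Cl}.
Two empirical softenings compensate for the rigid receptor: pair LJ
minimum-energy distances are scaled by 0.8, and all coupling charges by
1/√ε with ε = 4 (pair Coulomb energies scale by 1/ε). The lowest-energy
conformer and everything within 5 kcal/mol are selected, reported with
Lipinski rule-of-five counts, an Ertl-style synthetic accessibility score
and PAINS/NIH/Brenk liability flags, and optionally re-scored by an
external CNN scorer (score-only; predicted pK converts to
ΔG = −RT ln10 · pK).

## Worked example

Generate the synthetic fixtures and grow the bundled 24-member library on
a benzene core:

```bash
growkit fixtures --out demo --seed 1
python - <<'EOF'
from rdkit import Chem
from rdkit.Chem import AllChem
import numpy as np
mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
AllChem.EmbedMolecule(mol, randomSeed=1); AllChem.UFFOptimizeMolecule(mol)
conf = mol.GetConformer()
xyz = np.array(conf.GetPositions()); xyz -= xyz.mean(axis=0)
for i, p in enumerate(xyz):
    conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
w = Chem.SDWriter("demo/core.sdf"); w.write(mol); w.close()
print("attachment H index:", next(a.GetIdx() for a in mol.GetAtoms()
                                  if a.GetAtomicNum() == 1))
EOF
growkit grow --receptor demo/toy_pocket.pdb --core demo/core.sdf \
    --attach-idx 6 --rgroups toy --n-conformers 8 --seed 7 --out demo/run
```

which prints

```
attachment H index: 6
grew 24/24 ligands -> demo/run (11.11 s)
```

meaning every library R-group produced at least one clash-free,
pocket-minimised pose within the 5 kcal/mol window. `demo/run/` then holds
per-ligand `poses.sdf` (energies and stage flags as SD tags),
`complex.pdb` (receptor plus ligand as chain L), `properties.csv`,
`receptor.pdb`, and `run_log.json` with every parameter and per-stage
conformer counts. Prepare an FEP pair with

```bash
growkit fep-prep --run-dir demo/run --ligand-a methyl --ligand-b ethyl \
    --out demo/fep
# -> FEP inputs written to demo/fep (7 mapped atoms)
```

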