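# Methods

## Overview

growkit builds binding poses for a congeneric ligand series by growing
R-groups from a fixed, experimentally determined core pose inside a rigid
receptor. The design goal is a cheap, deterministic pipeline whose every
stage is independently checkable: molecule surgery and constrained
embedding (RDKit), a transparent pairwise nonbonded pocket model
(NumPy/SciPy), and black-box contracts for the optional external pieces
(ML ligand potentials, CNN re-scoring).

## Core-constrained conformer generation

The attachment point must be a hydrogen on the core; the R-group marks its
attachment vector with a `[*]` placeholder (or an explicit hydrogen to
consume). Merging is plain bond surgery on the combined graph followed by
sanitisation, so valence errors surface immediately. Conformers are
embedded with ETKDGv3 using a coordinate map that pins core heavy atoms to
the template pose, aligned onto the template, snapped, and minimised with
UFF plus per-atom isotropic harmonic positional restraints
(k = 10⁴ kcal·mol⁻¹·Å⁻², no flat-bottom region) on the restrained core
heavy atoms. Core hydrogens are not restrained: hydrogen placement differs
between tools and all pose metrics here are heavy-atom quantities. At this
force constant the residual core displacement under typical UFF forces
(≲10 kcal·mol⁻¹·Å⁻¹) is ≲10⁻³ Å, far inside the 0.1 Å fidelity bound the
tests assert.

Near-duplicate conformers are removed after vacuum minimisation (not
before: minimisation collapses distinct embeddings into the same basin,
and deduplicating first would keep redundant poses). The criterion is
R-group heavy-atom RMSD < 0.5 Å, configurable; a grown region with no
heavy atoms (hydrogen or single-halogen growth) keeps exactly one
conformer. The user can exempt additional core atoms from restraints
(e.g. a linking –CH₂– that should rotate); grown atoms are always free.

The core ↔ ligand correspondence for restraints and FEP atom maps comes
from a maximum common substructure search (elements and exact bond orders
must match, rings map only to rings, 10 s timeout) with a deterministic
tie-break: among all placements of the MCS pattern, the one with the
lowest sum of atom indices (then lexicographic) wins. An MCS covering less
than half the template heavy atoms is treated as a core mismatch and
rejected.

## Receptor model

The receptor is rigid by contract: its coordinates are read once and
never enter the optimisation variables. Waters and other non-protein
residues are stripped on load unless retained by selector (`"HOH 305"`),
for example to keep a bridging water in the pocket; retained residues are
fixed like the protein. Alternate locations keep altloc A; occupancies
are ignored.

Structure completion is a built-in geometric fixer: missing backbone
carbonyl oxygens (and C-terminal OXT) are rebuilt from ideal internal
coordinates, existing hydrogens are discarded, and a full hydrogen set is
constructed from residue topology tables (tetrahedral/planar completion,
staggered methyls, anti hydroxyls) at pH-7 protonation states — His is
ε-protonated (HIE) unless the residue name says otherwise
(HID/HIP/ASH/GLH/CYX/LYN are honoured), Asp/Glu are deprotonated,
Lys/Arg protonated, termini charged. Missing backbone N/CA/C or
side-chain heavy atoms cannot be rebuilt (no loop or rotamer modelling)
and raise an error naming the residues. Because hydrogen construction is
purely geometric, fixing is deterministic and idempotent.

Nonbonded parameters come from a coarse built-in fixed-charge model:
polar groups carry local dipoles from a per-atom table, ionisable groups
their integer pH-7 charge, and a per-residue residual correction (applied
on CA) makes every residue's net charge exactly its formal charge — the
parameterisation invariant Σq = total formal charge holds to machine
precision by construction. Lennard-Jones parameters are element-based
(UFF homoatomic r_min/ε, arithmetic-mean r_min and geometric-mean ε
combining). This model is deliberately simple: it is adequate for ranking
poses in a softened pocket, not for absolute energetics, and the toy
receptors used in testing carry hand-assigned parameters of the same form
so the pocket physics is exercised independently of the protein tables.

## The hybrid pocket potential

E_tot = E_MM(R) + E_MM(RL) + E_lig(L) is a strict partition: the three
terms are evaluated separately and summed, so the decomposition closure
|E_tot − ΣE_i| < 10⁻⁶ kcal/mol is exact, and placing the same classical
force field in the "ML" slot reproduces the full-MM single point
bit-for-bit. E_MM(R) is the unscaled receptor-internal pairwise energy,
computed once (a constant; it can be excluded when only pose ranking
matters). The coupling term is open-boundary pairwise Coulomb + LJ 12-6
over all receptor–ligand pairs — no cutoff, no periodicity; systems are a
single fixed complex.

Scalings (optimisation and ranking use the same scaled potential, with an
unscaled re-score available):

* LJ: each pair's minimum-energy distance is multiplied by `lj_scale`
  (default 0.8); well depths unchanged. This opens space in the pocket to
  compensate for receptor rigidity.
* Electrostatics: all charges entering the coupling term — both partners —
  are multiplied by 1/√ε (default ε = 4), so every pair energy scales by
  exactly 1/ε. Ligand intramolecular electrostatics are not scaled.
  Scaling both partners (rather than the ligand only) is the
  implicit-dielectric reading adopted here and is stated as a package
  choice.

The ligand term is pluggable: UFF or MMFF94 via RDKit, or any registered
backend exposing energy/gradient in kcal/mol and Å — the intended slot
for ANI-style neural potentials. The ML gate admits a ligand only when
its elements are within {H, C, N, O, F, S, Cl}; otherwise the classical
force field is used and a warning names the offending elements. The
ligand always carries classical coupling parameters (Gasteiger charges,
element-based LJ) regardless of backend.

## Refinement, selection, measurement

Conformers with any ligand–receptor atom pair (hydrogens included) closer
than 1.0 Å are rejected before minimisation; the comparison is strict
(`< cutoff`), so a contact at exactly the cutoff survives. The fast
kd-tree implementation is tested against an explicit all-pairs oracle.

Pocket minimisation is L-BFGS on the ligand coordinates only, with
analytic gradients, up to 2000 iterations. The gradient-infinity-norm
tolerance is 10⁻⁴ kcal·mol⁻¹·Å⁻¹ — tighter than typical engine defaults
because shallow LJ wells (ε ≈ 0.1 kcal/mol) otherwise stop >0.01 Å short
of their analytic minimum, which would blur the scaling-law checks and
re-minimisation idempotence. Core restraints (same k as the vacuum stage,
referenced to the template pose so the objective is identical across
repeated minimisations) are on by default and user-disableable. The
reported energy is the unbiased E_tot; if the optimiser's endpoint has a
higher unbiased energy than the entry pose (possible when it trades
strain for restraint satisfaction), the entry pose is kept, so per-pose
energy never increases. Non-finite starting energies drop the conformer
with a log entry.

Selection keeps the lowest-energy conformer and all within 5 kcal/mol
(boundary inclusive), sorted by energy with index tie-breaks.

Pose metrics: R-group RMSD is computed without superposition (the
restrained core already provides a common frame), over heavy atoms, and
optionally minimised over topological automorphisms that permute the
R-group onto itself while fixing all other heavy atoms — a para-phenyl
flip is correctly measured as 0 Å. Dihedrals follow the IUPAC sign
convention in (−180°, 180°] and reject collinear definitions.

## Properties, liabilities, scoring

Ro5 uses Lipinski's original counting: donors = N–H plus O–H, acceptors =
N plus O, average molecular weight, Crippen clogP; ≤1 violation is
compliant. The synthetic accessibility score follows Ertl's construction
— per-atom Morgan radius-2 fragment log-frequency contributions plus
penalties for size, assigned stereocentres, spiro and bridgehead atoms
and macrocycles, with a symmetry bonus, affine-mapped to [1, 10]. The
fragment table shipped with the package is a small synthetic snapshot
generated from a combinatorially built drug-like reference set
(`scripts/make_sa_table.py`); scores are therefore approximate and the
table is swappable per call. Liability flags use the PAINS (A+B+C), NIH
and Brenk catalogs as bundled with RDKit, plus a loader for user SMARTS
catalog files (`SMARTS<TAB>label`).

External CNN re-scoring is a command contract:
`<exe> -r receptor.pdb -l poses.sdf --score_only`, parsing per-pose
CNNscore/CNNaffinity fields (names configurable) from stdout. Poses are
never moved; a missing scorer yields unscored records and the pipeline
continues; a failing scorer records the error per pose. pK converts to a
free energy with ΔG = −RT ln10 · pK at 298.15 K (a package choice; the
conversion temperature is configurable). Benchmark statistics are RMSE,
MUE and squared Pearson correlation, with r² reported as unset under zero
variance.

## Synthetic fixtures and what they show

The toy pocket is a quasi-uniform (Fibonacci-sphere, seed-jittered) shell
of C/N/O atoms at radii within [cavity_radius, cavity_radius + 3 Å] of a
cavity centre, with alternating ±0.2 e charges summing to exactly zero
and hand-assigned element LJ parameters. The bundled 24-member R-group
library spans the common medicinal-chemistry substituents (alkyl, aryl,
ether, amine, halide, nitrile, CF₃, acyl, a uracil-like heterocycle) and
includes a bromo fragment specifically to exercise the ML-element
fallback. Test peptides are built from ideal internal coordinates in an
extended conformation (GLY/ALA/SER/CYS/VAL/ASP/LYS supported).

These fixtures exercise every code path at desk scale, deterministically
and offline. They do not emulate real pockets: no hydrogen-bonding
geometry, no buried polar networks, no induced fit, no crystallographic
noise. Passing tests therefore demonstrate the correctness of the
machinery (merging, restraints, filtering, the potential's scaling laws,
determinism, file contracts) — not prediction quality on real
protein–ligand systems, which additionally depends on the ligand backend
and receptor parameterisation quality. Default problem sizes in the test
and acceptance runs (8 embeddings per ligand, 60-atom pockets) are chosen
as the smallest sizes that leave every stage nondegenerate; all
thresholds are the method's operating parameters, not tuned values.

## Known limitations

* Receptor charges are a coarse built-in model, not a protein force
  field; absolute coupling energies should not be over-interpreted.
* No missing-residue or side-chain rebuilding; such structures are
  rejected explicitly rather than silently repaired.
* Ligand coupling charges are Gasteiger, not AM1-BCC.
* The ML backend is an interface; no neural potential ships with the
  package.
* Growth is supported from hydrogen positions only; no linker
  replacement or scaffold hopping.
* No explicit-solvent treatment; retained crystallographic waters are
  rigid point sets.
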