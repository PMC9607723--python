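"""Pose refinement in the rigid pocket under a hybrid ML/MM-style potential.

The total energy is a strict mechanical-embedding partition

    E_tot = E_MM(R) + E_MM(RL) + E_lig(L)

where E_MM(R) is the (constant) receptor internal nonbonded energy,
E_MM(RL) the receptor–ligand Coulomb + Lennard-Jones 12-6 coupling, and
E_lig(L) the ligand intramolecular energy from a pluggable backend — a
classical force field (UFF/MMFF via RDKit) or a registered ML potential.
Two empirical scalings soften the rigid-receptor approximation during
optimisation: pairwise LJ minimum-energy distances are multiplied by
lj_scale (default 0.8), and all charges entering the coupling term are
scaled by 1/sqrt(epsilon) (default epsilon = 4), so pair Coulomb energies
scale by 1/epsilon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .constants import COULOMB_CONSTANT, ML_SUPPORTED_ELEMENTS, lj_parameters
from .errors import GrowkitError
from .mol_build import Conformer, ConformerEnsemble, GrownLigand
from .receptor import Receptor

logger = logging.getLogger(__name__)

__all__ = ["ScalingParams", "HybridPotential", "clash_filter", "backend_select",
           "build_hybrid_potential", "minimise_in_pocket", "select_low_energy",
           "rgroup_rmsd", "dihedral", "register_ml_backend"]


@dataclass(frozen=True)
class ScalingParams:
    """Empirical pocket-softening parameters for the coupling term."""

    lj_scale: float = 0.8
    epsilon: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.lj_scale <= 1:
            raise GrowkitError("lj_scale must be in (0, 1]")
        if self.epsilon < 1:
            raise GrowkitError("epsilon must be >= 1")

    @property
    def charge_scale(self) -> float:
        return self.epsilon ** -0.5


class LigandTerm(Protocol):
    """Intramolecular ligand energy backend."""

    def energy(self, coords: np.ndarray) -> float: ...

    def gradient(self, coords: np.ndarray) -> np.ndarray: ...


class RDKitForceFieldTerm:
    """Ligand intramolecular term from an RDKit force field (UFF or MMFF94)."""

    def __init__(self, mol: Chem.Mol, variant: str = "uff"):
        self.mol = Chem.Mol(mol)
        if self.mol.GetNumConformers() == 0:
            raise GrowkitError("ligand term needs a molecule with a conformer")
        if variant == "uff":
            self._ff = AllChem.UFFGetMoleculeForceField(self.mol)
        elif variant == "mmff":
            props = AllChem.MMFFGetMoleculeProperties(self.mol)
            if props is None:
                raise GrowkitError("MMFF typing failed for ligand")
            self._ff = AllChem.MMFFGetMoleculeForceField(self.mol, props)
        else:
            raise GrowkitError(f"unknown force field variant: {variant!r}")
        if self._ff is None:
            raise GrowkitError("force field construction failed")
        self.variant = variant

    def energy(self, coords: np.ndarray) -> float:
        return float(self._ff.CalcEnergy(
            [float(x) for x in np.asarray(coords).ravel()]))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        g = self._ff.CalcGrad([float(x) for x in np.asarray(coords).ravel()])
        return np.asarray(g, dtype=float).reshape(-1, 3)


class ZeroLigandTerm:
    """Null intramolecular term (single-atom or rigid test ligands)."""

    def energy(self, coords: np.ndarray) -> float:
        return 0.0

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(coords, float).reshape(-1, 3))


#: registry of ML ligand backends: name -> factory(mol) -> LigandTerm
_ML_BACKENDS: dict[str, Callable[[Chem.Mol], LigandTerm]] = {}


def register_ml_backend(name: str,
                        factory: Callable[[Chem.Mol], LigandTerm]) -> None:
    """Register a machine-learned ligand potential under ``name``.

    The factory takes the ligand molecule (with explicit hydrogens and a
    conformer) and returns an object with energy/gradient methods in
    kcal/mol and Å.  The built-in workflow only requires that the backend
    obeys this interface — any ANI-style model can be slotted in.
    """
    _ML_BACKENDS[name] = factory


def backend_select(ligand: GrownLigand, want_ml: bool,
                   ml_name: str = "ani", mm_name: str = "uff") -> str:
    """Choose the ligand intramolecular backend.

    ML is used only when requested and every element is covered by the
    model (H, C, N, O, F, S, Cl); otherwise the classical force field is
    used and a warning names the offending elements.
    """
    if not want_ml:
        return mm_name
    offending = sorted(set(ligand.elements) - ML_SUPPORTED_ELEMENTS)
    if offending:
        logger.warning(
            "ligand %r contains elements %s not covered by the ML potential; "
            "falling back to the classical force field %r",
            ligand.name, offending, mm_name)
        return mm_name
    return ml_name


@dataclass
class HybridPotential:
    """E_tot = E_MM(R) + E_MM(RL) + E_lig(L) over ligand coordinates.

    Receptor coordinates are frozen; only the ligand moves.  All charges
    entering the coupling term (both partners) are pre-scaled by
    1/sqrt(epsilon); pairwise LJ minimum-energy distances are pre-scaled by
    lj_scale.  The decomposition is exact: ``total_energy`` is the sum of
    the three term evaluations.
    """

    receptor_coords: np.ndarray
    receptor_charges: np.ndarray
    receptor_rmin: np.ndarray
    receptor_eps: np.ndarray
    ligand_charges: np.ndarray
    ligand_rmin: np.ndarray
    ligand_eps: np.ndarray
    ligand_term: LigandTerm
    scaling: ScalingParams = field(default_factory=ScalingParams)
    ligand: GrownLigand | None = None
    backend_name: str = "uff"
    include_receptor_term: bool = True

    def __post_init__(self) -> None:
        self.receptor_coords = np.asarray(self.receptor_coords, float).reshape(-1, 3)
        s = self.scaling.charge_scale
        # pair tables (N_lig x N_rec), scalings applied once
        self._qq = (COULOMB_CONSTANT
                    * np.outer(self.ligand_charges * s, self.receptor_charges * s))
        rmin_pair = 0.5 * np.add.outer(self.ligand_rmin, self.receptor_rmin)
        self._rmin = rmin_pair * self.scaling.lj_scale
        self._eps = np.sqrt(np.outer(self.ligand_eps, self.receptor_eps))
        self._receptor_energy: float | None = None

    # --- term evaluations ---------------------------------------------------

    def receptor_energy(self) -> float:
        """E_MM(R): unscaled receptor internal nonbonded energy (constant)."""
        if not self.include_receptor_term:
            return 0.0
        if self._receptor_energy is None:
            c = self.receptor_coords
            n = len(c)
            if n < 2:
                self._receptor_energy = 0.0
            else:
                iu, ju = np.triu_indices(n, k=1)
                d = np.linalg.norm(c[iu] - c[ju], axis=1)
                d = np.maximum(d, 1e-6)
                qq = COULOMB_CONSTANT * self.receptor_charges[iu] * self.receptor_charges[ju]
                rmin = 0.5 * (self.receptor_rmin[iu] + self.receptor_rmin[ju])
                eps = np.sqrt(self.receptor_eps[iu] * self.receptor_eps[ju])
                x6 = (rmin / d) ** 6
                self._receptor_energy = float(np.sum(qq / d)
                                              + np.sum(eps * (x6 * x6 - 2 * x6)))
        return self._receptor_energy

    def _pair_distances(self, lig_coords: np.ndarray) -> np.ndarray:
        diff = lig_coords[:, None, :] - self.receptor_coords[None, :, :]
        return diff, np.maximum(np.linalg.norm(diff, axis=2), 1e-6)

    def coupling_energy(self, lig_coords: np.ndarray) -> float:
        """E_MM(RL): scaled Coulomb + LJ 12-6 receptor-ligand energy."""
        if self.receptor_coords.shape[0] == 0:
            return 0.0
        lig = np.asarray(lig_coords, float).reshape(-1, 3)
        _, r = self._pair_distances(lig)
        x6 = (self._rmin / r) ** 6
        return float(np.sum(self._qq / r) + np.sum(self._eps * (x6 * x6 - 2 * x6)))

    def coupling_gradient(self, lig_coords: np.ndarray) -> np.ndarray:
        lig = np.asarray(lig_coords, float).reshape(-1, 3)
        if self.receptor_coords.shape[0] == 0:
            return np.zeros_like(lig)
        diff, r = self._pair_distances(lig)
        x6 = (self._rmin / r) ** 6
        # dE/dr per pair
        dEdr = -self._qq / r ** 2 - 12.0 * self._eps * (x6 * x6 - x6) / r
        return np.einsum("lr,lrk->lk", dEdr / r, diff)

    def ligand_energy(self, lig_coords: np.ndarray) -> float:
        return self.ligand_term.energy(lig_coords)

    def ligand_gradient(self, lig_coords: np.ndarray) -> np.ndarray:
        return self.ligand_term.gradient(lig_coords)

    def total_energy(self, lig_coords: np.ndarray) -> float:
        return (self.receptor_energy() + self.coupling_energy(lig_coords)
                + self.ligand_energy(lig_coords))

    def total_gradient(self, lig_coords: np.ndarray) -> np.ndarray:
        return self.coupling_gradient(lig_coords) + self.ligand_gradient(lig_coords)

    def decomposition(self, lig_coords: np.ndarray) -> dict[str, float]:
        return {
            "receptor": self.receptor_energy(),
            "coupling": self.coupling_energy(lig_coords),
            "ligand": self.ligand_energy(lig_coords),
        }


def build_hybrid_potential(ligand: GrownLigand, receptor: Receptor,
                           backend: str = "uff",
                           scaling: ScalingParams | None = None,
                           include_receptor_term: bool = True) -> HybridPotential:
    """Assemble the hybrid potential for one grown ligand in the pocket.

    The ligand always gets classical nonbonded parameters for the coupling
    term (Gasteiger charges, element-based LJ), regardless of the
    intramolecular backend.  ``backend`` is "uff", "mmff", or the name of a
    registered ML backend.
    """
    if not receptor.parameterised:
        raise GrowkitError("receptor must be parameterised first")
    scaling = scaling or ScalingParams()
    mol = Chem.Mol(ligand.mol)
    if mol.GetNumConformers() == 0 and len(ligand.ensemble):
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(ligand.ensemble[0].coords):
            conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
        mol.AddConformer(conf, assignId=True)

    AllChem.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    q = np.nan_to_num(q, nan=0.0, posinf=0.0, neginf=0.0)
    lj = np.array([lj_parameters(a.GetSymbol()) for a in mol.GetAtoms()])

    if backend in ("uff", "mmff"):
        term = RDKitForceFieldTerm(mol, variant=backend)
    elif backend in _ML_BACKENDS:
        term = _ML_BACKENDS[backend](mol)
    else:
        raise GrowkitError(
            f"unknown ligand backend {backend!r}; register an ML backend or "
            "use 'uff'/'mmff'")

    return HybridPotential(
        receptor_coords=receptor.coords,
        receptor_charges=receptor.charges,
        receptor_rmin=receptor.lj_rmin,
        receptor_eps=receptor.lj_eps,
        ligand_charges=q, ligand_rmin=lj[:, 0], ligand_eps=lj[:, 1],
        ligand_term=term, scaling=scaling, ligand=ligand,
        backend_name=backend, include_receptor_term=include_receptor_term)


def clash_filter(ensemble: ConformerEnsemble, receptor: Receptor,
                 cutoff: float = 1.0) -> ConformerEnsemble:
    """Drop conformers with any ligand-receptor atom pair closer than
    ``cutoff`` (strict <; all atoms, hydrogens included).  Rejected
    conformers are flagged ``clash_rejected``; survivors pass unchanged.
    """
    rc = receptor.coords
    if rc.shape[0] == 0:
        return ConformerEnsemble(list(ensemble))
    tree = cKDTree(rc)
    kept: list[Conformer] = []
    for c in ensemble:
        dmin, _ = tree.query(c.coords, k=1)
        if float(np.min(dmin)) < cutoff:
            c.flags.add("clash_rejected")
        else:
            kept.append(c)
    return ConformerEnsemble(kept)


def minimise_in_pocket(ensemble: ConformerEnsemble, potential: HybridPotential,
                       core_restraints: bool = True,
                       restraint_k: float = 1.0e4,
                       max_iterations: int = 2000,
                       force_tolerance: float = 1e-4) -> ConformerEnsemble:
    """Locally minimise each conformer under the hybrid potential.

    Receptor atoms never move (they are not variables).  With
    ``core_restraints`` the restrained core atoms are held at the template
    pose by harmonic restraints (k in kcal/mol/Å²), so the restrained
    objective is identical across repeated minimisations (idempotence).
    Final unbiased E_tot is stored per conformer and is never above the
    starting energy (the entry coordinates are kept if the optimiser only
    traded intramolecular strain for restraint satisfaction); conformers
    with non-finite starting energies are dropped with a log entry.
    """
    restrained: list[int] = []
    ref = None
    if core_restraints and potential.ligand is not None:
        restrained = potential.ligand.restrained_atoms
        ref_map = potential.ligand.core_reference_coords()
        if restrained:
            ref = np.array([ref_map[i] for i in restrained])

    out: list[Conformer] = []
    for idx, c in enumerate(ensemble):
        x0 = c.coords.ravel().copy()
        n = c.coords.shape[0]

        def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            coords = x.reshape(n, 3)
            e = potential.total_energy(coords)
            g = potential.total_gradient(coords)
            if restrained:
                d = coords[restrained] - ref
                e += float(restraint_k * np.sum(d * d))
                g = g.copy()
                g[restrained] += 2.0 * restraint_k * d
            return e, g.ravel()

        e0, _ = objective(x0)
        if not np.isfinite(e0):
            logger.warning("conformer %d has non-finite energy; dropped", idx)
            c.flags.add("clash_rejected")
            continue
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iterations,
                                "gtol": force_tolerance,
                                "ftol": 1e-12})
        # keep whichever pose has the lower unbiased energy
        e_start = potential.total_energy(x0.reshape(n, 3))
        e_final = potential.total_energy(res.x.reshape(n, 3))
        x_best, energy = ((res.x, e_final) if e_final <= e_start
                          else (x0, e_start))
        coords = x_best.reshape(n, 3)
        c.coords = coords
        c.energy = float(energy)
        c.flags.add("pocket_minimised")
        out.append(c)
    return ConformerEnsemble(out)


def select_low_energy(ensemble: ConformerEnsemble,
                      window: float = 5.0) -> ConformerEnsemble:
    """Keep the lowest-energy conformer and everything within ``window``
    kcal/mol of it (boundary inclusive), sorted ascending by energy with
    ties broken by conformer index."""
    indexed = [(c.energy, i, c) for i, c in enumerate(ensemble)
               if "clash_rejected" not in c.flags]
    if not indexed or any(e is None for e, _, _ in indexed):
        raise GrowkitError("select_low_energy requires energies on all conformers")
    e_min = min(e for e, _, _ in indexed)
    chosen = sorted(((e, i, c) for e, i, c in indexed if e - e_min <= window),
                    key=lambda t: (t[0], t[1]))
    for _, _, c in chosen:
        c.flags.add("selected")
    return ConformerEnsemble([c for _, _, c in chosen])


def _automorphisms(mol: Chem.Mol, max_matches: int = 10000) -> list[tuple[int, ...]]:
    return list(mol.GetSubstructMatches(mol, uniquify=False,
                                        useChirality=False,
                                        maxMatches=max_matches))


def rgroup_rmsd(pose_a: np.ndarray, pose_b: np.ndarray,
                rgroup_atoms: list[int], symmetry: bool = False,
                mol: Chem.Mol | None = None) -> float:
    """RMSD over the R-group atoms between two poses of the same molecule.

    No superposition is performed — the core is assumed to sit in a common
    frame.  With ``symmetry=True`` (requires ``mol``) the RMSD is minimised
    over topological automorphisms that permute the R-group onto itself
    while fixing every atom outside it.
    """
    if not rgroup_atoms:
        raise GrowkitError("rgroup_atoms must be non-empty")
    a = np.asarray(pose_a, float)
    b = np.asarray(pose_b, float)

    def _rmsd(perm: dict[int, int]) -> float:
        d = a[rgroup_atoms] - b[[perm[i] for i in rgroup_atoms]]
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    identity = {i: i for i in rgroup_atoms}
    best = _rmsd(identity)
    if symmetry:
        if mol is None:
            raise GrowkitError("symmetry-aware RMSD needs the molecule graph")
        rset = set(rgroup_atoms)
        fixed_heavy = [i for i in range(mol.GetNumAtoms())
                       if i not in rset and mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
        for match in _automorphisms(mol):
            if any(match[i] != i for i in fixed_heavy):
                continue
            if any(match[i] not in rset for i in rset):
                continue
            best = min(best, _rmsd({i: match[i] for i in rgroup_atoms}))
    return best


def dihedral(pose: np.ndarray, atoms: tuple[int, int, int, int]) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (-180, 180]."""
    if len(set(atoms)) != 4:
        raise GrowkitError("dihedral needs 4 distinct atoms")
    p = np.asarray(pose, float)[list(atoms)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GrowkitError("dihedral undefined for collinear atoms")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)
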