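"""Core/R-group definition, merging, and core-constrained conformer generation.

The growing strategy: a ligand *core* with a known binding pose is kept
(nearly) fixed while a user-chosen R-group replaces a marked hydrogen.
Conformers of the grown molecule are embedded by distance geometry with the
core atoms pinned to their crystallographic coordinates, aligned, and then
relaxed with a general-purpose vacuum force field under stiff harmonic
positional restraints (default k = 1e4 kcal/mol/Å²) on the restrained core
heavy atoms, so that only the grown region explores conformational space.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS
from rdkit.Geometry import Point3D

from .errors import AttachmentError, CoreMismatchError, EmbeddingError, GrowkitError

logger = logging.getLogger(__name__)

#: Flags a conformer can carry through the pipeline.
CONFORMER_FLAGS = ("embedded", "vacuum_minimised", "clash_rejected",
                   "pocket_minimised", "selected")


@dataclass
class Conformer:
    """One coordinate set (N_atoms × 3, Å) with optional energy (kcal/mol)."""

    coords: np.ndarray
    energy: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("conformer coordinates must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("conformer coordinates must be finite")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError("conformer energy must be finite")


class ConformerEnsemble:
    """Ordered collection of conformers of one molecule."""

    def __init__(self, conformers: list[Conformer] | None = None):
        self.conformers: list[Conformer] = list(conformers or [])
        n_atoms = {c.coords.shape[0] for c in self.conformers}
        if len(n_atoms) > 1:
            raise ValueError("all conformers must share the atom count")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    def active(self, exclude: str = "clash_rejected") -> list[Conformer]:
        """Conformers not carrying the given rejection flag."""
        return [c for c in self.conformers if exclude not in c.flags]

    def selected(self) -> list[Conformer]:
        return [c for c in self.conformers if "selected" in c.flags]

    @property
    def energies(self) -> list[float | None]:
        return [c.energy for c in self.conformers]


@dataclass
class EmbedConfig:
    """Settings for constrained conformer enumeration.

    restraint_k is the harmonic force constant (kcal/mol/Å²) pinning
    restrained core heavy atoms to the template pose; dedup_rmsd is the
    R-group heavy-atom RMSD (Å) below which two conformers count as
    duplicates.
    """

    n_conformers: int = 50
    seed: int = 2022
    restraint_k: float = 1.0e4
    dedup_rmsd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.restraint_k <= 0:
            raise ValueError("restraint_k must be positive")
        if self.dedup_rmsd < 0:
            raise ValueError("dedup_rmsd must be non-negative")


@dataclass
class LigandTemplate:
    """Ligand core with a 3D pose and a marked attachment hydrogen."""

    mol: Chem.Mol
    attachment_h: int
    flexible_atoms: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = self.mol.GetNumAtoms()
        if not 0 <= self.attachment_h < n:
            raise AttachmentError(
                f"attachment index {self.attachment_h} out of range (0..{n - 1})")
        atom = self.mol.GetAtomWithIdx(self.attachment_h)
        if atom.GetAtomicNum() != 1:
            raise AttachmentError(
                "attachment atom must be hydrogen: growth only from hydrogen "
                f"is supported (atom {self.attachment_h} is {atom.GetSymbol()})")
        if atom.GetDegree() != 1:
            raise AttachmentError("attachment hydrogen must have exactly one bond")
        if self.mol.GetNumConformers() == 0:
            raise AttachmentError("core must carry 3D coordinates")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise AttachmentError("core coordinates must be finite")
        if np.allclose(coords[:, 2], 0.0) and n > 3:
            raise AttachmentError(
                "core appears to be 2D (all z = 0); a 3D pose is required")
        if not self.flexible_atoms <= set(range(n)):
            raise AttachmentError("flexible_atoms outside atom range")
        if self.attachment_h in self.flexible_atoms:
            raise AttachmentError("attachment hydrogen cannot be flexible")

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def heavy_atoms(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]


@dataclass
class RGroup:
    """Connected fragment with a marked heavy attachment atom.

    The molecule always carries explicit hydrogens.  If the fragment was
    built from SMILES with a ``[*]`` placeholder, the dummy atom is kept and
    consumed when the bond to the core is formed; otherwise one hydrogen on
    ``attachment_atom`` is consumed instead.
    """

    mol: Chem.Mol
    attachment_atom: int
    label: str = ""

    def __post_init__(self) -> None:
        n = self.mol.GetNumAtoms()
        if not 0 <= self.attachment_atom < n:
            raise AttachmentError("R-group attachment index out of range")
        if len(Chem.GetMolFrags(self.mol)) != 1:
            raise AttachmentError("R-group must be a single connected fragment")
        atom = self.mol.GetAtomWithIdx(self.attachment_atom)
        has_dummy = any(nb.GetAtomicNum() == 0 for nb in atom.GetNeighbors())
        has_h = (atom.GetTotalNumHs(includeNeighbors=True) > 0
                 or atom.GetAtomicNum() == 1)
        if not (has_dummy or has_h):
            raise AttachmentError(
                f"R-group attachment atom {self.attachment_atom} has no hydrogen "
                "or attachment placeholder to consume")

    @classmethod
    def from_smiles(cls, smiles: str, label: str = "") -> "RGroup":
        """Parse a fragment SMILES with the attachment marked as ``[*]``
        (or atom map number 1 on the attachment atom)."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise AttachmentError(f"unparseable R-group SMILES: {smiles!r}")
        from rdkit import rdBase
        with rdBase.BlockLogs():
            mol = Chem.AddHs(mol)
        dummy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if dummy:
            if len(dummy) > 1:
                raise AttachmentError("R-group must have exactly one [*]")
            neighbors = mol.GetAtomWithIdx(dummy[0]).GetNeighbors()
            if len(neighbors) != 1:
                raise AttachmentError("[*] placeholder must have one bond")
            return cls(mol=mol, attachment_atom=neighbors[0].GetIdx(), label=label)
        mapped = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() == 1]
        if not mapped:
            raise AttachmentError(
                "R-group SMILES needs a [*] placeholder or atom map 1")
        return cls(mol=mol, attachment_atom=mapped[0], label=label)

    @classmethod
    def from_file(cls, path: str | Path, attachment_atom: int | None = None,
                  label: str = "") -> "RGroup":
        """Load an SDF/MOL fragment; the attachment atom is either given
        explicitly or marked by a ``*`` dummy in the file."""
        mol = Chem.MolFromMolFile(str(path), removeHs=False)
        if mol is None:
            raise AttachmentError(f"unparseable R-group file: {path}")
        mol = Chem.AddHs(mol)
        if attachment_atom is None:
            dummy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
            if len(dummy) != 1:
                raise AttachmentError(
                    f"{path}: pass attachment_atom or mark it with one dummy atom")
            attachment_atom = mol.GetAtomWithIdx(dummy[0]).GetNeighbors()[0].GetIdx()
        return cls(mol=mol, attachment_atom=attachment_atom,
                   label=label or Path(path).stem)


@dataclass
class GrownLigand:
    """Merged core + R-group molecule, with provenance back to the template.

    core_map maps template atom index → merged-molecule atom index for every
    template atom except the replaced hydrogen; rgroup_atoms are the indices
    of the newly grown atoms; flexible_core holds merged-molecule core atoms
    exempted from positional restraints.
    """

    mol: Chem.Mol
    template: LigandTemplate
    core_map: dict[int, int]
    rgroup_atoms: set[int]
    name: str = ""
    flexible_core: set[int] = field(default_factory=set)
    ensemble: ConformerEnsemble = field(default_factory=ConformerEnsemble)
    provenance: list[str] = field(default_factory=list)

    @property
    def restrained_atoms(self) -> list[int]:
        """Core heavy atoms that receive positional restraints (merged-mol
        indices): all mapped template heavy atoms minus the flexible set."""
        heavy = set(self.template.heavy_atoms)
        out = [m for t, m in self.core_map.items()
               if t in heavy and m not in self.flexible_core]
        return sorted(out)

    @property
    def rgroup_heavy_atoms(self) -> list[int]:
        return sorted(i for i in self.rgroup_atoms
                      if self.mol.GetAtomWithIdx(i).GetAtomicNum() > 1)

    def core_reference_coords(self) -> dict[int, np.ndarray]:
        """Merged-mol index → template coordinate for every mapped atom."""
        tcoords = self.template.coords
        return {m: tcoords[t] for t, m in self.core_map.items()}

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]


def _read_structure(path: str | Path) -> Chem.Mol:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".sdf", ".mol", ".mdl"}:
        mol = Chem.MolFromMolFile(str(path), removeHs=False)
    elif suffix == ".pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=False)
    elif suffix in {".mol2"}:
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
    else:
        raise GrowkitError(f"unsupported core format: {path.suffix!r}")
    if mol is None:
        raise GrowkitError(f"unparseable structure file: {path}")
    return mol


def load_core(structure_file: str | Path, attachment_h: int) -> LigandTemplate:
    """Load the ligand core with its 3D pose and validate the attachment
    hydrogen (index 0-based).  Growth is only supported from hydrogens."""
    mol = _read_structure(structure_file)
    mol = Chem.AddHs(mol, addCoords=True)
    return LigandTemplate(mol=mol, attachment_h=attachment_h)


def attach(template: LigandTemplate, rgroup: RGroup) -> GrownLigand:
    """Replace the template's attachment hydrogen with the R-group.

    The attachment hydrogen is deleted, a single bond is formed between its
    former heavy-atom neighbour and the R-group attachment atom, and one
    hydrogen (or the ``[*]`` placeholder, if present) is consumed from the
    R-group side.  Template coordinates are copied onto the core atoms.
    """
    tmol, rmol = template.mol, rgroup.mol
    n_t = tmol.GetNumAtoms()
    anchor = tmol.GetAtomWithIdx(template.attachment_h).GetNeighbors()[0].GetIdx()

    # Identity growth: an R-group that is a bare hydrogen leaves the core as is.
    real_atoms = [a for a in rmol.GetAtoms() if a.GetAtomicNum() != 0]
    if len(real_atoms) == 1 and real_atoms[0].GetAtomicNum() == 1:
        merged = Chem.Mol(tmol)
        return GrownLigand(
            mol=merged, template=template,
            core_map={i: i for i in range(n_t) if i != template.attachment_h},
            rgroup_atoms={template.attachment_h},
            name=rgroup.label or "H",
            flexible_core=set(template.flexible_atoms),
            provenance=[f"identity growth of hydrogen R-group {rgroup.label!r}"],
        )

    combo = Chem.RWMol(Chem.CombineMols(tmol, rmol))
    r_attach = n_t + rgroup.attachment_atom

    # Consume the R-group's placeholder dummy or one explicit hydrogen.
    to_remove = [template.attachment_h]
    r_atom = combo.GetAtomWithIdx(r_attach)
    dummies = [nb.GetIdx() for nb in r_atom.GetNeighbors() if nb.GetAtomicNum() == 0]
    if dummies:
        to_remove.append(dummies[0])
    else:
        hs = [nb.GetIdx() for nb in r_atom.GetNeighbors() if nb.GetAtomicNum() == 1]
        if hs:
            to_remove.append(hs[0])
        elif r_atom.GetNumImplicitHs() == 0:
            raise AttachmentError(
                f"R-group attachment atom has full valence and no hydrogen "
                f"to consume ({rgroup.label!r})")

    combo.AddBond(anchor, r_attach, Chem.BondType.SINGLE)
    for idx in sorted(to_remove, reverse=True):
        combo.RemoveAtom(idx)

    def _shift(i: int) -> int:
        return i - sum(1 for r in to_remove if r < i)

    merged = combo.GetMol()
    try:
        Chem.SanitizeMol(merged)
    except Exception as exc:  # valence violations surface here
        raise AttachmentError(f"merge produced an invalid molecule: {exc}") from exc
    if len(Chem.GetMolFrags(merged)) != 1:
        raise AttachmentError("merge produced a disconnected molecule")

    core_map = {i: _shift(i) for i in range(n_t) if i != template.attachment_h}
    rgroup_atoms = {_shift(n_t + i) for i in range(rmol.GetNumAtoms())
                    if n_t + i not in to_remove}

    # Seed a conformer: core atoms at the template pose, grown atoms placed
    # crudely along the former C–H vector (refined later by embedding).
    conf = Chem.Conformer(merged.GetNumAtoms())
    tcoords = template.coords
    h_dir = tcoords[template.attachment_h] - tcoords[anchor]
    h_dir /= max(np.linalg.norm(h_dir), 1e-9)
    base = tcoords[anchor]
    for t_idx, m_idx in core_map.items():
        conf.SetAtomPosition(m_idx, Point3D(*tcoords[t_idx]))
    for k, m_idx in enumerate(sorted(rgroup_atoms)):
        p = base + h_dir * (1.5 + 0.3 * k)
        conf.SetAtomPosition(m_idx, Point3D(*p))
    merged.RemoveAllConformers()
    merged.AddConformer(conf, assignId=True)

    expected_q = (Chem.GetFormalCharge(tmol) + Chem.GetFormalCharge(rmol))
    if Chem.GetFormalCharge(merged) != expected_q:
        raise AttachmentError("formal charge not conserved by merge")

    return GrownLigand(
        mol=merged, template=template, core_map=core_map,
        rgroup_atoms=rgroup_atoms, name=rgroup.label,
        flexible_core={core_map[i] for i in template.flexible_atoms
                       if i in core_map},
        provenance=[f"attached R-group {rgroup.label!r} at template H "
                    f"{template.attachment_h} (anchor {anchor})"],
    )


def extend_flexible(ligand: GrownLigand, atom_ids: set[int]) -> GrownLigand:
    """Exempt the given core atoms (merged-molecule indices) from positional
    restraints in all subsequent minimisations."""
    core_atoms = set(ligand.core_map.values())
    bad = set(atom_ids) - core_atoms
    if bad:
        raise GrowkitError(
            f"atoms {sorted(bad)} are not core atoms (grown R-group atoms are "
            "already flexible)")
    ligand.flexible_core |= set(atom_ids)
    if atom_ids:
        ligand.provenance.append(f"flexible core extended by {sorted(atom_ids)}")
    return ligand


def _rgroup_rmsd_plain(a: np.ndarray, b: np.ndarray, atoms: list[int]) -> float:
    d = a[atoms] - b[atoms]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def enumerate_conformers(ligand: GrownLigand,
                         cfg: EmbedConfig | None = None) -> ConformerEnsemble:
    """Embed, align and restrained-minimise conformers of the grown ligand.

    Distance-geometry embeddings (ETKDG) are seeded from cfg.seed with the
    core atoms pinned through a coordinate map, aligned onto the template
    pose, snapped, and minimised with UFF plus harmonic positional restraints
    (k = cfg.restraint_k) on the restrained core heavy atoms.  Near-duplicate
    conformers (R-group heavy-atom RMSD < cfg.dedup_rmsd) are removed,
    keeping the first occurrence.
    """
    cfg = cfg or EmbedConfig()
    mol = Chem.Mol(ligand.mol)
    ref = ligand.core_reference_coords()
    heavy_core = [m for t, m in ligand.core_map.items()
                  if ligand.template.mol.GetAtomWithIdx(t).GetAtomicNum() > 1]

    coord_map = {m: Point3D(*ref[m]) for m in heavy_core}
    params = AllChem.ETKDGv3()
    params.randomSeed = cfg.seed
    params.numThreads = 1
    params.clearConfs = True
    params.useRandomCoords = True
    params.SetCoordMap(coord_map)
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=cfg.n_conformers, params=params)
    if len(cids) == 0:
        raise EmbeddingError(
            f"all {cfg.n_conformers} embedding attempts failed for "
            f"{ligand.name!r} (seed {cfg.seed})")

    atom_map = [(m, t) for t, m in sorted(ligand.core_map.items())
                if ligand.template.mol.GetAtomWithIdx(t).GetAtomicNum() > 1]
    restrained = ligand.restrained_atoms
    conformers: list[Conformer] = []
    for cid in cids:
        AllChem.AlignMol(mol, ligand.template.mol, prbCid=cid, refCid=0,
                         atomMap=atom_map)
        conf = mol.GetConformer(cid)
        for m in restrained:
            conf.SetAtomPosition(m, Point3D(*ref[m]))
        ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
        if ff is None:
            continue
        for m in restrained:
            ff.UFFAddPositionConstraint(m, 0.0, cfg.restraint_k)
        ff.Initialize()
        ff.Minimize(maxIts=2000)
        energy = float(ff.CalcEnergy())
        coords = np.asarray(conf.GetPositions(), dtype=float)
        conformers.append(Conformer(coords=coords, energy=energy,
                                    flags={"embedded", "vacuum_minimised"}))

    if not conformers:
        raise EmbeddingError(f"force-field setup failed for {ligand.name!r}")

    ligand.ensemble = dedup_ensemble(ConformerEnsemble(conformers),
                                     ligand.rgroup_heavy_atoms, cfg.dedup_rmsd)
    ligand.provenance.append(
        f"enumerated {len(cids)} embeddings -> {len(ligand.ensemble)} "
        f"unique conformers (seed {cfg.seed})")
    return ligand.ensemble


def dedup_ensemble(ensemble: ConformerEnsemble, rgroup_heavy: list[int],
                   threshold: float) -> ConformerEnsemble:
    """Remove near-duplicate conformers by R-group heavy-atom RMSD,
    keeping the earliest conformer of each cluster.  With no R-group heavy
    atoms every conformer is a duplicate of the first."""
    kept: list[Conformer] = []
    for c in ensemble:
        dup = False
        for k in kept:
            if not rgroup_heavy:
                dup = True
                break
            if _rgroup_rmsd_plain(c.coords, k.coords, rgroup_heavy) < threshold:
                dup = True
                break
        if not dup:
            kept.append(c)
    return ConformerEnsemble(kept)


def _heavy_copy(mol: Chem.Mol) -> Chem.Mol:
    """Heavy-atom copy with original indices stored as atom map numbers."""
    m = Chem.Mol(mol)
    for atom in m.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    return Chem.RemoveHs(m)


def core_mapping(ligand_mol: Chem.Mol, template: LigandTemplate,
                 timeout: int = 10) -> dict[int, int]:
    """Maximum common substructure map: template heavy-atom index → ligand
    atom index.  Matching requires equal elements and bond orders, rings map
    only to rings, and ties are broken deterministically by the lowest sum of
    matched indices.  Raises CoreMismatchError when the MCS covers less than
    half of the template heavy atoms.
    """
    t_heavy = _heavy_copy(template.mol)
    l_heavy = _heavy_copy(ligand_mol)
    res = rdFMCS.FindMCS(
        [t_heavy, l_heavy], timeout=timeout,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        ringMatchesRingOnly=True, completeRingsOnly=False)
    patt = Chem.MolFromSmarts(res.smartsString) if res.numAtoms else None
    n_template_heavy = t_heavy.GetNumAtoms()
    if patt is None or res.numAtoms < 0.5 * n_template_heavy:
        raise CoreMismatchError(
            f"common core covers only {res.numAtoms}/{n_template_heavy} "
            "template heavy atoms")

    def best_match(mol: Chem.Mol) -> tuple[int, ...]:
        matches = mol.GetSubstructMatches(patt, uniquify=False, maxMatches=10000)
        if not matches:
            raise CoreMismatchError("MCS pattern failed to re-match")
        return min(matches, key=lambda m: (sum(m), m))

    t_match = best_match(t_heavy)
    l_match = best_match(l_heavy)
    out = {}
    for ti, li in zip(t_match, l_match):
        t_orig = t_heavy.GetAtomWithIdx(ti).GetAtomMapNum() - 1
        l_orig = l_heavy.GetAtomWithIdx(li).GetAtomMapNum() - 1
        out[t_orig] = l_orig
    return out
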