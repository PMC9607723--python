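"""End-to-end growing pipeline: configuration, batch driver, FEP preparation.

One ``run_grow`` call takes a receptor, a core with a marked attachment
hydrogen and an R-group library through: attach → constrained conformer
enumeration → steric clash filter → backend selection → pocket
minimisation → energy-window selection → property report → optional
re-scoring, writing per-ligand SDF poses, complex PDBs, CSV tables and a
machine-readable run log.  Failures are recorded per ligand and the batch
continues.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from rdkit import Chem
from rdkit.Chem import rdFMCS
from rdkit.Geometry import Point3D

from . import fixtures as fx
from .errors import ConfigError, GrowkitError
from .mol_build import (EmbedConfig, GrownLigand, LigandTemplate, RGroup,
                        attach, enumerate_conformers, load_core)
from .pocket import (ScalingParams, backend_select, build_hybrid_potential,
                     clash_filter, minimise_in_pocket, select_low_energy)
from .props import property_report
from .receptor import (Receptor, fix_receptor, load_receptor,
                       parameterise_receptor, write_receptor_pdb)
from .scoring import ScorerCommand, score_poses

logger = logging.getLogger(__name__)

__all__ = ["WorkflowConfig", "run_grow", "write_fep_inputs", "write_poses_sdf",
           "write_complex_pdb", "prepare_receptor"]


class WorkflowConfig(BaseModel):
    """Validated workflow parameters; defaults are the method's published
    operating point (restraint k = 1e4 kcal/mol/Å², 1.0 Å clash cutoff,
    LJ scale 0.8, dielectric 4, 5 kcal/mol selection window)."""

    model_config = ConfigDict(extra="forbid")

    receptor: str
    core: str
    attach_idx: int
    rgroups: str = "toy"                       # "toy" or path to a TSV index
    out_dir: str = "growkit_out"
    n_conformers: int = Field(default=50, ge=1)
    seed: int = 2022
    restraint_k: float = Field(default=1.0e4, gt=0)
    dedup_rmsd: float = 0.5
    lj_scale: float = Field(default=0.8, gt=0, le=1)
    epsilon: float = Field(default=4.0, ge=1)
    clash_cutoff: float = Field(default=1.0, ge=0)
    energy_window: float = Field(default=5.0, ge=0)
    use_ml: bool = False
    mm_backend: str = "uff"
    keep_residues: list[str] = Field(default_factory=list)
    scorer: str | None = None
    core_restraints: bool = True
    flexible_atoms: list[int] = Field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        """Load from a YAML or TOML file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        elif path.suffix == ".toml":
            import tomllib
            data = tomllib.loads(text)
        else:
            raise ConfigError(f"unsupported config format: {path.suffix!r}")
        try:
            return cls(**data)
        except Exception as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


def prepare_receptor(path: str | Path,
                     keep_residues: list[str] | None = None) -> Receptor:
    """Load, fix and parameterise a receptor PDB.  Toy pockets (all-``TOY``
    residues, as written by the fixture generator) get their hand-assigned
    parameters instead of the protein model."""
    keep = keep_residues
    if not keep and _is_toy_pdb(path):
        keep = ["TOY"]
    rec = load_receptor(path, keep_residues=keep)
    if all(a.resname == "TOY" for a in rec.atoms):
        return fx.assign_toy_parameters(rec)
    rec = fix_receptor(rec)
    return parameterise_receptor(rec)


def _is_toy_pdb(path: str | Path) -> bool:
    try:
        text = Path(path).read_text()
    except OSError:
        return False
    return " TOY " in text


def _load_library(spec: str) -> list[RGroup]:
    if spec == "toy":
        return fx.toy_rgroup_library()
    p = Path(spec)
    if p.is_dir():
        p = p / "index.tsv"
    return fx.load_rgroup_library(p)


@dataclass
class LigandResult:
    name: str
    ligand: GrownLigand | None = None
    counts: dict[str, int] = field(default_factory=dict)
    error: str | None = None
    out_dir: Path | None = None


def run_grow(config: WorkflowConfig) -> dict:
    """Execute the full growing pipeline; returns the run log as a dict
    (also written to ``<out_dir>/run_log.json``)."""
    t_start = time.time()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    logger.info("run_grow starting: %s", config.model_dump())

    receptor = prepare_receptor(config.receptor, config.keep_residues or None)
    template = load_core(config.core, config.attach_idx)
    library = _load_library(config.rgroups)
    scaling = ScalingParams(lj_scale=config.lj_scale, epsilon=config.epsilon)
    embed_cfg = EmbedConfig(n_conformers=config.n_conformers, seed=config.seed,
                            restraint_k=config.restraint_k,
                            dedup_rmsd=config.dedup_rmsd)

    results: list[LigandResult] = []
    prop_rows, score_rows = [], []
    for rgroup in library:
        res = LigandResult(name=rgroup.label)
        try:
            res = _grow_one(rgroup, template, receptor, config, scaling,
                            embed_cfg, out_root)
        except GrowkitError as exc:
            res.error = str(exc)
            logger.warning("ligand %s failed: %s", rgroup.label, exc)
        results.append(res)
        if res.ligand is not None and res.error is None:
            report = property_report(res.ligand.mol)
            prop_rows.append({"name": res.name, **report.as_dict()})
            if config.scorer:
                records = score_poses(
                    res.out_dir / "poses.sdf", out_root / "receptor.pdb",
                    ScorerCommand(executable=config.scorer))
                for rec in records:
                    score_rows.append({
                        "name": res.name, "pose_id": rec.pose_id,
                        "cnn_pose_score": rec.cnn_pose_score,
                        "cnn_affinity": rec.cnn_affinity,
                        "dg_pred": rec.dg_pred, "error": rec.error})

    write_receptor_pdb(receptor, out_root / "receptor.pdb")
    if prop_rows:
        pd.DataFrame(prop_rows).to_csv(out_root / "properties.csv", index=False)
    if score_rows:
        pd.DataFrame(score_rows).to_csv(out_root / "scores.csv", index=False)

    log = {
        "config": config.model_dump(),
        "n_rgroups": len(library),
        "elapsed_s": round(time.time() - t_start, 2),
        "ligands": [
            {"name": r.name, "counts": r.counts, "error": r.error,
             "out_dir": str(r.out_dir) if r.out_dir else None}
            for r in results],
    }
    (out_root / "run_log.json").write_text(json.dumps(log, indent=2))
    return log


def _grow_one(rgroup: RGroup, template: LigandTemplate, receptor: Receptor,
              config: WorkflowConfig, scaling: ScalingParams,
              embed_cfg: EmbedConfig, out_root: Path) -> LigandResult:
    res = LigandResult(name=rgroup.label)
    ligand = attach(template, rgroup)
    if config.flexible_atoms:
        merged = {ligand.core_map[i] for i in config.flexible_atoms
                  if i in ligand.core_map}
        ligand.flexible_core |= merged
    res.ligand = ligand

    ensemble = enumerate_conformers(ligand, embed_cfg)
    res.counts["embedded"] = len(ensemble)
    survivors = clash_filter(ensemble, receptor, config.clash_cutoff)
    res.counts["after_clash_filter"] = len(survivors)
    if len(survivors) == 0:
        res.error = "no conformers survive the steric clash filter"
        return res

    backend = backend_select(ligand, config.use_ml, mm_name=config.mm_backend)
    res.counts["backend_" + backend] = 1
    potential = build_hybrid_potential(ligand, receptor, backend, scaling,
                                       include_receptor_term=False)
    minimised = minimise_in_pocket(survivors, potential,
                                   core_restraints=config.core_restraints,
                                   restraint_k=config.restraint_k)
    res.counts["pocket_minimised"] = len(minimised)
    if len(minimised) == 0:
        res.error = "all conformers dropped during pocket minimisation"
        return res
    selected = select_low_energy(minimised, config.energy_window)
    res.counts["selected"] = len(selected)
    ligand.ensemble = selected

    lig_dir = out_root / (rgroup.label or "ligand")
    lig_dir.mkdir(parents=True, exist_ok=True)
    write_poses_sdf(ligand, lig_dir / "poses.sdf")
    write_complex_pdb(receptor, ligand, selected[0].coords,
                      lig_dir / "complex.pdb")
    res.out_dir = lig_dir
    return res


def write_poses_sdf(ligand: GrownLigand, path: str | Path,
                    conformers=None) -> None:
    """Write poses as a multi-record SDF with energy and flags as SD tags."""
    conformers = conformers if conformers is not None else list(ligand.ensemble)
    writer = Chem.SDWriter(str(path))
    try:
        for i, c in enumerate(conformers):
            mol = Chem.Mol(ligand.mol)
            mol.RemoveAllConformers()
            conf = Chem.Conformer(mol.GetNumAtoms())
            for j, p in enumerate(c.coords):
                conf.SetAtomPosition(j, Point3D(*p))
            mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", f"{ligand.name}_pose{i}")
            if c.energy is not None:
                mol.SetProp("E_tot_kcal_mol", f"{c.energy:.6f}")
            mol.SetProp("flags", ",".join(sorted(c.flags)))
            writer.write(mol)
    finally:
        writer.close()


def write_complex_pdb(receptor: Receptor, ligand: GrownLigand,
                      lig_coords: np.ndarray, path: str | Path) -> None:
    """Receptor + ligand (as HETATM chain L, residue LIG) in one PDB."""
    import gemmi

    st = gemmi.Structure()
    st.name = "complex"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for key, idxs in receptor.residues():
        chain_name, resseq, resname = key
        chains.setdefault(chain_name, gemmi.Chain(chain_name or "A"))
        r = gemmi.Residue()
        r.name = resname
        r.seqid = gemmi.SeqId(resseq, " ")
        r.het_flag = "A"
        for i in idxs:
            a = receptor.atoms[i]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = 1.0
            r.add_atom(at)
        chains[chain_name].add_residue(r)

    lig_chain = gemmi.Chain("L")
    lr = gemmi.Residue()
    lr.name = "LIG"
    lr.seqid = gemmi.SeqId(1, " ")
    lr.het_flag = "H"
    counts: dict[str, int] = {}
    for atom, p in zip(ligand.mol.GetAtoms(), np.asarray(lig_coords)):
        el = atom.GetSymbol()
        counts[el] = counts.get(el, 0) + 1
        at = gemmi.Atom()
        at.name = f"{el}{counts[el]}"
        at.element = gemmi.Element(el)
        at.pos = gemmi.Position(*p)
        at.occ = 1.0
        lr.add_atom(at)
    lig_chain.add_residue(lr)

    for ch in chains.values():
        model.add_chain(ch)
    model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def pairwise_atom_map(mol_a: Chem.Mol, mol_b: Chem.Mol,
                      timeout: int = 10) -> dict[int, int]:
    """Heavy-atom map between two ligands from their pairwise MCS
    (deterministic lowest-index tie-break); raises when the molecules share
    no meaningful common substructure."""
    from .mol_build import _heavy_copy

    a_heavy, b_heavy = _heavy_copy(mol_a), _heavy_copy(mol_b)
    res = rdFMCS.FindMCS([a_heavy, b_heavy], timeout=timeout,
                         atomCompare=rdFMCS.AtomCompare.CompareElements,
                         bondCompare=rdFMCS.BondCompare.CompareOrderExact,
                         ringMatchesRingOnly=True)
    if res.numAtoms < 2:
        raise GrowkitError("ligands share no common core")
    patt = Chem.MolFromSmarts(res.smartsString)

    def best(mol):
        matches = mol.GetSubstructMatches(patt, uniquify=False, maxMatches=10000)
        if not matches:
            raise GrowkitError("MCS pattern failed to re-match")
        return min(matches, key=lambda m: (sum(m), m))

    return {a_heavy.GetAtomWithIdx(ia).GetAtomMapNum() - 1:
            b_heavy.GetAtomWithIdx(ib).GetAtomMapNum() - 1
            for ia, ib in zip(best(a_heavy), best(b_heavy))}


def write_fep_inputs(ligand_a: GrownLigand, ligand_b: GrownLigand,
                     receptor: Receptor, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle a relative binding free energy setup consumes:
    receptor PDB, each ligand's lowest-energy selected pose as SDF, and a
    TSV atom map (index_a, index_b) over the pairwise MCS."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    files: dict[str, Path] = {}
    files["receptor"] = outdir / "receptor.pdb"
    write_receptor_pdb(receptor, files["receptor"])
    for tag, lig in (("a", ligand_a), ("b", ligand_b)):
        sel = lig.ensemble.selected() or list(lig.ensemble)
        if not sel:
            raise GrowkitError(f"ligand {lig.name!r} has no poses")
        best_pose = min(sel, key=lambda c: (c.energy if c.energy is not None
                                            else np.inf))
        files[f"ligand_{tag}"] = outdir / f"ligand_{tag}.sdf"
        write_poses_sdf(lig, files[f"ligand_{tag}"], conformers=[best_pose])

    amap = pairwise_atom_map(ligand_a.mol, ligand_b.mol)
    files["atom_map"] = outdir / "atom_map.tsv"
    with open(files["atom_map"], "w") as fh:
        fh.write("index_a\tindex_b\n")
        for ia, ib in sorted(amap.items()):
            fh.write(f"{ia}\t{ib}\n")
    return files
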