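"""Rigid receptor: loading, sanitising, protonation and nonbonded parameters.

The receptor is an immovable set of atoms: every downstream stage treats its
coordinates as constants.  Waters and other non-protein residues are
stripped on load unless explicitly retained (e.g. a bridging water in the
binding site).  Structure completion is handled by a built-in fixer that
reconstructs missing backbone carbonyl/terminal oxygens and places all
hydrogens geometrically at pH-7 protonation states; nonbonded parameters
come from a coarse built-in fixed-charge model with element-based
Lennard-Jones parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import _protein_data as pdat
from ._geometry import (hydrogens_planar_1, hydrogens_terminal,
                        hydrogens_tetra_1, hydrogens_tetra_2, hydrogens_water,
                        place_atom)
from .constants import lj_parameters
from .errors import ReceptorError

__all__ = ["Receptor", "load_receptor", "fix_receptor", "parameterise_receptor",
           "write_receptor_pdb"]


@dataclass
class Atom:
    name: str
    element: str
    resname: str
    resseq: int
    chain: str
    coords: np.ndarray  # (3,) Å


@dataclass
class Receptor:
    """Fixed-position atom set with optional nonbonded parameters."""

    atoms: list[Atom] = field(default_factory=list)
    charges: np.ndarray | None = None     # e
    lj_rmin: np.ndarray | None = None     # homoatomic r_min, Å
    lj_eps: np.ndarray | None = None      # kcal/mol
    retained_waters: list[tuple[str, str, int]] = field(default_factory=list)
    fixed_up: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def parameterised(self) -> bool:
        return self.charges is not None

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Atoms grouped by (chain, resseq, resname), input order preserved."""
        out: list[tuple[tuple[str, int, str], list[int]]] = []
        index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resseq, a.resname)
            if key not in index:
                index[key] = len(out)
                out.append((key, []))
            out[index[key]][1].append(i)
        return out

    def total_charge(self) -> float:
        if self.charges is None:
            raise ReceptorError("receptor is not parameterised")
        return float(np.sum(self.charges))


_TWO_LETTER = {"CL", "BR", "SE", "FE", "ZN", "MG", "MN", "NA", "CU", "NI", "CO"}


def _element_from_name(name: str) -> str:
    """Infer an element from a PDB atom name.  In amino-acid context the
    first letter wins (CA is a carbon); two-letter ions/halogens are
    recognised for hetero atoms."""
    stripped = name.strip(" 0123456789'\"")
    if not stripped:
        return "C"
    if stripped[:2].upper() in _TWO_LETTER and len(stripped) <= 2:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _match_selector(selector: str, resname: str, chain: str, resseq: int) -> bool:
    parts = selector.split()
    if len(parts) == 1:
        return resname == parts[0].upper()
    if len(parts) == 2:
        return resname == parts[0].upper() and str(resseq) == parts[1]
    if len(parts) == 3:
        return (resname == parts[0].upper() and chain == parts[1]
                and str(resseq) == parts[2])
    raise ReceptorError(f"unparseable residue selector: {selector!r}")


def load_receptor(pdb_file: str | Path,
                  keep_residues: list[str] | None = None) -> Receptor:
    """Load a PDB file, keeping protein residues and stripping waters and
    other hetero residues unless matched by a ``keep_residues`` selector
    (``"HOH"``, ``"HOH 305"`` or ``"HOH A 305"``).  Elements missing from
    the file are inferred from atom names.  Alternate locations: altloc A.
    """
    keep_residues = list(keep_residues or [])
    try:
        st = gemmi.read_structure(str(pdb_file))
    except Exception as exc:
        raise ReceptorError(f"unparseable PDB file {pdb_file}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ReceptorError(f"no models in {pdb_file}")

    atoms: list[Atom] = []
    retained: list[tuple[str, str, int]] = []
    matched = [False] * len(keep_residues)
    for chain in st[0]:
        for res in chain:
            resname = res.name.strip().upper()
            resseq = res.seqid.num
            is_protein = resname in pdat.PROTEIN_RESIDUES
            hits = [i for i, sel in enumerate(keep_residues)
                    if _match_selector(sel, resname, chain.name, resseq)]
            if not is_protein and not hits:
                continue
            for i in hits:
                matched[i] = True
            if not is_protein:
                retained.append((resname, chain.name, resseq))
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                el = atom.element.name if atom.element.name != "X" else ""
                if not el:
                    el = _element_from_name(atom.name)
                atoms.append(Atom(
                    name=atom.name.strip(), element=el, resname=resname,
                    resseq=resseq, chain=chain.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z])))

    for sel, hit in zip(keep_residues, matched):
        if not hit:
            raise ReceptorError(f"keep_residues selector matched nothing: {sel!r}")
    if not atoms:
        raise ReceptorError(f"no atoms retained from {pdb_file}")
    return Receptor(atoms=atoms, retained_waters=retained)


def _terminal_flags(receptor: Receptor) -> dict[tuple[str, int, str], tuple[bool, bool]]:
    """Per protein residue: (is_n_terminal, is_c_terminal) within its chain."""
    by_chain: dict[str, list[tuple[str, int, str]]] = {}
    for key, _ in receptor.residues():
        if key[2] in pdat.PROTEIN_RESIDUES:
            by_chain.setdefault(key[0], []).append(key)
    flags = {}
    for keys in by_chain.values():
        for k in keys:
            flags[k] = (k == keys[0], k == keys[-1])
    return flags


def fix_receptor(receptor: Receptor) -> Receptor:
    """Complete the structure: rebuild missing backbone carbonyl oxygens
    (and C-terminal OXT), then place all hydrogens geometrically with pH-7
    protonation states (His ε-protonated by default).  Existing hydrogens
    are discarded and rebuilt, so the result is deterministic; heavy-atom
    coordinates are never moved.  Missing backbone N/CA/C or side-chain
    heavy atoms cannot be rebuilt and raise an error naming the residues.
    """
    res_groups = receptor.residues()
    flags = _terminal_flags(receptor)
    broken: list[str] = []
    out_atoms: list[Atom] = []
    retained = list(receptor.retained_waters)

    # positions of each chain's residues for inter-residue geometry
    chain_res: dict[str, list[tuple[tuple[str, int, str], dict[str, np.ndarray]]]] = {}
    heavy_by_res: list[dict[str, np.ndarray]] = []
    for key, idxs in res_groups:
        pos = {receptor.atoms[i].name: receptor.atoms[i].coords
               for i in idxs if receptor.atoms[i].element != "H"}
        heavy_by_res.append(pos)
        if key[2] in pdat.PROTEIN_RESIDUES:
            chain_res.setdefault(key[0], []).append((key, pos))

    next_n: dict[tuple[str, int, str], np.ndarray | None] = {}
    for chain_keys in chain_res.values():
        for j, (key, pos) in enumerate(chain_keys):
            nxt = chain_keys[j + 1][1].get("N") if j + 1 < len(chain_keys) else None
            next_n[key] = nxt

    for (key, idxs), pos in zip(res_groups, heavy_by_res):
        chain, resseq, resname = key
        canon = pdat.canonical_residue(resname)
        if canon in pdat.WATER_RESIDUES or resname in pdat.WATER_RESIDUES:
            out_atoms.extend(_fix_water(key, pos))
            continue
        if canon not in pdat.PROTEIN_RESIDUES:
            # retained hetero residue: pass through untouched
            out_atoms.extend(copy.deepcopy([receptor.atoms[i] for i in idxs]))
            continue

        n_term, c_term = flags[key]
        missing_bb = [n for n in ("N", "CA", "C") if n not in pos]
        if missing_bb:
            broken.append(f"{resname} {chain}{resseq} (missing {missing_bb})")
            continue
        expected_side = {a for b in pdat.SIDECHAIN_BONDS.get(canon, [])
                         for a in b} - {"CA", "N"}
        missing_side = sorted(expected_side - set(pos))
        if missing_side:
            broken.append(f"{resname} {chain}{resseq} (missing {missing_side})")
            continue

        if "O" not in pos:
            pos["O"] = _rebuild_carbonyl_o(pos, next_n[key])
        if c_term and "OXT" not in pos:
            pos["OXT"] = _rebuild_oxt(pos)

        out_atoms.extend(_build_residue(key, pos, n_term, c_term))

    if broken:
        raise ReceptorError(
            "cannot rebuild missing heavy atoms (no loop/side-chain "
            "modelling): " + "; ".join(broken))
    if not out_atoms:
        raise ReceptorError("receptor empty after fixing")
    return Receptor(atoms=out_atoms, retained_waters=retained, fixed_up=True)


def _rebuild_carbonyl_o(pos: dict[str, np.ndarray],
                        next_n: np.ndarray | None) -> np.ndarray:
    c, ca = pos["C"], pos["CA"]
    if next_n is not None:
        u1 = (ca - c) / np.linalg.norm(ca - c)
        u2 = (next_n - c) / np.linalg.norm(next_n - c)
        d = -(u1 + u2)
        return c + 1.229 * d / np.linalg.norm(d)
    return place_atom(pos["N"], ca, c, 1.229, 120.5, -35.0)


def _rebuild_oxt(pos: dict[str, np.ndarray]) -> np.ndarray:
    # carboxylate: OXT opposite O in the CA-C plane
    c, ca, o = pos["C"], pos["CA"], pos["O"]
    u1 = (ca - c) / np.linalg.norm(ca - c)
    u2 = (o - c) / np.linalg.norm(o - c)
    d = -(u1 + u2)
    return c + 1.249 * d / np.linalg.norm(d)


def _fix_water(key: tuple[str, int, str], pos: dict[str, np.ndarray]) -> list[Atom]:
    chain, resseq, resname = key
    o_name = next((n for n in pos if n.startswith("O")), None)
    if o_name is None:
        raise ReceptorError(f"water {chain}{resseq} has no oxygen")
    o = pos[o_name]
    hs = [pos[n] for n in pos if n.startswith("H")]
    if len(hs) < 2:
        hs = hydrogens_water(o)
    atoms = [Atom("O", "O", resname, resseq, chain, o)]
    for i, h in enumerate(hs[:2]):
        atoms.append(Atom(f"H{i + 1}", "H", resname, resseq, chain, np.asarray(h)))
    return atoms


def _build_residue(key: tuple[str, int, str], pos: dict[str, np.ndarray],
                   n_term: bool, c_term: bool) -> list[Atom]:
    """Emit heavy atoms plus geometrically constructed hydrogens."""
    chain, resseq, resname = key
    canon = pdat.canonical_residue(resname)
    bonds = pdat.heavy_bonds(canon)
    neighbours: dict[str, list[str]] = {}
    for a, b in bonds:
        if a in pos and b in pos:
            neighbours.setdefault(a, []).append(b)
            neighbours.setdefault(b, []).append(a)
    if "OXT" in pos:
        neighbours.setdefault("C", []).append("OXT")
        neighbours.setdefault("OXT", []).append("C")

    h_counts = pdat.hydrogen_counts(canon, n_terminal=n_term)
    heavy_order = [n for n in pos]
    atoms: list[Atom] = []
    for name in heavy_order:
        el = _element_from_name(name)
        atoms.append(Atom(name, el, resname, resseq, chain, pos[name]))
        n_h = h_counts.get(name, 0)
        if n_h == 0:
            continue
        x = pos[name]
        nbr_names = neighbours.get(name, [])
        nbrs = [pos[n] for n in nbr_names]
        element = el
        bl = pdat.H_BOND_LENGTH.get(element, 1.09)
        if len(nbrs) == 3 and n_h == 1:
            hpos = hydrogens_tetra_1(x, nbrs, bl)
        elif len(nbrs) == 2 and n_h == 2:
            hpos = hydrogens_tetra_2(x, nbrs, bl)
        elif len(nbrs) == 2 and n_h == 1:
            hpos = hydrogens_planar_1(x, nbrs, bl)
        elif len(nbrs) == 1:
            ref_name = next((n for n in neighbours.get(nbr_names[0], [])
                             if n != name), None)
            ref = pos.get(ref_name) if ref_name else None
            sp3 = (element in ("O", "S")
                   or (canon, name) in pdat.SP3_NITROGENS
                   or (name == "N" and n_term)
                   or element == "C")
            hpos = hydrogens_terminal(x, nbrs[0], ref, n_h, bl, sp3=sp3)
        else:
            raise ReceptorError(
                f"cannot place hydrogens on {resname} {chain}{resseq} {name}")
        for hname, hp in zip(pdat.hydrogen_names(name, n_h, n_term), hpos):
            atoms.append(Atom(hname, "H", resname, resseq, chain, np.asarray(hp)))
    return atoms


def parameterise_receptor(receptor: Receptor,
                          ff_name: str = "builtin-coarse") -> Receptor:
    """Assign partial charges and Lennard-Jones parameters.

    ``builtin-coarse`` is the package's internal fixed-charge model: polar
    groups carry local dipoles, ionisable side chains and termini their pH-7
    integer charge, and a per-residue residual correction (on CA) makes
    every residue's net charge exactly its formal charge.  LJ parameters
    are element-based (r_min/epsilon).
    """
    if ff_name not in ("builtin-coarse",):
        raise ReceptorError(f"unknown force field: {ff_name!r}")
    out = copy.deepcopy(receptor)
    flags = _terminal_flags(out)
    charges = np.zeros(out.n_atoms)
    for key, idxs in out.residues():
        chain, resseq, resname = key
        canon = pdat.canonical_residue(resname)
        names = [out.atoms[i].name for i in idxs]
        if canon in pdat.WATER_RESIDUES or resname in pdat.WATER_RESIDUES:
            table = pdat.WATER_CHARGES
            target = 0
        elif canon in pdat.PROTEIN_RESIDUES:
            n_term, c_term = flags[key]
            table = dict(pdat.BACKBONE_CHARGES)
            table.update(pdat.SIDECHAIN_CHARGES.get(canon, {}))
            if n_term:
                for k in ("N", "H"):
                    table.pop(k, None)
                table.update(pdat.NTERM_CHARGES)
            if c_term:
                table.update(pdat.CTERM_CHARGES)
            target = pdat.residue_formal_charge(canon, n_term, c_term)
        else:
            raise ReceptorError(
                f"no charge template for residue {resname} {chain}{resseq}; "
                "assign parameters explicitly for non-protein residues")
        res_q = [table.get(n, 0.0) for n in names]
        residual = target - sum(res_q)
        sink = names.index("CA") if "CA" in names else 0
        res_q[sink] += residual
        for i, q in zip(idxs, res_q):
            charges[i] = q

    lj = np.array([lj_parameters(a.element) for a in out.atoms])
    out.charges = charges
    out.lj_rmin = lj[:, 0]
    out.lj_eps = lj[:, 1]
    return out


def write_receptor_pdb(receptor: Receptor, path: str | Path) -> None:
    """Write the receptor as a PDB file (audit output)."""
    st = gemmi.Structure()
    st.name = "receptor"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for key, idxs in receptor.residues():
        chain_name, resseq, resname = key
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name or "A")
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resseq, " ")
        if resname not in pdat.PROTEIN_RESIDUES:
            res.het_flag = "H"
        else:
            res.het_flag = "A"
        for i in idxs:
            a = receptor.atoms[i]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = 1.0
            res.add_atom(at)
        chains[chain_name].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
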