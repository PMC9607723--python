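"""Download-free synthetic fixtures: toy pockets, peptides, R-group library.

Everything here is generated programmatically and deterministically, so the
full pipeline can be exercised at desk scale without fetching structures.
Toy receptors are geometric scaffolds, not realistic proteins: atoms get
hand-assigned nonbonded parameters and a concave-shell arrangement around a
cavity that can host a grown ligand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _protein_data as pdat
from ._geometry import place_atom
from .constants import lj_parameters
from .errors import GrowkitError
from .mol_build import RGroup
from .receptor import Atom, Receptor, write_receptor_pdb

__all__ = ["ToyPocket", "make_toy_pocket", "toy_rgroup_library",
           "oracle_pairwise_min_distance", "make_peptide"]


@dataclass
class ToyPocket:
    """Concave shell of parameterised atoms around a cavity centre."""

    receptor: Receptor
    centre: np.ndarray
    cavity_radius: float
    seed: int


def make_toy_pocket(seed: int, cavity_radius: float = 6.0,
                    n_atoms: int = 60,
                    centre: np.ndarray | None = None) -> ToyPocket:
    """Build a pseudo-random shell of C/N/O atoms around a cavity.

    Atoms are placed at radii in [cavity_radius, cavity_radius + 3 Å] on
    quasi-uniform directions; charges alternate ±0.2 e (trailing atoms
    neutral) so the net charge is exactly zero.  The result is emitted as a
    parameterised Receptor whose coordinates are fixed by contract.
    """
    if n_atoms < 10:
        raise GrowkitError("toy pocket needs at least 10 atoms")
    if cavity_radius <= 0:
        raise GrowkitError("cavity_radius must be positive")
    centre = np.zeros(3) if centre is None else np.asarray(centre, dtype=float)
    rng = np.random.default_rng(seed)
    # quasi-uniform directions: Fibonacci sphere with seeded jitter
    i = np.arange(n_atoms)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_atoms
    r_xy = np.sqrt(1.0 - z * z)
    dirs = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    dirs += rng.normal(scale=0.05, size=dirs.shape)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = cavity_radius + rng.uniform(0.0, 3.0, size=n_atoms)
    coords = centre + dirs * radii[:, None]

    elements = np.array(["C", "N", "O"])[i % 3]
    charges = np.zeros(n_atoms)
    n_pairs = (n_atoms // 2) * 2
    charges[:n_pairs:2] = 0.2
    charges[1:n_pairs:2] = -0.2

    atoms = [Atom(name=f"{el}{k + 1}", element=el, resname="TOY",
                  resseq=k + 1, chain="X", coords=coords[k])
             for k, el in enumerate(elements)]
    lj = np.array([lj_parameters(el) for el in elements])
    receptor = Receptor(atoms=atoms, charges=charges,
                        lj_rmin=lj[:, 0], lj_eps=lj[:, 1], fixed_up=True)
    return ToyPocket(receptor=receptor, centre=centre,
                     cavity_radius=cavity_radius, seed=seed)


def assign_toy_parameters(receptor: Receptor, seed: int = 0) -> Receptor:
    """Re-assign the hand-table nonbonded parameters to a reloaded toy
    receptor (used after PDB round-trips, which do not carry charges)."""
    n = receptor.n_atoms
    charges = np.zeros(n)
    n_pairs = (n // 2) * 2
    charges[:n_pairs:2] = 0.2
    charges[1:n_pairs:2] = -0.2
    lj = np.array([lj_parameters(a.element) for a in receptor.atoms])
    receptor.charges = charges
    receptor.lj_rmin = lj[:, 0]
    receptor.lj_eps = lj[:, 1]
    return receptor


def write_toy_pocket_pdb(pocket: ToyPocket, path: str | Path) -> None:
    write_receptor_pdb(pocket.receptor, path)


#: label → fragment SMILES with [*] marking the attachment vector
TOY_RGROUP_SMILES: list[tuple[str, str]] = [
    ("hydrogen", "[*][H]"),
    ("methyl", "[*]C"),
    ("ethyl", "[*]CC"),
    ("propyl", "[*]CCC"),
    ("isopropyl", "[*]C(C)C"),
    ("cyclopropyl", "[*]C1CC1"),
    ("tert-butyl", "[*]C(C)(C)C"),
    ("phenyl", "[*]c1ccccc1"),
    ("benzyl", "[*]Cc1ccccc1"),
    ("hydroxy", "[*]O"),
    ("methoxy", "[*]OC"),
    ("propoxy", "[*]OCCC"),
    ("amino", "[*]N"),
    ("methylamino", "[*]NC"),
    ("dimethylamino", "[*]N(C)C"),
    ("fluoro", "[*]F"),
    ("chloro", "[*]Cl"),
    ("bromo", "[*]Br"),
    ("cyano", "[*]C#N"),
    ("trifluoromethyl", "[*]C(F)(F)F"),
    ("acetyl", "[*]C(C)=O"),
    ("carboxamide", "[*]C(N)=O"),
    ("nitrile-methyl", "[*]CC#N"),
    ("uracil-1-yl", "[*]N1C=CC(=O)NC1=O"),
]


def toy_rgroup_library() -> list[RGroup]:
    """A small stand-in library of common medicinal-chemistry R-groups,
    including a bromo fragment to exercise the ML-element fallback."""
    return [RGroup.from_smiles(smi, label) for label, smi in TOY_RGROUP_SMILES]


def write_rgroup_library(directory: str | Path) -> Path:
    """Write the toy library as SDF-free SMILES TSV index (label\tsmiles)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = directory / "index.tsv"
    with open(index, "w") as fh:
        for label, smi in TOY_RGROUP_SMILES:
            fh.write(f"{label}\t{smi}\n")
    return index


def load_rgroup_library(index_file: str | Path) -> list[RGroup]:
    """Load an R-group library from a TSV index of label\tSMILES rows, or
    label\tfilename rows pointing at SDF fragments in the same directory."""
    index_file = Path(index_file)
    groups: list[RGroup] = []
    for line in index_file.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, spec = line.split("\t")[:2]
        if spec.lower().endswith((".sdf", ".mol")):
            groups.append(RGroup.from_file(index_file.parent / spec, label=label))
        else:
            groups.append(RGroup.from_smiles(spec, label))
    return groups


def oracle_pairwise_min_distance(coords_a: np.ndarray,
                                 coords_b: np.ndarray) -> float:
    """Exact minimum inter-set atom distance by explicit double loop.

    Deliberately naive: this is the reference implementation the fast
    clash filter is checked against.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise GrowkitError("oracle needs non-empty coordinate sets")
    best = np.inf
    for p in a.reshape(-1, 3):
        for q in b.reshape(-1, 3):
            d = float(np.sqrt(np.sum((p - q) ** 2)))
            if d < best:
                best = d
    return best


# --- ideal-geometry peptides -------------------------------------------------

# side-chain heavy atoms as internal coordinates:
# atom, (a, b, c) frame, distance to c, angle b-c-atom, dihedral a-b-c-atom
_SIDECHAIN_ZMAT: dict[str, list[tuple[str, tuple[str, str, str],
                                      float, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", ("C", "N", "CA"), 1.530, 110.5, 122.5)],
    "SER": [("CB", ("C", "N", "CA"), 1.530, 110.5, 122.5),
            ("OG", ("N", "CA", "CB"), 1.417, 110.8, 180.0)],
    "CYS": [("CB", ("C", "N", "CA"), 1.530, 110.5, 122.5),
            ("SG", ("N", "CA", "CB"), 1.810, 114.4, 180.0)],
    "VAL": [("CB", ("C", "N", "CA"), 1.540, 111.5, 122.5),
            ("CG1", ("N", "CA", "CB"), 1.530, 110.5, 60.0),
            ("CG2", ("N", "CA", "CB"), 1.530, 110.5, 180.0)],
    "ASP": [("CB", ("C", "N", "CA"), 1.530, 110.5, 122.5),
            ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
            ("OD1", ("CA", "CB", "CG"), 1.250, 118.5, 0.0),
            ("OD2", ("CA", "CB", "CG"), 1.250, 118.5, 180.0)],
    "LYS": [("CB", ("C", "N", "CA"), 1.530, 110.5, 122.5),
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.489, 112.0, 180.0)],
}

SUPPORTED_PEPTIDE_RESIDUES = frozenset(_SIDECHAIN_ZMAT)


def make_peptide(sequence: list[str], chain: str = "A",
                 with_carbonyl_o: bool = True) -> Receptor:
    """Build an extended-conformation peptide from ideal internal
    coordinates (heavy atoms only; run fix_receptor to add hydrogens).

    Supported residues: GLY, ALA, SER, CYS, VAL, ASP, LYS.
    """
    unknown = [r for r in sequence if r.upper() not in SUPPORTED_PEPTIDE_RESIDUES]
    if unknown:
        raise GrowkitError(f"unsupported fixture residues: {unknown}")
    atoms: list[Atom] = []
    prev: dict[str, np.ndarray] | None = None
    for i, resname in enumerate([r.upper() for r in sequence]):
        pos: dict[str, np.ndarray] = {}
        if prev is None:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([1.458, 0.0, 0.0])
            ang = np.deg2rad(111.1)
            pos["C"] = pos["CA"] + 1.525 * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            pos["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  1.329, 116.6, 180.0)
            pos["CA"] = place_atom(prev["CA"], prev["C"], pos["N"],
                                   1.458, 121.7, 180.0)
            pos["C"] = place_atom(prev["C"], pos["N"], pos["CA"],
                                  1.525, 111.1, 180.0)
        for name, (a, b, c), dist, angle, dih in _SIDECHAIN_ZMAT[resname]:
            pos[name] = place_atom(pos[a], pos[b], pos[c], dist, angle, dih)
        if with_carbonyl_o:
            # approximate: O placed anti to CA in the peptide plane
            pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"],
                                  1.229, 120.5, 135.0)
        for name, xyz in pos.items():
            atoms.append(Atom(name=name, element=name[0], resname=resname,
                              resseq=i + 1, chain=chain, coords=xyz))
        prev = pos
    return Receptor(atoms=atoms)
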