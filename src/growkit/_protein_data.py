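"""Residue topology and coarse nonbonded parameter tables.

The tables cover the 20 standard amino acids plus the common protonation
variants (HID/HIE/HIP, ASH, GLH, CYX, LYN) and water.  Hydrogen counts and
side-chain connectivity drive geometric hydrogen construction; the charge
table is a deliberately coarse fixed-charge model — polar groups carry
local dipoles, ionisable groups carry their pH-7 integer charge — with a
per-residue residual correction (applied on CA) so every residue's net
charge is exactly its formal charge.
"""

from __future__ import annotations

# --- residue classification -------------------------------------------------

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
VARIANT_RESIDUES = {"HID", "HIE", "HIP", "ASH", "GLH", "CYX", "LYN"}
PROTEIN_RESIDUES = STANDARD_RESIDUES | VARIANT_RESIDUES
WATER_RESIDUES = {"HOH", "WAT", "H2O", "TIP3", "SOL"}

#: default protonation variant used for topology/charges at pH 7
VARIANT_OF = {"HIS": "HIE"}

#: residue formal charge at pH 7 (side chain only; termini handled separately)
FORMAL_CHARGE = {
    "ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1, "HIP": 1,
}

# --- topology ---------------------------------------------------------------

BACKBONE_ATOMS = ("N", "CA", "C", "O")
BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O")]

#: side-chain heavy-atom bonds (CA anchors each side chain)
SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIE": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}
SIDECHAIN_BONDS["HID"] = SIDECHAIN_BONDS["HIE"]
SIDECHAIN_BONDS["HIP"] = SIDECHAIN_BONDS["HIE"]
SIDECHAIN_BONDS["ASH"] = SIDECHAIN_BONDS["ASP"]
SIDECHAIN_BONDS["GLH"] = SIDECHAIN_BONDS["GLU"]
SIDECHAIN_BONDS["CYX"] = SIDECHAIN_BONDS["CYS"]
SIDECHAIN_BONDS["LYN"] = SIDECHAIN_BONDS["LYS"]

#: hydrogens per side-chain heavy atom (backbone handled separately)
SIDECHAIN_H: dict[str, dict[str, int]] = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "ND2": 2},
    "ASP": {"CB": 2},
    "ASH": {"CB": 2, "OD2": 1},
    "CYS": {"CB": 2, "SG": 1},
    "CYX": {"CB": 2},
    "GLN": {"CB": 2, "CG": 2, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2},
    "GLH": {"CB": 2, "CG": 2, "OE2": 1},
    "GLY": {},
    "HIE": {"CB": 2, "CD2": 1, "CE1": 1, "NE2": 1},
    "HID": {"CB": 2, "CD2": 1, "CE1": 1, "ND1": 1},
    "HIP": {"CB": 2, "CD2": 1, "CE1": 1, "ND1": 1, "NE2": 1},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "LYN": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 2},
    "MET": {"CB": 2, "CG": 2, "CE": 3},
    "PHE": {"CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CD1": 1, "NE1": 1, "CE3": 1, "CZ3": 1, "CH2": 1,
            "CZ2": 1},
    "TYR": {"CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}

#: nitrogen atoms with tetrahedral (sp3) hydrogen geometry; every other
#: N/C with hydrogens defaults to the count-derived geometry, O/S-H are
#: always built sp3 with an anti dihedral
SP3_NITROGENS = {("LYS", "NZ"), ("LYN", "NZ")}

#: X–H bond lengths by heavy element (Å)
H_BOND_LENGTH = {"C": 1.090, "N": 1.010, "O": 0.960, "S": 1.340}

# --- coarse charges ---------------------------------------------------------

BACKBONE_CHARGES = {"N": -0.40, "H": 0.25, "CA": 0.10, "HA": 0.05,
                    "C": 0.55, "O": -0.55}

SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "SER": {"CB": 0.20, "OG": -0.65, "HG": 0.45},
    "THR": {"CB": 0.20, "OG1": -0.65, "HG1": 0.45},
    "TYR": {"CZ": 0.15, "OH": -0.55, "HH": 0.40},
    "CYS": {"CB": 0.10, "SG": -0.30, "HG": 0.20},
    "CYX": {"CB": 0.10, "SG": -0.10},
    "MET": {"CG": 0.10, "SD": -0.20, "CE": 0.10},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": -0.80,
            "HD21": 0.40, "HD22": 0.40},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": -0.80,
            "HE21": 0.40, "HE22": 0.40},
    "ASP": {"CG": 0.60, "OD1": -0.80, "OD2": -0.80},
    "ASH": {"CG": 0.55, "OD1": -0.50, "OD2": -0.50, "HD2": 0.45},
    "GLU": {"CD": 0.60, "OE1": -0.80, "OE2": -0.80},
    "GLH": {"CD": 0.55, "OE1": -0.50, "OE2": -0.50, "HE2": 0.45},
    "LYS": {"NZ": -0.20, "HZ1": 0.40, "HZ2": 0.40, "HZ3": 0.40},
    "LYN": {"NZ": -0.80, "HZ1": 0.40, "HZ2": 0.40},
    "ARG": {"NE": -0.55, "HE": 0.35, "CZ": 0.80, "NH1": -0.80, "NH2": -0.80,
            "HH11": 0.50, "HH12": 0.50, "HH21": 0.50, "HH22": 0.50},
    "HIE": {"CG": 0.15, "ND1": -0.55, "CE1": 0.25, "NE2": -0.35,
            "HE2": 0.35, "CD2": 0.15},
    "HID": {"CG": 0.15, "ND1": -0.35, "HD1": 0.35, "CE1": 0.25,
            "NE2": -0.55, "CD2": 0.15},
    "HIP": {"CG": 0.15, "ND1": -0.30, "HD1": 0.45, "CE1": 0.40,
            "NE2": -0.30, "HE2": 0.45, "CD2": 0.15},
    "TRP": {"NE1": -0.35, "HE1": 0.35},
}

#: water (TIP3P-like point charges)
WATER_CHARGES = {"O": -0.834, "H1": 0.417, "H2": 0.417}

#: N-terminal ammonium group (replaces backbone N/H entries; net +1 vs 0)
NTERM_CHARGES = {"N": -0.20, "H1": 0.40, "H2": 0.40, "H3": 0.40}
#: C-terminal carboxylate group (replaces backbone C/O entries; net -1)
CTERM_CHARGES = {"C": 0.60, "O": -0.80, "OXT": -0.80}


def canonical_residue(resname: str) -> str:
    """Map a residue name to the topology/charge table key."""
    name = resname.strip().upper()
    return VARIANT_OF.get(name, name)


def heavy_bonds(resname: str, is_pro_like: bool = False) -> list[tuple[str, str]]:
    """Backbone plus side-chain heavy-atom bonds for one residue."""
    key = canonical_residue(resname)
    return list(BACKBONE_BONDS) + SIDECHAIN_BONDS.get(key, [])


def hydrogen_counts(resname: str, n_terminal: bool = False) -> dict[str, int]:
    """Hydrogens carried by each heavy atom of the residue."""
    key = canonical_residue(resname)
    counts = dict(SIDECHAIN_H.get(key, {}))
    if key == "GLY":
        counts["CA"] = 2
    else:
        counts["CA"] = 1
    if key == "PRO":
        counts["N"] = 2 if n_terminal else 0
    else:
        counts["N"] = 3 if n_terminal else 1
    return counts


def hydrogen_names(heavy_name: str, n_h: int, n_terminal: bool = False) -> list[str]:
    """PDB-style hydrogen names for n_h hydrogens on a heavy atom."""
    if heavy_name == "N":
        if n_terminal:
            return [f"H{i + 1}" for i in range(n_h)]
        return ["H"] if n_h == 1 else [f"H{i + 1}" for i in range(n_h)]
    suffix = heavy_name[1:]
    if n_h == 1:
        return [f"H{suffix}"]
    if heavy_name == "CA":
        return ["HA2", "HA3"][:n_h]
    if n_h == 2:
        return [f"H{suffix}2", f"H{suffix}3"]
    return [f"H{suffix}{i + 1}" for i in range(n_h)]


def residue_formal_charge(resname: str, n_terminal: bool = False,
                          c_terminal: bool = False) -> int:
    key = canonical_residue(resname)
    q = FORMAL_CHARGE.get(key, 0)
    if n_terminal:
        q += 1
    if c_terminal:
        q -= 1
    return q
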