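"""Drug-likeness and liability reporting for grown ligands.

Covers Lipinski's rule of five (original N/O counting for acceptors and
N-H/O-H counting for donors), an Ertl-style synthetic accessibility score,
and substructure liability flags (PAINS, NIH, Brenk unwanted motifs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, FilterCatalog, Lipinski
from rdkit.Chem import rdMolDescriptors

from .errors import GrowkitError

__all__ = ["PropertyReport", "ro5_report", "sa_score", "substructure_flags",
           "property_report"]


@dataclass
class PropertyReport:
    """Per-ligand drug-likeness metrics and liability flags."""

    mw: float = 0.0
    clogp: float = 0.0
    hbd: int = 0
    hba: int = 0
    ro5_violations: int = 0
    ro5_compliant: bool = True
    sa_score: float | None = None
    pains: bool = False
    nih: bool = False
    unwanted: bool = False
    matched_patterns: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "mw": self.mw, "clogp": self.clogp, "hbd": self.hbd,
            "hba": self.hba, "ro5_violations": self.ro5_violations,
            "ro5_compliant": self.ro5_compliant, "sa_score": self.sa_score,
            "pains": self.pains, "nih": self.nih, "unwanted": self.unwanted,
            "matched_patterns": ";".join(self.matched_patterns),
        }


def _check_mol(mol: Chem.Mol) -> Chem.Mol:
    if mol is None or mol.GetNumAtoms() == 0:
        raise GrowkitError("uninterpretable or empty molecule")
    return mol


def ro5_report(mol: Chem.Mol) -> PropertyReport:
    """Lipinski rule-of-five descriptors and violation count.

    MW is the average molecular weight; logP is the Crippen
    atom-contribution estimate; donors count N-H and O-H, acceptors count
    N and O atoms (Lipinski's original definitions).  A molecule is
    compliant with at most one violation.
    """
    _check_mol(mol)
    mw = float(Descriptors.MolWt(mol))
    clogp = float(Crippen.MolLogP(mol))
    hbd = int(Lipinski.NHOHCount(mol))
    hba = int(Lipinski.NOCount(mol))
    violations = sum([mw > 500.0, clogp > 5.0, hbd > 5, hba > 10])
    return PropertyReport(mw=mw, clogp=clogp, hbd=hbd, hba=hba,
                          ro5_violations=violations,
                          ro5_compliant=violations <= 1)


# --- synthetic accessibility -------------------------------------------------

_SA_TABLE_RESOURCE = "sa_fragment_scores_synthetic.tsv"


@lru_cache(maxsize=4)
def _load_fragment_scores(path: str | None = None) -> dict[int, float]:
    if path is None:
        text = (resources.files("growkit") / "data"
                / _SA_TABLE_RESOURCE).read_text()
    else:
        text = Path(path).read_text()
    scores: dict[int, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        bit, score = line.split("\t")
        scores[int(bit)] = float(score)
    if not scores:
        raise GrowkitError("empty synthetic-accessibility fragment table")
    return scores


def fragment_contributions(mol: Chem.Mol, radius: int = 2) -> dict[int, int]:
    """Per-molecule circular-fragment (Morgan, chirality-insensitive)
    identifier counts, the raw material of the fragment score."""
    from rdkit.Chem import rdFingerprintGenerator
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, includeChirality=False)
    fp = gen.GetSparseCountFingerprint(mol)
    return dict(fp.GetNonzeroElements())


def sa_score(mol: Chem.Mol, table_path: str | None = None) -> float:
    """Ertl-style synthetic accessibility score in [1, 10] (1 = easy).

    A fragment-contribution term (log-frequency of Morgan radius-2
    fragments from a bundled frequency table — a synthetic snapshot built
    from the package's reference molecule set, swappable via
    ``table_path``) is combined with complexity penalties for size,
    stereocentres, spiro and bridgehead atoms, and macrocycles, then
    affine-mapped onto [1, 10].
    """
    _check_mol(mol)
    if mol.GetNumHeavyAtoms() == 0:
        raise GrowkitError("synthetic accessibility undefined without heavy atoms")
    mol = Chem.RemoveHs(mol)  # fragment table uses implicit-hydrogen graphs
    scores = _load_fragment_scores(table_path)
    frags = fragment_contributions(mol)
    n_frag_instances = sum(frags.values())
    score1 = sum(scores.get(bit, -4.0) * count for bit, count in frags.items())
    score1 /= max(n_frag_instances, 1)

    n_atoms = mol.GetNumHeavyAtoms()
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=False))
    ri = mol.GetRingInfo()
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    macrocycle = any(len(r) > 8 for r in ri.AtomRings())

    size_penalty = n_atoms ** 1.005 - n_atoms
    stereo_penalty = math.log10(n_chiral + 1)
    spiro_penalty = math.log10(n_spiro + 1)
    bridge_penalty = math.log10(n_bridge + 1)
    macro_penalty = math.log10(2) if macrocycle else 0.0
    score2 = -(size_penalty + stereo_penalty + spiro_penalty
               + bridge_penalty + macro_penalty)

    # symmetry bonus: few unique fragments for many atoms = easy
    n_unique = len(frags)
    score3 = 0.0
    if n_atoms > n_unique:
        score3 = math.log(float(n_atoms) / n_unique) * 0.5

    raw = score1 + score2 + score3
    raw_min, raw_max = -4.0, 2.5
    sa = 11.0 - (raw - raw_min) / (raw_max - raw_min) * 9.0
    if sa > 8.0:
        sa = 8.0 + math.log(sa - 8.0 + 1.0)
    return float(min(10.0, max(1.0, sa)))


# --- substructure liability flags -------------------------------------------

_CatalogEnum = FilterCatalog.FilterCatalogParams.FilterCatalogs


@lru_cache(maxsize=1)
def _builtin_catalogs() -> dict[str, FilterCatalog.FilterCatalog]:
    def make(*cats):
        params = FilterCatalog.FilterCatalogParams()
        for c in cats:
            params.AddCatalog(c)
        return FilterCatalog.FilterCatalog(params)

    return {
        "pains": make(_CatalogEnum.PAINS_A, _CatalogEnum.PAINS_B,
                      _CatalogEnum.PAINS_C),
        "nih": make(_CatalogEnum.NIH),
        "unwanted": make(_CatalogEnum.BRENK),
    }


def load_smarts_catalog(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Load a user catalog from a ``SMARTS<TAB>label`` text file."""
    entries: list[tuple[str, Chem.Mol]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smarts = parts[0]
        label = parts[1] if len(parts) > 1 else f"pattern_{ln}"
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise GrowkitError(f"{path}:{ln}: invalid SMARTS {smarts!r}")
        entries.append((label, patt))
    if not entries:
        raise GrowkitError(f"catalog file {path} contains no patterns")
    return entries


def substructure_flags(mol: Chem.Mol,
                       extra_catalogs: dict[str, str | Path] | None = None
                       ) -> tuple[dict[str, bool], list[str]]:
    """Match the molecule against the PAINS (A+B+C), NIH and Brenk
    unwanted-substructure catalogs; returns per-catalog booleans and the
    labels of every matched pattern.  ``extra_catalogs`` maps additional
    flag names to SMARTS catalog files."""
    _check_mol(mol)
    flags: dict[str, bool] = {}
    matched: list[str] = []
    for name, catalog in _builtin_catalogs().items():
        entries = catalog.GetMatches(mol)
        flags[name] = len(entries) > 0
        matched.extend(f"{name}:{e.GetDescription()}" for e in entries)
    for name, path in (extra_catalogs or {}).items():
        hits = [label for label, patt in load_smarts_catalog(path)
                if mol.HasSubstructMatch(patt)]
        flags[name] = bool(hits)
        matched.extend(f"{name}:{h}" for h in hits)
    return flags, matched


def property_report(mol: Chem.Mol, with_sa: bool = True) -> PropertyReport:
    """Full per-ligand report: Ro5, synthetic accessibility, liability flags."""
    report = ro5_report(mol)
    if with_sa:
        report.sa_score = sa_score(mol)
    flags, matched = substructure_flags(mol)
    report.pains = flags["pains"]
    report.nih = flags["nih"]
    report.unwanted = flags["unwanted"]
    report.matched_patterns = matched
    return report
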