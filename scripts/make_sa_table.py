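"""Regenerate the synthetic-accessibility fragment frequency table.

Builds a synthetic reference set of drug-like molecules by combinatorial
decoration of common medicinal-chemistry scaffolds, counts Morgan radius-2
fragment identifiers over the set, and converts counts to log-frequency
contributions (most common fragment -> +3, unseen -> -4).  The resulting
table ships with the package as
src/growkit/data/sa_fragment_scores_synthetic.tsv and is deliberately a
small synthetic snapshot, not a PubChem-derived table; swap in a larger
table via sa_score(table_path=...) for production scoring.

Run from the repository root:  python scripts/make_sa_table.py
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path

from rdkit import Chem

SCAFFOLDS = [
    "c1ccccc1[*]", "c1ccncc1[*]", "c1ccc2ccccc2c1[*]", "c1ccc2[nH]ccc2c1[*]",
    "c1cnc2ccccc2c1[*]", "c1csc(n1)[*]", "c1cnn(c1)[*]", "c1ccoc1[*]",
    "C1CCNCC1[*]", "C1CCCCC1[*]", "C1CCOCC1[*]", "C1CCNC1[*]",
    "c1ccc(cc1)C(=O)N[*]", "c1ccc(cc1)S(=O)(=O)N[*]", "c1ccc(cc1)C(=O)O[*]",
    "c1ccc(cc1)NC(=O)[*]", "c1ccc(cc1)O[*]", "c1ccc(cc1)N[*]",
    "O=C1NC(=O)C=CN1[*]", "c1nc2ccccc2n1[*]", "c1ccc(cc1)c1ccccc1[*]",
    "C(=O)(N1CCOCC1)[*]", "c1cc(F)ccc1[*]", "c1cc(Cl)ccc1[*]",
    "c1cc(OC)ccc1[*]", "N1CCN(CC1)[*]",
]

SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "C1CC1", "Cc1ccccc1",
    "c1ccccc1", "O", "OC", "OCC", "OCCC", "N", "NC", "N(C)C", "F", "Cl",
    "Br", "C#N", "C(F)(F)F", "C(=O)C", "C(=O)N", "C(=O)O", "C(=O)OC",
    "S(=O)(=O)C", "SC", "CO", "CCO", "CN", "CCN", "[H]", "C=C",
    "CC#N", "COC", "CC(=O)N", "NCC",
]

EXTRA = [
    # small common molecules and linker chemistries
    "CC(=O)Oc1ccccc1C(=O)O", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "CC(=O)Nc1ccc(O)cc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "c1ccc(cc1)C(=O)Nc1ccccc1", "OCC(O)CO", "NCCO", "CC(N)C(=O)O",
    "C1CCC(CC1)N", "c1ccc(cc1)CN1CCCC1", "OC(=O)CCC(=O)O",
    "c1ccc(cc1)/C=C/C(=O)O", "CCOC(=O)c1ccccc1", "CN1CCC(CC1)O",
    "CCN(CC)CC", "CSCC", "CC(=O)C",
    "c1ccc(cc1)C#N", "Nc1ncnc2c1nc[nH]2", "OC1CCCCC1",
]


def reference_molecules() -> list[Chem.Mol]:
    smiles = set(EXTRA)
    for scaf in SCAFFOLDS:
        for sub in SUBSTITUENTS:
            smiles.add(scaf.replace("[*]", sub))
    mols = []
    for smi in sorted(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            mols.append(mol)
    return mols


def main() -> None:
    import sys
    sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
    from growkit.props import fragment_contributions

    mols = reference_molecules()
    print(f"reference set: {len(mols)} molecules")
    counts: Counter[int] = Counter()
    for mol in mols:
        counts.update(fragment_contributions(mol))
    max_count = max(counts.values())
    out = Path(__file__).resolve().parents[1] / "src" / "growkit" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "sa_fragment_scores_synthetic.tsv"
    kept = 0
    with open(path, "w") as fh:
        fh.write("# synthetic Morgan radius-2 fragment log-frequency scores\n")
        fh.write("# built by scripts/make_sa_table.py from a generated "
                 "drug-like reference set\n")
        for bit, count in sorted(counts.items()):
            if count < 2:
                continue
            score = max(-4.0, math.log10(count) - math.log10(max_count) + 3.0)
            fh.write(f"{bit}\t{score:.4f}\n")
            kept += 1
    print(f"wrote {kept} fragment scores to {path} "
          f"({path.stat().st_size / 1024:.1f} KB)")


if __name__ == "__main__":
    main()
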