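"""Physical constants and element-level nonbonded parameters.

Units throughout the package: Å, kcal/mol, elementary charge (e), degrees.
"""

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0637

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Default temperature for pK → ΔG conversion (K).
DEFAULT_TEMPERATURE = 298.15

#: Elements covered by ANI-style neural network potentials; ligands
#: containing anything else fall back to a classical force field.
ML_SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "S", "Cl"})

# Element-level Lennard-Jones parameters used for the receptor-ligand
# coupling term: r_min is the homoatomic minimum-energy distance (Å),
# epsilon the well depth (kcal/mol).  Values follow the UFF vdW set
# (x_i = minimum distance, D_i = well depth), which is defined for the
# whole periodic table and keeps r_min semantics explicit — convenient
# because the pocket model scales minimum-energy distances directly.
LJ_BY_ELEMENT: dict[str, tuple[float, float]] = {
    "H": (2.886, 0.044),
    "C": (3.851, 0.105),
    "N": (3.660, 0.069),
    "O": (3.500, 0.060),
    "F": (3.364, 0.050),
    "P": (4.147, 0.305),
    "S": (4.035, 0.274),
    "Cl": (3.947, 0.227),
    "Br": (4.189, 0.251),
    "I": (4.500, 0.339),
}

#: Fallback for elements missing from the table (carbon-like).
LJ_DEFAULT = (3.851, 0.105)


def lj_parameters(element: str) -> tuple[float, float]:
    """Return (r_min, epsilon) for an element symbol, carbon-like fallback."""
    return LJ_BY_ELEMENT.get(element.capitalize(), LJ_DEFAULT)
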