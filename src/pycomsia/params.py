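"""Atomic parameter tables for similarity-field weighting.

The field engine weights every atom by a physicochemical property:
van der Waals radius cubed for the steric field, partial charge for the
electrostatic field, an atomic hydrophobicity increment for the
hydrophobic field, and binary donor/acceptor flags for the two
hydrogen-bond fields.  The tables below are the shipped defaults; they
are plain dictionaries so an alternative parameterization can be passed
anywhere a ``scheme`` argument is accepted.
"""

from __future__ import annotations

# Bondi van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "B": 1.92,
    "Si": 2.10,
    # pseudo-atom used by the synthetic generator; radius set per atom
    "X": 1.70,
}

# Covalent radii, Å (Cordero et al. consensus values), used only to infer
# connectivity when a structure file carries no bond block.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
    "B": 0.84,
    "Si": 1.11,
    "X": 0.76,
}

# Element-level atomic hydrophobicity increments (dimensionless).  Carbon
# and sulfur contribute positively, polar heteroatoms negatively, apolar
# hydrogens weakly positively — a deliberately coarse, documented scheme
# in the spirit of atom-additive logP contributions.
HYDROPHOBICITY: dict[str, float] = {
    "H": 0.20,
    "C": 0.50,
    "N": -0.40,
    "O": -0.40,
    "F": 0.15,
    "P": -0.20,
    "S": 0.30,
    "Cl": 0.35,
    "Br": 0.40,
    "I": 0.45,
    "B": 0.10,
    "Si": 0.30,
    "X": 0.00,
}

#: Default parameter scheme name.
DEFAULT_SCHEME = "default"

SCHEMES: dict[str, dict[str, dict[str, float]]] = {
    DEFAULT_SCHEME: {
        "vdw": VDW_RADII,
        "hydrophobicity": HYDROPHOBICITY,
    }
}


class UnknownElementError(KeyError):
    """Raised when a parameter table has no entry for an element."""


def lookup(scheme: str, table: str, element: str, compound_id: str = "?") -> float:
    tables = SCHEMES.get(scheme)
    if tables is None:
        raise KeyError(f"unknown parameter scheme {scheme!r}")
    try:
        return tables[table][element]
    except KeyError:
        raise UnknownElementError(
            f"element {element!r} (compound {compound_id}) not in "
            f"{table} table of scheme {scheme!r}"
        ) from None
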