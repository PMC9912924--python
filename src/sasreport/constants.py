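"""Physical constants and residue reference tables.

All scattering-length-density work in this package runs off the tables in
this module: element masses / electron counts / bound coherent neutron
scattering lengths, per-residue chemical formulas for protein and nucleic
acid chains, per-residue crystallographic packing volumes, and exchangeable
hydrogen censuses.  Conventions follow the contrast calculators in common
use for biomolecular SANS (MULCh-style): neutral protonation states,
phosphodiester P-OH hydrogens counted as exchangeable, 5'-OH oligonucleotide
termini.
"""

from __future__ import annotations

# --- fundamental constants -------------------------------------------------

AVOGADRO = 6.02214076e23          # mol^-1
R_ELECTRON_CM = 2.8179403262e-13  # classical electron radius, cm
FM_TO_CM = 1.0e-13
A3_TO_CM3 = 1.0e-24
M_D_MINUS_M_H = 1.006277          # Da, mass added per H -> D substitution

# --- elements --------------------------------------------------------------
# mass (Da), electrons, bound coherent neutron scattering length (fm)
ELEMENTS: dict[str, tuple[float, int, float]] = {
    "H":  (1.00794,   1, -3.7390),
    "D":  (2.014102,  1,  6.671),
    "C":  (12.0107,   6,  6.6460),
    "N":  (14.0067,   7,  9.36),
    "O":  (15.9994,   8,  5.803),
    "P":  (30.97376, 15,  5.13),
    "S":  (32.065,   16,  2.847),
    "Se": (78.96,    34,  7.970),
    "Zn": (65.38,    30,  5.680),
    "Fe": (55.845,   26,  9.45),
    "Mg": (24.305,   12,  5.375),
    "Ca": (40.078,   20,  4.70),
    "Mn": (54.938,   25, -3.73),
    "Cu": (63.546,   29,  7.718),
    "Na": (22.98977, 11,  3.63),
    "K":  (39.0983,  19,  3.67),
    "Cl": (35.453,   17,  9.577),
}

# volumes (A^3) assigned to bound ions / extra atoms; crystal ionic volumes
ION_VOLUMES: dict[str, float] = {
    "Zn": 11.0, "Fe": 9.0, "Mg": 6.0, "Ca": 12.0, "Mn": 10.0, "Cu": 9.5,
    "Na": 4.5, "K": 11.0, "Cl": 25.0, "S": 26.0, "Se": 28.0,
}

# --- water -----------------------------------------------------------------
# per-molecule volumes from molar volume at 20 C
V_H2O_A3 = 29.97
V_D2O_A3 = 30.11

# --- protein residues ------------------------------------------------------
# In-chain residue (amino acid minus H2O): formula {element: count},
# exchangeable H (backbone amide + labile side-chain H, neutral form),
# packing volume (A^3; Perkins 1986 consensus crystal volumes).
AMINO_ACIDS: dict[str, tuple[dict[str, int], int, float]] = {
    "G": ({"C": 2,  "H": 3,  "N": 1, "O": 1},          1, 66.4),
    "A": ({"C": 3,  "H": 5,  "N": 1, "O": 1},          1, 91.5),
    "V": ({"C": 5,  "H": 9,  "N": 1, "O": 1},          1, 141.7),
    "L": ({"C": 6,  "H": 11, "N": 1, "O": 1},          1, 167.9),
    "I": ({"C": 6,  "H": 11, "N": 1, "O": 1},          1, 168.8),
    "P": ({"C": 5,  "H": 7,  "N": 1, "O": 1},          0, 129.3),
    "F": ({"C": 9,  "H": 9,  "N": 1, "O": 1},          1, 203.4),
    "W": ({"C": 11, "H": 10, "N": 2, "O": 1},          2, 237.6),
    "M": ({"C": 5,  "H": 9,  "N": 1, "O": 1, "S": 1},  1, 170.8),
    "S": ({"C": 3,  "H": 5,  "N": 1, "O": 2},          2, 99.1),
    "T": ({"C": 4,  "H": 7,  "N": 1, "O": 2},          2, 122.1),
    "C": ({"C": 3,  "H": 5,  "N": 1, "O": 1, "S": 1},  2, 105.6),
    "Y": ({"C": 9,  "H": 9,  "N": 1, "O": 2},          2, 203.6),
    "N": ({"C": 4,  "H": 6,  "N": 2, "O": 2},          3, 135.2),
    "Q": ({"C": 5,  "H": 8,  "N": 2, "O": 2},          3, 161.1),
    "D": ({"C": 4,  "H": 5,  "N": 1, "O": 3},          2, 113.6),
    "E": ({"C": 5,  "H": 7,  "N": 1, "O": 3},          2, 140.6),
    "K": ({"C": 6,  "H": 12, "N": 2, "O": 1},          3, 176.2),
    "R": ({"C": 6,  "H": 12, "N": 4, "O": 1},          5, 202.1),
    "H": ({"C": 6,  "H": 7,  "N": 3, "O": 1},          2, 167.3),
}

# --- nucleic acid residues -------------------------------------------------
# In-chain residue = nucleoside - H2O + HPO3 (neutral phosphodiester with
# one P-OH).  Exchangeable H = base amino/imino H + 1 P-OH.
# Volumes: package reference set consistent with B-DNA crystallographic
# packing volumes (see docs/methods.md).
DNA_NUCLEOTIDES: dict[str, tuple[dict[str, int], int, float]] = {
    "A": ({"C": 10, "H": 12, "N": 5, "O": 5, "P": 1},  3, 307.0),
    "G": ({"C": 10, "H": 12, "N": 5, "O": 6, "P": 1},  4, 316.0),
    "C": ({"C": 9,  "H": 12, "N": 3, "O": 6, "P": 1},  3, 284.0),
    "T": ({"C": 10, "H": 13, "N": 2, "O": 7, "P": 1},  2, 302.0),
}

RNA_NUCLEOTIDES: dict[str, tuple[dict[str, int], int, float]] = {
    "A": ({"C": 10, "H": 12, "N": 5, "O": 6, "P": 1},  4, 315.0),
    "G": ({"C": 10, "H": 12, "N": 5, "O": 7, "P": 1},  5, 324.0),
    "C": ({"C": 9,  "H": 12, "N": 3, "O": 7, "P": 1},  4, 292.0),
    "U": ({"C": 9,  "H": 11, "N": 2, "O": 8, "P": 1},  3, 292.0),
}

# --- named chemical modifications -----------------------------------------
# name -> (formula delta, exchangeable-H delta, volume delta A^3)
MODIFICATIONS: dict[str, tuple[dict[str, int], int, float]] = {
    # 5-methylcytosine: cytosine + CH2
    "5mC": ({"C": 1, "H": 2}, 0, 22.0),
    # generic methylation
    "methyl": ({"C": 1, "H": 2}, 0, 22.0),
    # phosphorylation (adds HPO3)
    "phospho": ({"H": 1, "P": 1, "O": 3}, 1, 54.0),
}

WATER_FORMULA = {"H": 2, "O": 1}
HPO3_FORMULA = {"H": 1, "P": 1, "O": 3}


def formula_mass(formula: dict[str, int | float]) -> float:
    """Mass in Da of a chemical formula given as {element: count}."""
    return sum(ELEMENTS[el][0] * n for el, n in formula.items())


def formula_electrons(formula: dict[str, int | float]) -> float:
    return sum(ELEMENTS[el][1] * n for el, n in formula.items())


def formula_bcoh_fm(formula: dict[str, int | float]) -> float:
    """Total bound coherent neutron scattering length in fm."""
    return sum(ELEMENTS[el][2] * n for el, n in formula.items())


def add_formula(a: dict[str, float], b: dict[str, int | float],
                scale: float = 1.0) -> None:
    """In-place a += scale * b for element-count dicts."""
    for el, n in b.items():
        a[el] = a.get(el, 0.0) + scale * n
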