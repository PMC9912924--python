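"""Molecular composition engine: mass, partial specific volume, scattering
lengths, scattering-length densities, contrasts and solvent match points.

Everything is computed from sequence-level descriptions of the particle's
components.  The neutron scattering length of a component is affine in the
solvent D2O fraction because H/D exchange of labile hydrogens is modelled
linearly:

    b_exch(f) = b_H + x * f * (b_D - b_H)

with x the exchange fraction (default 1: all labile H equilibrate) and f the
D2O volume fraction of the solvent.  Non-exchangeable hydrogens can be
perdeuterated to a stated fraction, which is solvent independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .constants import (
    AMINO_ACIDS,
    AVOGADRO,
    DNA_NUCLEOTIDES,
    ELEMENTS,
    HPO3_FORMULA,
    ION_VOLUMES,
    MODIFICATIONS,
    M_D_MINUS_M_H,
    RNA_NUCLEOTIDES,
    R_ELECTRON_CM,
    V_D2O_A3,
    V_H2O_A3,
    WATER_FORMULA,
    add_formula,
    formula_bcoh_fm,
    formula_electrons,
    formula_mass,
)

_B_H = ELEMENTS["H"][2]
_B_D = ELEMENTS["D"][2]

_RESIDUE_TABLES = {
    "protein": AMINO_ACIDS,
    "dna": DNA_NUCLEOTIDES,
    "rna": RNA_NUCLEOTIDES,
}

# accession patterns used for identifier sanity warnings (never hard errors)
ACCESSION_PATTERNS = {
    "uniprot": re.compile(
        r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
    ),
    "genbank": re.compile(r"^[A-Z]{1,2}_?[0-9]{5,8}(?:\.[0-9]+)?$"),
    "glytoucan": re.compile(r"^G[0-9]{5}[A-Z]{2}$"),
    "ncbi_taxid": re.compile(r"^(?:NCBI:)?txid[0-9]+$"),
}


class CompositionError(ValueError):
    """Raised for invalid sequences or missing residue table entries."""


@dataclass
class Component:
    """One biomolecule chain (or set of identical chains).

    Parameters
    ----------
    name : str
        Free-text label.
    kind : {'protein', 'dna', 'rna'}
    sequence : str
        One-letter residue codes (a single chain).
    copies : int
        Number of identical chains in the particle.
    nonexchangeable_deuteration : float
        Fraction of non-exchangeable (carbon-bound) hydrogens replaced by
        deuterium, in [0, 1].
    modifications : list of (name_or_formula, count)
        Chemical deltas applied per chain, e.g. ``[("5mC", 2)]`` for two
        5-methylcytosines.  A dict of element counts may be given in place
        of a registered modification name.
    extra_atoms : dict
        Additional bound atoms per chain, e.g. ``{"Zn": 5}``.
    identifiers : dict
        Accession strings, e.g. ``{"uniprot": "P16497"}``.
    """

    name: str
    kind: str
    sequence: str
    copies: int = 1
    nonexchangeable_deuteration: float = 0.0
    modifications: list = field(default_factory=list)
    extra_atoms: dict = field(default_factory=dict)
    identifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _RESIDUE_TABLES:
            raise CompositionError(f"unknown component kind {self.kind!r}")
        if not self.sequence:
            raise CompositionError(f"component {self.name!r}: empty sequence")
        self.sequence = self.sequence.upper().replace(" ", "")
        table = _RESIDUE_TABLES[self.kind]
        for i, letter in enumerate(self.sequence):
            if letter not in table:
                raise CompositionError(
                    f"component {self.name!r}: unknown {self.kind} residue "
                    f"{letter!r} at position {i + 1}"
                )
        if not 0.0 <= self.nonexchangeable_deuteration <= 1.0:
            raise CompositionError(
                f"component {self.name!r}: deuteration fraction must be in [0, 1]"
            )
        if self.copies < 1:
            raise CompositionError(f"component {self.name!r}: copies must be >= 1")

    # ---- per-chain census ---------------------------------------------

    def _chain_census(self):
        """(formula, exchangeable_H, volume_A3) for ONE chain."""
        table = _RESIDUE_TABLES[self.kind]
        formula: dict[str, float] = {}
        n_exch = 0
        volume = 0.0
        for letter in self.sequence:
            res_formula, res_exch, res_vol = table[letter]
            add_formula(formula, res_formula)
            n_exch += res_exch
            volume += res_vol
        # chain closure: one water per chain
        add_formula(formula, WATER_FORMULA)
        if self.kind == "protein":
            # terminal NH2 extra H + carboxyl OH, both labile
            n_exch += 2
        else:
            # 5'-OH oligo: drop the 5' phosphate, gain 5'-OH + 3'-OH
            add_formula(formula, HPO3_FORMULA, scale=-1.0)
            n_exch += 1  # net: -1 P-OH, +2 terminal OH
        for mod, count in self.modifications:
            if isinstance(mod, str):
                if mod not in MODIFICATIONS:
                    raise CompositionError(f"unknown modification {mod!r}")
                mod_formula, mod_exch, mod_vol = MODIFICATIONS[mod]
            else:
                mod_formula, mod_exch, mod_vol = dict(mod), 0, 0.0
            add_formula(formula, mod_formula, scale=count)
            n_exch += mod_exch * count
            volume += mod_vol * count
        for el, count in self.extra_atoms.items():
            if el not in ELEMENTS:
                raise CompositionError(f"unknown element {el!r} in extra_atoms")
            add_formula(formula, {el: count})
            volume += ION_VOLUMES.get(el, 10.0) * count
        return formula, n_exch, volume

    # ---- public single-component quantities ---------------------------

    def mass(self) -> float:
        """Mass in Da of all copies, including deuteration."""
        formula, n_exch, _ = self._chain_census()
        m = formula_mass(formula)
        n_nonexch = formula.get("H", 0.0) - n_exch
        m += self.nonexchangeable_deuteration * n_nonexch * M_D_MINUS_M_H
        return self.copies * m

    def volume(self) -> float:
        """Dry packing volume in A^3 of all copies."""
        _, _, v = self._chain_census()
        return self.copies * v

    def electrons(self) -> float:
        formula, _, _ = self._chain_census()
        return self.copies * formula_electrons(formula)

    def n_exchangeable(self) -> float:
        _, n_exch, _ = self._chain_census()
        return self.copies * n_exch

    def n_nonexchangeable_h(self) -> float:
        formula, n_exch, _ = self._chain_census()
        return self.copies * (formula.get("H", 0.0) - n_exch)

    def neutron_b_fm(self, f_d2o: float = 0.0,
                     exchange_fraction: float = 1.0) -> float:
        """Total neutron scattering length (fm) of all copies in a solvent
        with D2O volume fraction ``f_d2o``."""
        formula, n_exch, _ = self._chain_census()
        n_h_total = formula.get("H", 0.0)
        n_nonexch = n_h_total - n_exch
        b = formula_bcoh_fm({el: n for el, n in formula.items() if el != "H"})
        d = self.nonexchangeable_deuteration
        b += n_nonexch * (_B_H + d * (_B_D - _B_H))
        b += n_exch * (_B_H + exchange_fraction * f_d2o * (_B_D - _B_H))
        return self.copies * b


@dataclass
class Assembly:
    """The stoichiometric scattering particle: one or more components."""

    components: list

    def __post_init__(self):
        if not self.components:
            raise CompositionError("assembly needs at least one component")

    def mass(self) -> float:
        return sum(c.mass() for c in self.components)

    def volume(self) -> float:
        return sum(c.volume() for c in self.components)


@dataclass
class SolventSpec:
    """Aqueous solvent: D2O volume fraction plus (ignored by default) solutes."""

    d2o_volume_fraction: float = 0.0
    solutes: list = field(default_factory=list)
    include_solutes: bool = False

    def __post_init__(self):
        if not 0.0 <= self.d2o_volume_fraction <= 1.0:
            raise CompositionError("d2o_volume_fraction must be in [0, 1]")


@dataclass
class ScatteringParams:
    """All composition-derived scattering quantities for one condition."""

    M: float                 # Da
    nu: float                # cm^3 g^-1
    V: float                 # A^3
    b_X: float               # total X-ray scattering length, cm
    b_N: float               # total neutron scattering length, cm
    n_exch: float            # exchangeable hydrogens
    rho: float               # particle scattering-length density, cm^-2
    rho_solvent: float       # solvent scattering-length density, cm^-2
    delta_rho: float         # contrast, cm^-2
    delta_rho_M: float       # contrast per unit mass, cm g^-1
    probe: str = "xray"


# ---- module-level operations ----------------------------------------------


def molecular_mass(assembly: Assembly) -> float:
    """Mass of the particle in Da (deuteration included)."""
    return assembly.mass()


def partial_specific_volume(assembly: Assembly) -> float:
    """nu = V * N_A / M in cm^3 g^-1 (mass-weighted over components)."""
    return assembly.volume() * 1.0e-24 * AVOGADRO / assembly.mass()


def solvent_sld(solvent: SolventSpec, probe: str = "neutron") -> float:
    """Solvent scattering-length density in cm^-2.

    Linear volume-fraction mix of pure H2O and pure D2O.  For X-rays the
    electron densities of H2O and D2O are equal per molecule; the small
    difference comes from the molar volumes.
    """
    f = solvent.d2o_volume_fraction
    if probe == "neutron":
        b_h2o = formula_bcoh_fm({"H": 2, "O": 1})
        b_d2o = formula_bcoh_fm({"D": 2, "O": 1})
        rho_h = b_h2o * 1.0e-13 / (V_H2O_A3 * 1.0e-24)
        rho_d = b_d2o * 1.0e-13 / (V_D2O_A3 * 1.0e-24)
    elif probe == "xray":
        rho_h = 10.0 * R_ELECTRON_CM / (V_H2O_A3 * 1.0e-24)
        rho_d = 10.0 * R_ELECTRON_CM / (V_D2O_A3 * 1.0e-24)
    else:
        raise ValueError(f"unknown probe {probe!r}")
    return (1.0 - f) * rho_h + f * rho_d


def contrast(assembly: Assembly, solvent: SolventSpec, probe: str = "xray",
             exchange_fraction: float = 1.0) -> ScatteringParams:
    """Contrast of the whole particle against the solvent.

    delta_rho = sum(b) / V - rho_solvent, with exchangeable hydrogens
    interpolated between b_H and b_D by exchange_fraction * f_D2O.
    """
    M = assembly.mass()
    V = assembly.volume()
    nu = V * 1.0e-24 * AVOGADRO / M
    f = solvent.d2o_volume_fraction
    b_x = sum(c.electrons() for c in assembly.components) * R_ELECTRON_CM
    b_n = sum(
        c.neutron_b_fm(f, exchange_fraction) for c in assembly.components
    ) * 1.0e-13
    n_exch = sum(c.n_exchangeable() for c in assembly.components)
    b = b_x if probe == "xray" else b_n
    rho = b / (V * 1.0e-24)
    rho_s = solvent_sld(solvent, probe)
    delta_rho = rho - rho_s
    return ScatteringParams(
        M=M, nu=nu, V=V, b_X=b_x, b_N=b_n, n_exch=n_exch, rho=rho,
        rho_solvent=rho_s, delta_rho=delta_rho,
        delta_rho_M=delta_rho * nu, probe=probe,
    )


def match_point_calculated(assembly: Assembly,
                           exchange_fraction: float = 1.0) -> float:
    """Neutron solvent match point in %(v/v) D2O.

    delta_rho is affine in the D2O fraction, so the zero crossing is
    closed-form from the contrasts at f = 0 and f = 1.  Raises ValueError
    (with the endpoint contrasts in the message) when no root lies in
    [0, 1].
    """
    d0 = contrast(assembly, SolventSpec(0.0), "neutron", exchange_fraction).delta_rho
    d1 = contrast(assembly, SolventSpec(1.0), "neutron", exchange_fraction).delta_rho
    if d0 == d1:
        raise ValueError("no match point in range: contrast independent of f_D2O")
    f = d0 / (d0 - d1)
    if not 0.0 <= f <= 1.0:
        raise ValueError(
            "no match point in range [0, 1]: delta_rho(0) = "
            f"{d0:.4g} cm^-2, delta_rho(1) = {d1:.4g} cm^-2"
        )
    return 100.0 * f
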