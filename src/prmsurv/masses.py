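"""Monoisotopic mass and m/z arithmetic for peptides and PEG oligomers.

Targeted (PRM) quantitation rests on exact precursor and fragment m/z
values.  This module computes them from first principles: monoisotopic
residue masses, fixed/variable modification deltas, stable-isotope label
shifts, and the ethylene-oxide repeat of polyethylene glycol.  Only the
y-ion series is provided for peptide fragments, since C-terminal fragments
are the ones that retain a C-terminal-lysine isotope label and are the
usual quantifier ions for tryptic peptides.

All masses are monoisotopic and in daltons; charging uses the proton mass
(not the hydrogen atom mass), so ``m/z = (M + z * proton) / z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "MassConstants",
    "ModifiedPeptide",
    "PegOligomer",
    "DEFAULT_CONSTANTS",
    "peptide_monoisotopic_mass",
    "precursor_mz",
    "y_ion_mz",
    "peg_mz",
    "round_half_up",
]

#: Monoisotopic residue (i.e. dehydrated amino acid) masses, Da.
_RESIDUE_MONO = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: Mass deltas of the modifications used in this workflow, Da.
_MOD_DELTAS = {
    "carbamidomethyl": 57.021464,
    "oxidation": 15.994915,
    "phosphorylation": 79.966331,
    "acetylation": 42.010565,
    # 13C6,15N2 heavy lysine of the stable-isotope-labeled (SIS) peptide.
    "label_13C6_15N2_K": 8.014199,
}


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Instrument-software reports round half-up, unlike Python's banker's
    rounding, so printed m/z tables are matched with this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MassConstants:
    """The mass scale: residue masses, adduct masses and modification deltas."""

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(_RESIDUE_MONO)
    )
    proton_mass: float = 1.007276
    water_mass: float = 18.010565
    ethylene_oxide_mass: float = 44.026215
    modification_deltas: dict[str, float] = field(
        default_factory=lambda: dict(_MOD_DELTAS)
    )

    def __post_init__(self) -> None:
        if set(self.residue_masses) != set(_RESIDUE_MONO):
            raise ValueError("residue table must contain exactly the 20 standard residues")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be strictly positive")
        missing = set(_MOD_DELTAS) - set(self.modification_deltas)
        if missing:
            raise ValueError(f"modification map missing required names: {sorted(missing)}")


DEFAULT_CONSTANTS = MassConstants()


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications and a precursor charge.

    ``modifications`` is a list of ``(position, name)`` pairs with 0-based
    positions into ``sequence``; names must exist in the constants table.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    charge: int = 1

    def __init__(
        self,
        sequence: str,
        modifications=(),
        charge: int = 1,
        constants: MassConstants = DEFAULT_CONSTANTS,
    ) -> None:
        if not sequence:
            raise ValueError("peptide sequence must be non-empty")
        for res in sequence:
            if res not in constants.residue_masses:
                raise ValueError(f"unknown residue {res!r} in sequence {sequence!r}")
        mods = tuple((int(pos), str(name)) for pos, name in modifications)
        for pos, name in mods:
            if not 0 <= pos < len(sequence):
                raise ValueError(
                    f"modification position {pos} outside sequence of length {len(sequence)}"
                )
            if name not in constants.modification_deltas:
                raise ValueError(f"unknown modification name {name!r}")
        if charge < 1:
            raise ValueError(f"charge must be a positive integer, got {charge}")
        object.__setattr__(self, "sequence", sequence)
        object.__setattr__(self, "modifications", mods)
        object.__setattr__(self, "charge", int(charge))


@dataclass(frozen=True)
class PegOligomer:
    """A polyethylene-glycol chain of ``n_units`` ethylene-oxide repeats."""

    n_units: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ValueError("degree of polymerization must be non-negative")
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")


def peptide_monoisotopic_mass(
    p: ModifiedPeptide, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    mass = constants.water_mass
    for res in p.sequence:
        mass += constants.residue_masses[res]
    for _pos, name in p.modifications:
        mass += constants.modification_deltas[name]
    return mass


def precursor_mz(p: ModifiedPeptide, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """m/z of the intact peptide at its precursor charge."""
    mass = peptide_monoisotopic_mass(p, constants)
    return (mass + p.charge * constants.proton_mass) / p.charge


def y_ion_mz(
    p: ModifiedPeptide,
    k: int,
    fragment_charge: int = 1,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """m/z of the y_k fragment (C-terminal ``k`` residues).

    A modification contributes iff its residue lies within the C-terminal
    ``k`` residues, so a heavy C-terminal lysine shifts every y-ion.
    """
    n = len(p.sequence)
    if not 1 <= k <= n:
        raise ValueError(f"y-ion index k={k} out of range for length-{n} peptide")
    if fragment_charge < 1:
        raise ValueError(f"fragment charge must be positive, got {fragment_charge}")
    mass = constants.water_mass
    for res in p.sequence[n - k :]:
        mass += constants.residue_masses[res]
    for pos, name in p.modifications:
        if pos >= n - k:
            mass += constants.modification_deltas[name]
    return (mass + fragment_charge * constants.proton_mass) / fragment_charge


def peg_mz(o: PegOligomer, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """m/z of a protonated PEG oligomer (or CID fragment) of ``n_units`` repeats.

    PEG fragments at the C–O bonds between ethylene-oxide units, so a
    fragment of degree of polymerization n shares the intact-oligomer
    formula: n repeats + water, protonated.
    """
    mass = o.n_units * constants.ethylene_oxide_mass + constants.water_mass
    return (mass + o.charge * constants.proton_mass) / o.charge
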