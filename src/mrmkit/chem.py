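"""Monoisotopic peptide and fragment-ion mass arithmetic.

Everything in a scheduled-MRM method ultimately reduces to m/z values of
protonated peptides and their a/b/y backbone fragments.  This module keeps
that arithmetic in one place: a :class:`MassConstants` table of monoisotopic
residue masses (plus proton, water, carbon monoxide and fixed modifications),
and pure functions mapping sequences and ion labels to m/z.

Conventions
-----------
* Monoisotopic masses throughout; average-mass mode is deliberately absent.
* ``b_i`` = sum of the first *i* residues + ``charge`` protons, over charge.
* ``y_i`` = sum of the last *i* residues + water + protons, over charge.
* ``a_i`` = ``b_i`` minus carbon monoxide (27.994915 Da) per charge.
* Fixed modifications (default: carbamidomethylation of cysteine,
  +57.021464 Da) are applied once per matching residue.
* Only the a, b and y series are supported; other series raise rather than
  silently returning nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "MassConstants",
    "Ion",
    "DEFAULT_CONSTANTS",
    "InvalidResidueError",
    "peptide_mass",
    "ion_mz",
    "precursor_mz",
    "fragment_mass",
    "fragment_mz",
    "parse_ion_label",
    "format_ion_label",
]

#: Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

PROTON = 1.007276
WATER = 18.010565
CARBON_MONOXIDE = 27.994915
CARBAMIDOMETHYL = 57.021464

SUPPORTED_SERIES = ("a", "b", "y")


class InvalidResidueError(ValueError):
    """A sequence contains a letter with no entry in the residue-mass table."""

    def __init__(self, residue: str, position: int, sequence: str):
        self.residue = residue
        self.position = position  # 1-based
        self.sequence = sequence
        super().__init__(
            f"unknown residue {residue!r} at position {position} of {sequence!r}"
        )


@dataclass(frozen=True)
class MassConstants:
    """Mass basis for all m/z computations.

    ``fixed_mods`` maps a residue letter to a mass shift applied once per
    occurrence (default: carbamidomethylated cysteine).  Pass an empty map to
    compute unmodified masses.
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASSES)
    )
    proton: float = PROTON
    water: float = WATER
    carbon_monoxide: float = CARBON_MONOXIDE
    fixed_mods: Mapping[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )

    def residue_mass(self, letter: str) -> float:
        """Residue mass including any fixed modification on that letter."""
        return self.residue_masses[letter] + self.fixed_mods.get(letter, 0.0)


DEFAULT_CONSTANTS = MassConstants()


def _validate(sequence: str, constants: MassConstants) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, letter in enumerate(sequence, start=1):
        if letter not in constants.residue_masses:
            raise InvalidResidueError(letter, i, sequence)


def _residue_sum(sequence: str, constants: MassConstants) -> float:
    return sum(constants.residue_mass(letter) for letter in sequence)


def peptide_mass(sequence: str, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Neutral monoisotopic mass of a peptide (Da), fixed mods included."""
    _validate(sequence, constants)
    return _residue_sum(sequence, constants) + constants.water


def ion_mz(
    neutral_mass: float, charge: int, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """m/z of an ion carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * constants.proton) / charge


def precursor_mz(
    sequence: str, charge: int, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """m/z of the protonated intact peptide [M + zH]z+."""
    return ion_mz(peptide_mass(sequence, constants), charge, constants)


def fragment_mass(
    sequence: str,
    series: str,
    index: int,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """Neutral fragment mass (Da) for the a/b/y series at ``index``."""
    _validate(sequence, constants)
    if series not in SUPPORTED_SERIES:
        raise ValueError(
            f"unsupported ion series {series!r}; supported: {SUPPORTED_SERIES}"
        )
    n = len(sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(
            f"fragment index {index} out of range 1..{n - 1} for {sequence!r}"
        )
    if series == "y":
        return _residue_sum(sequence[n - index :], constants) + constants.water
    b = _residue_sum(sequence[:index], constants)
    if series == "a":
        return b - constants.carbon_monoxide
    return b


def fragment_mz(
    sequence: str,
    series: str,
    index: int,
    charge: int,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """m/z of a protonated a/b/y fragment ion."""
    return ion_mz(fragment_mass(sequence, series, index, constants), charge, constants)


_LABEL_RE = re.compile(r"^([aby])(\d+)(?:\^(\d+)\+)?$")


def parse_ion_label(label: str) -> tuple[str, int, int]:
    """Parse a fragment label like ``y11^2+``, ``b3`` or ``a4``.

    Returns ``(series, index, charge)``; an omitted charge suffix means 1+.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed ion label {label!r} (expected e.g. 'y4', 'b6^2+')")
    series, index, charge = m.group(1), int(m.group(2)), int(m.group(3) or 1)
    if index < 1:
        raise ValueError(f"ion label {label!r} has index < 1")
    if charge < 1:
        raise ValueError(f"ion label {label!r} has charge < 1")
    return series, index, charge


def format_ion_label(series: str, index: int, charge: int = 1) -> str:
    """Inverse of :func:`parse_ion_label`; charge 1 prints without a suffix."""
    if series not in SUPPORTED_SERIES:
        raise ValueError(f"unsupported ion series {series!r}")
    if index < 1 or charge < 1:
        raise ValueError("index and charge must be >= 1")
    return f"{series}{index}" if charge == 1 else f"{series}{index}^{charge}+"


@dataclass(frozen=True)
class Ion:
    """A precursor or a/b/y fragment ion with its computed m/z."""

    kind: str  # "precursor", "a", "b" or "y"
    charge: int
    mz: float
    index: int | None = None  # fragment length; None for precursors

    def __post_init__(self):
        if self.kind not in ("precursor",) + SUPPORTED_SERIES:
            raise ValueError(f"unsupported ion kind {self.kind!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.kind != "precursor" and (self.index is None or self.index < 1):
            raise ValueError("fragment ions need an index >= 1")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")

    @property
    def label(self) -> str:
        if self.kind == "precursor":
            return f"[M+{self.charge}H]{self.charge}+"
        return format_ion_label(self.kind, self.index, self.charge)

    @classmethod
    def from_label(
        cls,
        label: str,
        sequence: str,
        constants: MassConstants = DEFAULT_CONSTANTS,
    ) -> "Ion":
        """Build a fragment Ion for ``sequence`` from its text label."""
        series, index, charge = parse_ion_label(label)
        return cls(
            kind=series,
            index=index,
            charge=charge,
            mz=fragment_mz(sequence, series, index, charge, constants),
        )
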