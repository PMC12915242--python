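"""Elemental-formula arithmetic, monoisotopic masses, and adduct m/z.

This is the numeric bedrock of the package.  All lipid masses are
monoisotopic (lightest-isotope) sums; isotope envelopes are deliberately
out of scope because unit-resolution triple-quadrupole MRM selects the
monoisotopic peak.  The charge carrier for singly protonated species is
the proton (1.00728 Da); the electron mass is otherwise ignored, which
is the standard convention at unit resolution.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ElementalFormula",
    "AdductSpec",
    "ADDUCTS",
    "WATER",
    "CHOLESTEROL",
    "monoisotopic_mass",
    "adduct_mz",
    "nominal_mz",
    "apply_deuterium_label",
]

#: IUPAC monoisotopic atomic masses (Da).  ``D`` is deuterium, kept as a
#: separate symbol so labeled internal standards stay distinguishable
#: from unlabeled hydrogen.  Version: CODATA/IUPAC 2021 values truncated
#: to the precision used throughout.
MONOISOTOPIC_MASSES: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "N": 14.0030740052,
    "D": 2.0141017780,
}

#: Mass of a proton in Da (charge carrier of [M+H]+).
PROTON_MASS = 1.00728

#: Mass gained per H -> D substitution.
DEUTERIUM_SHIFT = MONOISOTOPIC_MASSES["D"] - MONOISOTOPIC_MASSES["H"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Hill order: carbon, hydrogen, then remaining symbols alphabetically.
_HILL_ORDER = {"C": 0, "H": 1, "D": 2, "N": 3, "O": 4}


class ElementalFormula:
    """An immutable bag of atoms with element-wise arithmetic.

    Supports ``+``, ``-`` (never producing negative counts) and ``*`` by a
    non-negative integer.  Renders to Hill notation (``C74H140O4``).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kw:
            for element, n in source.items():
                merged[element] = merged.get(element, 0) + int(n)
        for element, n in merged.items():
            if element not in MONOISOTOPIC_MASSES:
                raise ValueError(f"unsupported element symbol: {element!r}")
            if n < 0:
                raise ValueError(f"negative count for element {element}: {n}")
        self._counts = {e: n for e, n in merged.items() if n > 0}

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation string such as ``'C56H106O4'``."""
        pos, counts = 0, {}
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos or not match.group(1):
                break
            counts[match.group(1)] = counts.get(match.group(1), 0) + int(match.group(2) or 1)
            pos = match.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse elemental formula: {text!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def items(self):
        return self._counts.items()

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for e, n in other.items():
            counts[e] = counts.get(e, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for e, n in other.items():
            counts[e] = counts.get(e, 0) - n
            if counts[e] < 0:
                raise ValueError(
                    f"subtraction would give negative {e} count: {self} - {other}"
                )
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("formula multiplier must be >= 0")
        return ElementalFormula({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementalFormula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def hill(self) -> str:
        parts = []
        for e in sorted(self._counts, key=lambda s: _HILL_ORDER.get(s, 99)):
            n = self._counts[e]
            parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass of ``formula`` in Da (deterministic element-wise sum)."""
    return sum(MONOISOTOPIC_MASSES[e] * n for e, n in formula.items())


WATER = ElementalFormula(H=2, O=1)
#: Cholesterol backbone, C27H46O — the fixed moiety of both cholesteryl classes.
CHOLESTEROL = ElementalFormula(C=27, H=46, O=1)


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode adduct: name, mass shift in Da, charge (+1 here)."""

    name: str
    mass_shift: float
    charge: int = 1


#: The two adducts the method uses: protonation everywhere, ammonium for
#: cholesteryl-ester precursors (their Q3 fragments are still protonated).
ADDUCTS: Mapping[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS),
    "[M+NH4]+": AdductSpec("[M+NH4]+", 18.03383),
}


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z of ``neutral_mass`` carrying ``adduct`` (singly charged)."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(
                f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}"
            ) from None
    return neutral_mass + adduct.mass_shift


def nominal_mz(mz: float) -> int:
    """Nominal (unit-resolution) m/z: round-half-up to the nearest integer."""
    if mz < 0:
        raise ValueError("m/z must be non-negative")
    return math.floor(mz + 0.5)


def apply_deuterium_label(formula: ElementalFormula, n_label: int) -> ElementalFormula:
    """Replace ``n_label`` hydrogens with deuterium (labeled internal standard).

    The mass increases by ``n_label`` x 1.0062767 Da.
    """
    if n_label < 0:
        raise ValueError("n_label must be >= 0")
    if n_label > formula["H"]:
        raise ValueError(
            f"cannot label {n_label} hydrogens: formula {formula} has only {formula['H']}"
        )
    if n_label == 0:
        return formula
    return (formula - ElementalFormula(H=n_label)) + ElementalFormula(D=n_label)
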