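"""Lipid species construction and grid enumeration.

Six ester lipid classes of sebum/meibum are modeled:

* ``WmE`` — wax monoester: fatty acid (FA) esterified to a fatty alcohol (FAl).
* ``1α-/1ω-WdiE`` — type 1 wax diester: a hydroxy FA whose carboxyl carries a
  FAl and whose hydroxyl (alpha or omega position) carries an FA.
* ``2α-/2ω-WdiE`` — type 2 wax diester: a fatty diol (1,α- or 1,ω-diol) with
  an FA on each hydroxyl.
* ``Chol-E`` — cholesteryl ester of one FA.
* ``Chol-OAHFA`` — cholesteryl ester of an (O-acyl)-ω-hydroxy fatty acid.

An MRM transition for a type 2 WdiE identifies one FA and "the rest" — the
diol esterified with the other FA, called the diol-FA conjugate.  Species may
therefore be built either from full components (diol + FA + FA) or from the
two-part measured readout (FA + diol-FA); both give the same molecule.
"""

from __future__ import annotations

import io
import itertools
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .chem import (
    ADDUCTS,
    CHOLESTEROL,
    WATER,
    AdductSpec,
    ElementalFormula,
    adduct_mz,
    monoisotopic_mass,
    nominal_mz,
)

__all__ = [
    "ChainKind",
    "ChainMoiety",
    "LipidClass",
    "LipidSpecies",
    "MoietyRange",
    "SpeciesGrid",
    "build_species",
    "diol_fa_moiety",
    "oahfa_moiety",
    "enumerate_grid",
    "parse_shorthand",
    "species_table",
    "species_to_csv",
    "SEBUM_PRESETS",
]


class ChainKind(str, Enum):
    """Acyl/alkyl building-block kinds.  The last two are derived conjugates."""

    FA = "FA"                # fatty acid, CnH(2n-2d)O2
    FAL = "FAl"              # fatty alcohol, CnH(2n+2-2d)O
    DIOL_1A = "diol_1a"      # 1,alpha-fatty diol, CnH(2n+2-2d)O2
    DIOL_1W = "diol_1w"      # 1,omega-fatty diol, CnH(2n+2-2d)O2
    AOH_FA = "aOH_FA"        # alpha-hydroxy FA, CnH(2n-2d)O3
    WOH_FA = "wOH_FA"        # omega-hydroxy FA, CnH(2n-2d)O3
    DIOL_FA = "diol_FA"      # diol + FA conjugate (one ester), CnH(2n-2d)O3
    OAHFA = "OAHFA"          # (O-acyl)-omega-OH FA (one ester), CnH(2n-2-2d)O4


# hydrogen offset relative to 2n-2d, and oxygen count, per kind
_FORMULA_RULES: dict[ChainKind, tuple[int, int]] = {
    ChainKind.FA: (0, 2),
    ChainKind.FAL: (2, 1),
    ChainKind.DIOL_1A: (2, 2),
    ChainKind.DIOL_1W: (2, 2),
    ChainKind.AOH_FA: (0, 3),
    ChainKind.WOH_FA: (0, 3),
    ChainKind.DIOL_FA: (0, 3),
    ChainKind.OAHFA: (-2, 4),
}

# ester bonds already embedded in a derived moiety
_EMBEDDED_ESTERS = {ChainKind.DIOL_FA: 1, ChainKind.OAHFA: 1}


@dataclass(frozen=True)
class ChainMoiety:
    """One chain building block: kind + carbon count + double-bond count.

    ``branched`` is a bookkeeping flag for iso/anteiso chains; branching does
    not change the elemental formula (constitutional isomers).
    """

    kind: ChainKind
    carbons: int
    double_bonds: int = 0
    branched: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"moiety needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds > self.carbons / 2:
            raise ValueError(
                f"{self.carbons} carbons cannot carry {self.double_bonds} double bonds"
            )

    @property
    def formula(self) -> ElementalFormula:
        h_offset, oxygens = _FORMULA_RULES[self.kind]
        hydrogens = 2 * self.carbons - 2 * self.double_bonds + h_offset
        if hydrogens <= 0:
            raise ValueError(f"degenerate moiety {self}")
        return ElementalFormula(C=self.carbons, H=hydrogens, O=oxygens)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def name(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        return f"{self.kind.value} {self.name}"


def diol_fa_moiety(diol: ChainMoiety, fa: ChainMoiety) -> ChainMoiety:
    """Condense a fatty diol with an FA into the derived diol-FA conjugate.

    Carbons and double bonds add; the formula is diol + FA - H2O.
    """
    if diol.kind not in (ChainKind.DIOL_1A, ChainKind.DIOL_1W):
        raise ValueError(f"expected a fatty diol, got {diol.kind.value}")
    if fa.kind is not ChainKind.FA:
        raise ValueError(f"expected an FA, got {fa.kind.value}")
    derived = ChainMoiety(ChainKind.DIOL_FA, diol.carbons + fa.carbons,
                          diol.double_bonds + fa.double_bonds)
    assert derived.formula == diol.formula + fa.formula - WATER
    return derived


def oahfa_moiety(woh_fa: ChainMoiety, fa: ChainMoiety) -> ChainMoiety:
    """Condense an omega-OH FA with an FA into the derived OAHFA conjugate."""
    if woh_fa.kind is not ChainKind.WOH_FA:
        raise ValueError(f"expected an omega-OH FA, got {woh_fa.kind.value}")
    if fa.kind is not ChainKind.FA:
        raise ValueError(f"expected an FA, got {fa.kind.value}")
    derived = ChainMoiety(ChainKind.OAHFA, woh_fa.carbons + fa.carbons,
                          woh_fa.double_bonds + fa.double_bonds)
    assert derived.formula == woh_fa.formula + fa.formula - WATER
    return derived


class LipidClass(str, Enum):
    WME = "WmE"
    WDIE_1A = "1α-WdiE"
    WDIE_1W = "1ω-WdiE"
    WDIE_2A = "2α-WdiE"
    WDIE_2W = "2ω-WdiE"
    CHOL_E = "Chol-E"
    CHOL_OAHFA = "Chol-OAHFA"


_WDIE_CLASSES = {LipidClass.WDIE_1A, LipidClass.WDIE_1W,
                 LipidClass.WDIE_2A, LipidClass.WDIE_2W}
_CHOL_CLASSES = {LipidClass.CHOL_E, LipidClass.CHOL_OAHFA}

#: Accepted moiety-kind sequences per class (alternatives allowed).
CLASS_RECIPES: dict[LipidClass, tuple[tuple[ChainKind, ...], ...]] = {
    LipidClass.WME: ((ChainKind.FA, ChainKind.FAL),),
    LipidClass.WDIE_1A: ((ChainKind.AOH_FA, ChainKind.FAL, ChainKind.FA),),
    LipidClass.WDIE_1W: ((ChainKind.WOH_FA, ChainKind.FAL, ChainKind.FA),),
    LipidClass.WDIE_2A: (
        (ChainKind.DIOL_1A, ChainKind.FA, ChainKind.FA),
        (ChainKind.FA, ChainKind.DIOL_FA),
    ),
    LipidClass.WDIE_2W: (
        (ChainKind.DIOL_1W, ChainKind.FA, ChainKind.FA),
        (ChainKind.FA, ChainKind.DIOL_FA),
    ),
    LipidClass.CHOL_E: ((ChainKind.FA,),),
    LipidClass.CHOL_OAHFA: (
        (ChainKind.WOH_FA, ChainKind.FA),
        (ChainKind.OAHFA,),
    ),
}

_ESTER_BONDS = {
    LipidClass.WME: 1,
    LipidClass.WDIE_1A: 2,
    LipidClass.WDIE_1W: 2,
    LipidClass.WDIE_2A: 2,
    LipidClass.WDIE_2W: 2,
    LipidClass.CHOL_E: 1,
    LipidClass.CHOL_OAHFA: 2,
}


@dataclass(frozen=True)
class LipidSpecies:
    """An assembled molecule: class, ordered component moieties, formula."""

    lipid_class: LipidClass
    moieties: tuple[ChainMoiety, ...]
    formula: ElementalFormula
    neutral_mass: float
    shorthand: str
    precursor_adduct: AdductSpec

    @property
    def precursor_mz(self) -> float:
        return adduct_mz(self.neutral_mass, self.precursor_adduct)

    @property
    def nominal_precursor_mz(self) -> int:
        return nominal_mz(self.precursor_mz)

    @property
    def total_carbons(self) -> int:
        """Chain carbons summed over moieties (cholesterol not counted)."""
        return sum(m.carbons for m in self.moieties)

    @property
    def total_double_bonds(self) -> int:
        return sum(m.double_bonds for m in self.moieties)

    def __str__(self) -> str:
        return self.shorthand


def _shorthand(lipid_class: LipidClass, moieties: Sequence[ChainMoiety]) -> str:
    """Two-part shorthand: ``<CLASS> <FA C:d>/<other moiety C:d>``.

    For three-component builds the "other" part is the condensed remainder
    (diol + second FA, or hydroxy-FA + FAl), matching the two-part readout
    an MRM transition actually identifies.
    """
    cls = lipid_class.value
    kinds = tuple(m.kind for m in moieties)
    if lipid_class is LipidClass.WME:
        fa, fal = moieties
        return f"{cls} {fa.name}/{fal.name}"
    if lipid_class is LipidClass.CHOL_E:
        return f"{cls} {moieties[0].name}"
    if lipid_class is LipidClass.CHOL_OAHFA:
        if kinds == (ChainKind.OAHFA,):
            return f"{cls} {moieties[0].name}"
        woh, fa = moieties
        return f"{cls} {fa.name}/{woh.name}"
    # wax diesters
    if kinds[-1] is ChainKind.DIOL_FA:
        fa, dfa = moieties
        return f"{cls} {fa.name}/{dfa.name}"
    if lipid_class in (LipidClass.WDIE_2A, LipidClass.WDIE_2W):
        diol, fa1, fa2 = moieties
        rest = diol_fa_moiety(diol, fa2)
        return f"{cls} {fa1.name}/{rest.name}"
    # type 1: remainder is hydroxy-FA + FAl (one ester)
    ohfa, fal, fa = moieties
    rest_c = ohfa.carbons + fal.carbons
    rest_d = ohfa.double_bonds + fal.double_bonds
    return f"{cls} {fa.name}/{rest_c}:{rest_d}"


def build_species(lipid_class: LipidClass,
                  moieties: Sequence[ChainMoiety]) -> LipidSpecies:
    """Assemble a species of ``lipid_class`` from ``moieties``.

    The formula is the sum of component formulas (plus cholesterol for the
    cholesteryl classes) minus one H2O per newly formed ester bond.
    """
    moieties = tuple(moieties)
    kinds = tuple(m.kind for m in moieties)
    if kinds not in CLASS_RECIPES[lipid_class]:
        recipes = " or ".join(
            "(" + ", ".join(k.value for k in r) + ")"
            for r in CLASS_RECIPES[lipid_class]
        )
        raise ValueError(
            f"{lipid_class.value} expects moieties {recipes}; "
            f"got ({', '.join(k.value for k in kinds)})"
        )
    formula = ElementalFormula()
    for m in moieties:
        formula = formula + m.formula
    if lipid_class in _CHOL_CLASSES:
        formula = formula + CHOLESTEROL
    n_water = _ESTER_BONDS[lipid_class] - sum(
        _EMBEDDED_ESTERS.get(k, 0) for k in kinds
    )
    formula = formula - n_water * WATER
    adduct = ADDUCTS["[M+NH4]+"] if lipid_class is LipidClass.CHOL_E else ADDUCTS["[M+H]+"]
    return LipidSpecies(
        lipid_class=lipid_class,
        moieties=moieties,
        formula=formula,
        neutral_mass=monoisotopic_mass(formula),
        shorthand=_shorthand(lipid_class, moieties),
        precursor_adduct=adduct,
    )


_SHORTHAND_RE = re.compile(r"^(?P<cls>.+?)\s+(?P<a>\d+:\d+)(?:/(?P<b>\d+:\d+))?$")


def _parse_cd(token: str) -> tuple[int, int]:
    c, d = token.split(":")
    return int(c), int(d)


def parse_shorthand(text: str) -> LipidSpecies:
    """Rebuild a species from its shorthand name.

    The two-part WdiE shorthand maps to the (FA, diol-FA) construction; the
    underlying diol / second-FA split is not encoded in the name, by design.
    """
    m = _SHORTHAND_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse species shorthand: {text!r}")
    try:
        cls = LipidClass(m.group("cls"))
    except ValueError:
        raise ValueError(f"unknown lipid class in shorthand: {m.group('cls')!r}") from None
    a, b = m.group("a"), m.group("b")
    if cls is LipidClass.WME:
        if b is None:
            raise ValueError("WmE shorthand needs FA/FAl")
        return build_species(cls, (ChainMoiety(ChainKind.FA, *_parse_cd(a)),
                                   ChainMoiety(ChainKind.FAL, *_parse_cd(b))))
    if cls is LipidClass.CHOL_E:
        return build_species(cls, (ChainMoiety(ChainKind.FA, *_parse_cd(a)),))
    if cls is LipidClass.CHOL_OAHFA:
        if b is None:
            return build_species(cls, (ChainMoiety(ChainKind.OAHFA, *_parse_cd(a)),))
        return build_species(cls, (ChainMoiety(ChainKind.WOH_FA, *_parse_cd(b)),
                                   ChainMoiety(ChainKind.FA, *_parse_cd(a))))
    if cls in (LipidClass.WDIE_2A, LipidClass.WDIE_2W):
        if b is None:
            raise ValueError(f"{cls.value} shorthand needs FA/diol-FA")
        return build_species(cls, (ChainMoiety(ChainKind.FA, *_parse_cd(a)),
                                   ChainMoiety(ChainKind.DIOL_FA, *_parse_cd(b))))
    raise ValueError(f"type 1 WdiE shorthand is not reconstructible: {text!r}")


# ---------------------------------------------------------------------------
# grids

@dataclass(frozen=True)
class MoietyRange:
    """An enumerable axis of moieties: carbon range x saturation set."""

    kind: ChainKind
    carbons: tuple[int, int]  # inclusive (min, max)
    double_bonds: tuple[int, ...]
    carbon_step: int = 1

    def moieties(self) -> list[ChainMoiety]:
        lo, hi = self.carbons
        return [
            ChainMoiety(self.kind, c, d)
            for c in range(lo, hi + 1, self.carbon_step)
            for d in sorted(set(self.double_bonds))
        ]


@dataclass(frozen=True)
class SpeciesGrid:
    """A finite Cartesian grid of species of one class."""

    lipid_class: LipidClass
    axes: tuple[MoietyRange, ...]
    #: true when the range extends beyond chain lengths explicitly reported
    extrapolated: bool = False


def enumerate_grid(grid: SpeciesGrid) -> list[LipidSpecies]:
    """All species of the grid, deterministic, duplicate-free, ordered.

    Order is lexicographic over the axes, each axis sorted by (carbons,
    double bonds).  Empty ranges yield an empty list.
    """
    axis_moieties = [ax.moieties() for ax in grid.axes]
    seen: set[str] = set()
    out: list[LipidSpecies] = []
    for combo in itertools.product(*axis_moieties):
        sp = build_species(grid.lipid_class, combo)
        if sp.shorthand not in seen:
            seen.add(sp.shorthand)
            out.append(sp)
    return out


def species_table(species: Iterable[LipidSpecies]) -> pd.DataFrame:
    rows = [
        {
            "class": sp.lipid_class.value,
            "shorthand": sp.shorthand,
            "formula": sp.formula.hill(),
            "neutral_mass": sp.neutral_mass,
            "precursor_adduct": sp.precursor_adduct.name,
            "precursor_mz": sp.precursor_mz,
            "nominal_mz": sp.nominal_precursor_mz,
        }
        for sp in species
    ]
    return pd.DataFrame(
        rows,
        columns=["class", "shorthand", "formula", "neutral_mass",
                 "precursor_adduct", "precursor_mz", "nominal_mz"],
    )


def species_to_csv(species: Iterable[LipidSpecies], path=None) -> str:
    """Write the species list as CSV (masses to 5, m/z to 4 decimals)."""
    df = species_table(species)
    df["neutral_mass"] = df["neutral_mass"].map(lambda x: f"{x:.5f}")
    df["precursor_mz"] = df["precursor_mz"].map(lambda x: f"{x:.4f}")
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text


#: Default grids mirroring the measured sebum chain/saturation ranges.
#: The Chol-OAHFA and Chol-E ranges extend modestly beyond the chain lengths
#: explicitly printed and are marked ``extrapolated``; all presets are
#: user-overridable.
SEBUM_PRESETS: dict[str, SpeciesGrid] = {
    "WmE": SpeciesGrid(
        LipidClass.WME,
        (MoietyRange(ChainKind.FA, (14, 25), (0, 1)),
         MoietyRange(ChainKind.FAL, (16, 40), (0, 1))),
    ),
    "2α-WdiE": SpeciesGrid(
        LipidClass.WDIE_2A,
        (MoietyRange(ChainKind.FA, (16, 16), (0, 1)),
         MoietyRange(ChainKind.DIOL_FA, (32, 60), (0, 1, 2, 3))),
    ),
    "2ω-WdiE": SpeciesGrid(
        LipidClass.WDIE_2W,
        (MoietyRange(ChainKind.FA, (18, 22), (1,), carbon_step=2),
         MoietyRange(ChainKind.DIOL_FA, (32, 60), (0, 1, 2, 3))),
    ),
    "Chol-OAHFA": SpeciesGrid(
        LipidClass.CHOL_OAHFA,
        (MoietyRange(ChainKind.OAHFA, (50, 60), (1, 2, 3)),),
        extrapolated=True,
    ),
    "Chol-E": SpeciesGrid(
        LipidClass.CHOL_E,
        (MoietyRange(ChainKind.FA, (24, 40), (0, 1, 2)),),
        extrapolated=True,
    ),
}
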