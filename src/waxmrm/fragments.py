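"""Class- and moiety-specific product-ion m/z rules.

Collision-induced dissociation of protonated wax diesters yields two
diagnostic ion families: the acylium of one fatty acid, [FA − OH]+, and the
dehydrated protonated remainder, [M + H − (FA − OH) − H2O]+, i.e. the
diol-FA conjugate minus water.  Cholesteryl esters fragment to the
cholestadienyl cation (cholesterol + H − H2O, C27H45+).  Wax monoesters
yield an FA-derived ion whose identity depends on FA saturation; the
saturated/unsaturated channel mapping is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

from .chem import CHOLESTEROL, PROTON_MASS, WATER, monoisotopic_mass, nominal_mz
from .species import ChainKind, ChainMoiety, LipidClass, LipidSpecies

__all__ = [
    "CHOLESTADIENYL_MZ",
    "Fragment",
    "FragmentConfig",
    "acylium_mz",
    "protonated_fa_mz",
    "diolfa_fragment_mz",
    "wohfa_fragment_mz",
    "fragment_set",
]

_WATER_MASS = monoisotopic_mass(WATER)

#: m/z of the cholestadienyl cation C27H45+ (cholesterol + H+ − H2O).
CHOLESTADIENYL_MZ = monoisotopic_mass(CHOLESTEROL) + PROTON_MASS - _WATER_MASS


def _require_kind(moiety: ChainMoiety, kind: ChainKind, rule: str) -> None:
    if moiety.kind is not kind:
        raise ValueError(
            f"{rule} applies to {kind.value} moieties, got {moiety.kind.value}"
        )


def acylium_mz(fa: ChainMoiety) -> float:
    """[FA − OH]+ : protonated FA minus water."""
    _require_kind(fa, ChainKind.FA, "acylium")
    return fa.mass + PROTON_MASS - _WATER_MASS


def protonated_fa_mz(fa: ChainMoiety) -> float:
    """[FA + H]+ without water loss."""
    _require_kind(fa, ChainKind.FA, "protonated_FA")
    return fa.mass + PROTON_MASS


def diolfa_fragment_mz(diolfa: ChainMoiety) -> float:
    """[M + H − (FA − OH) − H2O]+ : dehydrated protonated diol-FA conjugate."""
    _require_kind(diolfa, ChainKind.DIOL_FA, "diolFA_dehydrated")
    return diolfa.mass + PROTON_MASS - _WATER_MASS


def wohfa_fragment_mz(wohfa: ChainMoiety) -> float:
    """Dehydrated protonated omega-OH FA (registry default, replaceable)."""
    _require_kind(wohfa, ChainKind.WOH_FA, "wOHFA_dehydrated")
    return wohfa.mass + PROTON_MASS - _WATER_MASS


@dataclass(frozen=True)
class Fragment:
    """One product-ion channel: rule name, source moiety, m/z."""

    rule: str
    moiety: str  # source moiety shorthand ("16:1") or "" for constants
    mz: float

    @property
    def nominal_mz(self) -> int:
        return nominal_mz(self.mz)


@dataclass(frozen=True)
class FragmentConfig:
    """Per-class fragment-channel configuration.

    ``wme_saturated_rule`` / ``wme_unsaturated_rule`` choose the WmE Q3 ion
    by FA saturation (default: saturated FA -> protonated FA, unsaturated ->
    acylium; water loss is facile for unsaturated acyl cations).  ``extra``
    registers additional per-class channels, e.g. diagnostic ions for type 1
    WdiEs, which ship with no default rules.
    """

    wme_saturated_rule: str = "protonated_FA"
    wme_unsaturated_rule: str = "acylium"
    extra: dict[LipidClass, tuple[Callable[[LipidSpecies], Fragment], ...]] = field(
        default_factory=dict
    )

    def with_extra(self, lipid_class: LipidClass,
                   *rules: Callable[[LipidSpecies], Fragment]) -> "FragmentConfig":
        extra = dict(self.extra)
        extra[lipid_class] = extra.get(lipid_class, ()) + rules
        return replace(self, extra=extra)


DEFAULT_CONFIG = FragmentConfig()

_FA_RULES: dict[str, Callable[[ChainMoiety], float]] = {
    "acylium": acylium_mz,
    "protonated_FA": protonated_fa_mz,
}


def _wme_fragments(species: LipidSpecies, config: FragmentConfig) -> list[Fragment]:
    fa = species.moieties[0]
    rule = config.wme_saturated_rule if fa.double_bonds == 0 else config.wme_unsaturated_rule
    try:
        fn = _FA_RULES[rule]
    except KeyError:
        raise ValueError(f"unknown WmE FA rule {rule!r}; known: {sorted(_FA_RULES)}") from None
    return [Fragment(rule, fa.name, fn(fa))]


def _wdie2_fragments(species: LipidSpecies, config: FragmentConfig) -> list[Fragment]:
    kinds = tuple(m.kind for m in species.moieties)
    pairs: list[tuple[ChainMoiety, ChainMoiety]] = []
    if kinds[-1] is ChainKind.DIOL_FA:
        fa, dfa = species.moieties
        pairs.append((fa, dfa))
    else:
        diol, fa1, fa2 = species.moieties
        from .species import diol_fa_moiety
        pairs.append((fa1, diol_fa_moiety(diol, fa2)))
        pairs.append((fa2, diol_fa_moiety(diol, fa1)))
    out: list[Fragment] = []
    for fa, dfa in pairs:
        out.append(Fragment("acylium", fa.name, acylium_mz(fa)))
        out.append(Fragment("diolFA_dehydrated", dfa.name, diolfa_fragment_mz(dfa)))
    # identical FAs on a diol give duplicate channels; keep one of each
    seen: set[tuple[str, str]] = set()
    unique = []
    for f in out:
        key = (f.rule, f.moiety)
        if key not in seen:
            seen.add(key)
            unique.append(f)
    return unique


def _chol_oahfa_fragments(species: LipidSpecies, config: FragmentConfig) -> list[Fragment]:
    out = [Fragment("cholestadienyl", "", CHOLESTADIENYL_MZ)]
    kinds = tuple(m.kind for m in species.moieties)
    if kinds == (ChainKind.WOH_FA, ChainKind.FA):
        woh, fa = species.moieties
        out.insert(0, Fragment("acylium", fa.name, acylium_mz(fa)))
        out.insert(1, Fragment("wOHFA_dehydrated", woh.name, wohfa_fragment_mz(woh)))
    # OAHFA-level species: the FA / omega-OH-FA split is unknown, so only the
    # split-independent cholestadienyl channel is emitted.
    return out


_CLASS_RULES: dict[LipidClass, Callable[[LipidSpecies, FragmentConfig], list[Fragment]]] = {
    LipidClass.WME: _wme_fragments,
    LipidClass.WDIE_2A: _wdie2_fragments,
    LipidClass.WDIE_2W: _wdie2_fragments,
    LipidClass.CHOL_E: lambda sp, cfg: [Fragment("cholestadienyl", "", CHOLESTADIENYL_MZ)],
    LipidClass.CHOL_OAHFA: _chol_oahfa_fragments,
}


def fragment_set(species: LipidSpecies,
                 config: FragmentConfig = DEFAULT_CONFIG) -> list[Fragment]:
    """All default product-ion channels for ``species``.

    Type 1 WdiEs ship with no default channels (their diagnostic fragments
    are not established); register rules via ``FragmentConfig.with_extra``.
    """
    extra = config.extra.get(species.lipid_class, ())
    builder = _CLASS_RULES.get(species.lipid_class)
    if builder is None and not extra:
        configured = sorted(c.value for c in _CLASS_RULES)
        raise ValueError(
            f"no fragment rules configured for {species.lipid_class.value}; "
            f"classes with defaults: {configured}"
        )
    out = builder(species, config) if builder else []
    out.extend(rule(species) for rule in extra)
    return out
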