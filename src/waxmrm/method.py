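"""Instrument-ready MRM transition tables.

One transition per (species x fragment channel).  Q1 carries the class
adduct rule — ammonium adducts for cholesteryl esters, proton adducts for
everything else — and Q3 the fragment rules from :mod:`waxmrm.fragments`.
Collision energies are per-class defaults (per-species tuning values are
instrument-dependent) and every row is overridable.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .fragments import DEFAULT_CONFIG, FragmentConfig, fragment_set
from .species import LipidClass, SpeciesGrid, enumerate_grid

__all__ = [
    "MRMTransition",
    "MethodConfig",
    "DEFAULT_METHOD_CONFIG",
    "build_method",
    "validate_method",
    "MethodReport",
    "transitions_to_csv",
    "method_metadata_json",
]

#: bit-exact CSV header for transition tables
CSV_HEADER = "compound,class,precursor_mz,product_mz,collision_energy_eV,dwell_s,polarity"


@dataclass(frozen=True)
class MRMTransition:
    compound: str
    lipid_class: LipidClass
    precursor_mz: float  # Q1
    product_mz: float    # Q3
    collision_energy_eV: float
    dwell_s: float = 0.03
    polarity: str = "positive"

    def with_collision_energy(self, ce: float) -> "MRMTransition":
        return replace(self, collision_energy_eV=ce)


@dataclass(frozen=True)
class MethodConfig:
    """Per-class collision energies plus carried-along method metadata.

    The 30 eV (WdiE) and 15 eV (Chol-OAHFA) defaults follow the product-ion
    scan settings of the source method; WmE and Chol-E default to 25 eV as
    placeholders for per-species tuning values.  Ion-source parameters and
    the LC gradient are annotations only — never used in computation.
    """

    collision_energies: Mapping[LipidClass, float] = field(default_factory=lambda: {
        LipidClass.WME: 25.0,
        LipidClass.WDIE_1A: 30.0,
        LipidClass.WDIE_1W: 30.0,
        LipidClass.WDIE_2A: 30.0,
        LipidClass.WDIE_2W: 30.0,
        LipidClass.CHOL_E: 25.0,
        LipidClass.CHOL_OAHFA: 15.0,
    })
    dwell_s: float = 0.03
    source_params: Mapping[str, object] = field(default_factory=lambda: {
        "capillary_voltage_kV": {"WmE": 3.0, "WdiE": 3.0, "Chol-OAHFA": 3.5, "Chol-E": 1.5},
        "cone_voltage_V": {"WmE": 40, "WdiE": 35, "Chol-OAHFA": 35, "Chol-E": 15},
        "desolvation_gas_flow_L_per_h": 1200,
        "source_temperature_C": {"WmE": 150, "WdiE": 150, "Chol-OAHFA": 150, "Chol-E": 110},
    })
    lc_gradient: str = ("0 min 60% B; 0-21 min gradient to 100% B; 21-25 min 100% B; "
                       "25-30 min gradient to 60% B; flow 0.3 mL/min")


DEFAULT_METHOD_CONFIG = MethodConfig()


def build_method(grids: Sequence[SpeciesGrid],
                 config: MethodConfig = DEFAULT_METHOD_CONFIG,
                 fragment_config: FragmentConfig = DEFAULT_CONFIG) -> list[MRMTransition]:
    """One transition per (species, fragment channel) over all grids.

    Deterministic ordering: class, then compound shorthand, then Q3.
    """
    transitions: list[MRMTransition] = []
    for grid in grids:
        if grid.lipid_class not in config.collision_energies:
            raise ValueError(
                f"no collision energy configured for class {grid.lipid_class.value}"
            )
        ce = config.collision_energies[grid.lipid_class]
        for sp in enumerate_grid(grid):
            for frag in fragment_set(sp, fragment_config):
                transitions.append(MRMTransition(
                    compound=sp.shorthand,
                    lipid_class=sp.lipid_class,
                    precursor_mz=sp.precursor_mz,
                    product_mz=frag.mz,
                    collision_energy_eV=ce,
                    dwell_s=config.dwell_s,
                ))
    transitions.sort(key=lambda t: (t.lipid_class.value, t.compound, t.product_mz))
    return transitions


@dataclass(frozen=True)
class MethodReport:
    """Report-only validation findings (nothing here raises)."""

    duplicates: tuple[tuple[str, str], ...]         # co-measured (Q1,Q3) pairs
    q3_not_below_q1: tuple[str, ...]                # compounds with Q3 >= Q1
    isobaric_resolvable: tuple[tuple[str, str], ...]  # share Q1, differ in Q3

    @property
    def ok(self) -> bool:
        return not (self.duplicates or self.q3_not_below_q1)


def validate_method(transitions: Sequence[MRMTransition],
                    mz_window: float = 0.5) -> MethodReport:
    """Flag co-measured channels, Q3 >= Q1 rows, and MRM-resolvable isobars.

    Two transitions are co-measured when both Q1 and Q3 agree within
    ``mz_window``.  Two distinct compounds are "isobaric, MRM-resolvable"
    when their Q1 agree within the window but at least one Q3 differs —
    exactly the cases a triple quadrupole can separate that LC-MS cannot.
    """
    duplicates: list[tuple[str, str]] = []
    q3_viol = tuple(t.compound for t in transitions if t.product_mz >= t.precursor_mz)

    by_q1 = sorted(range(len(transitions)), key=lambda i: transitions[i].precursor_mz)
    for pos, i in enumerate(by_q1):
        ti = transitions[i]
        for j in by_q1[pos + 1:]:
            tj = transitions[j]
            if tj.precursor_mz - ti.precursor_mz > mz_window:
                break
            if abs(ti.product_mz - tj.product_mz) <= mz_window:
                duplicates.append(tuple(sorted((ti.compound, tj.compound))))

    # compound-level Q1 and Q3 sets
    q1_of: dict[str, float] = {}
    q3s_of: dict[str, set[float]] = {}
    for t in transitions:
        q1_of.setdefault(t.compound, t.precursor_mz)
        q3s_of.setdefault(t.compound, set()).add(t.product_mz)
    names = sorted(q1_of, key=lambda c: q1_of[c])
    isobaric: list[tuple[str, str]] = []
    for pos, a in enumerate(names):
        for b in names[pos + 1:]:
            if q1_of[b] - q1_of[a] > mz_window:
                break
            resolvable = any(
                all(abs(qa - qb) > mz_window for qb in q3s_of[b]) for qa in q3s_of[a]
            )
            if resolvable:
                isobaric.append((a, b))
    return MethodReport(
        duplicates=tuple(dict.fromkeys(duplicates)),
        q3_not_below_q1=q3_viol,
        isobaric_resolvable=tuple(isobaric),
    )


def transitions_to_csv(transitions: Iterable[MRMTransition], path=None) -> str:
    """Transition table CSV with the documented header; m/z at 4 decimals."""
    buf = io.StringIO()
    buf.write(CSV_HEADER + "\n")
    for t in transitions:
        buf.write(
            f"{t.compound},{t.lipid_class.value},{t.precursor_mz:.4f},"
            f"{t.product_mz:.4f},{t.collision_energy_eV:g},{t.dwell_s:g},{t.polarity}\n"
        )
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text


def method_metadata_json(config: MethodConfig = DEFAULT_METHOD_CONFIG, path=None) -> str:
    """Method metadata (CEs, source parameters, gradient) as a JSON sidecar."""
    payload = {
        "collision_energies_eV": {c.value: ce for c, ce in config.collision_energies.items()},
        "dwell_s": config.dwell_s,
        "source_params": config.source_params,
        "lc_gradient": config.lc_gradient,
        "polarity": "positive",
    }
    text = json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
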