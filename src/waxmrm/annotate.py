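"""Product-ion-scan interpretation.

A product-ion scan of one wax-diester precursor mixes fragments from every
co-isobaric FA / diol-FA split of the same total composition.  This module
enumerates those splits, matches observed centroids to the theoretical
acylium ([FA − OH]+) and dehydrated diol-FA ([M + H − (FA − OH) − H2O]+)
channels, and reports the two fragment clusters and the dominant split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chem import adduct_mz, monoisotopic_mass
from .fragments import acylium_mz, diolfa_fragment_mz
from .species import (
    ChainKind,
    ChainMoiety,
    LipidClass,
    MoietyRange,
    build_species,
)

__all__ = [
    "Spectrum",
    "SpeciesHypothesis",
    "PeakAssignment",
    "AnnotationResult",
    "isobaric_splits",
    "annotate_spectrum",
    "read_mgf",
    "write_mgf",
    "read_spectrum_csv",
    "read_mzml",
]

FA_CLUSTER = "FA cluster"
DIOLFA_CLUSTER = "diol-FA cluster"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Spectrum:
    """A centroided product-ion spectrum of one precursor."""

    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_peaks(cls, precursor_mz: float,
                   peaks: Iterable[tuple[float, float]],
                   collision_energy: float | None = None) -> "Spectrum":
        pairs = sorted(peaks)
        mz = np.array([p[0] for p in pairs])
        inten = np.array([p[1] for p in pairs])
        return cls(precursor_mz, mz, inten, collision_energy)

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class SpeciesHypothesis:
    """A class + total composition hypothesis for one precursor.

    ``fa_range`` constrains the candidate FA moieties of the splits.
    """

    lipid_class: LipidClass
    total_carbons: int
    total_double_bonds: int
    fa_range: MoietyRange = MoietyRange(ChainKind.FA, (14, 26), (0, 1))

    def precursor_mz(self) -> float:
        splits = isobaric_splits(self.lipid_class, self.total_carbons,
                                 self.total_double_bonds, self.fa_range)
        if splits:
            sp = build_species(self.lipid_class, splits[0])
            return sp.precursor_mz
        # no admissible split: fall back to the class hydrogen rule
        c, d = self.total_carbons, self.total_double_bonds
        from .chem import ElementalFormula
        return adduct_mz(
            monoisotopic_mass(ElementalFormula(C=c, H=2 * c - 2 - 2 * d, O=4)),
            "[M+H]+",
        )


def isobaric_splits(lipid_class: LipidClass, total_carbons: int,
                    total_double_bonds: int,
                    fa_range: MoietyRange) -> list[tuple[ChainMoiety, ChainMoiety]]:
    """All (FA, diol-FA) decompositions of a type 2 WdiE total composition.

    Deterministic order by FA carbon count then FA double bonds.  Totals
    unreachable under the constraints give an empty list.
    """
    if lipid_class not in (LipidClass.WDIE_2A, LipidClass.WDIE_2W):
        raise ValueError(
            f"isobaric splits are defined for type 2 WdiEs, not {lipid_class.value}"
        )
    if fa_range.kind is not ChainKind.FA:
        raise ValueError("fa_range must enumerate FA moieties")
    out = []
    for fa in fa_range.moieties():
        c = total_carbons - fa.carbons
        d = total_double_bonds - fa.double_bonds
        if c < 2 or d < 0 or d > c / 2:
            continue
        out.append((fa, ChainMoiety(ChainKind.DIOL_FA, c, d)))
    return out


@dataclass(frozen=True)
class PeakAssignment:
    peak_mz: float
    intensity: float
    cluster: str                    # FA cluster | diol-FA cluster | unassigned
    fragment: str = ""              # e.g. "acylium 16:1"
    split: str = ""                 # e.g. "16:1/40:1"
    theoretical_mz: float | None = None
    mass_error: float | None = None
    alternatives: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnnotationResult:
    spectrum: Spectrum
    hypothesis: SpeciesHypothesis
    tolerance: float
    assignments: tuple[PeakAssignment, ...]

    def cluster_intensity(self) -> dict[str, float]:
        totals: dict[str, float] = {FA_CLUSTER: 0.0, DIOLFA_CLUSTER: 0.0, UNASSIGNED: 0.0}
        for a in self.assignments:
            totals[a.cluster] += a.intensity
        return totals

    def split_intensity(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for a in self.assignments:
            if a.split:
                totals[a.split] = totals.get(a.split, 0.0) + a.intensity
        return totals

    def dominant_split(self) -> str | None:
        totals = self.split_intensity()
        if not totals:
            return None
        return max(sorted(totals), key=lambda s: totals[s])

    def recovered_splits(self) -> set[str]:
        return {a.split for a in self.assignments if a.split}

    def to_tsv(self, path=None) -> str:
        header = ("peak_mz\tintensity\tcluster\tfragment\tsplit\t"
                  "theoretical_mz\tmass_error_da\talternatives")
        lines = [header]
        for a in self.assignments:
            theo = "" if a.theoretical_mz is None else f"{a.theoretical_mz:.4f}"
            err = "" if a.mass_error is None else f"{a.mass_error:+.4f}"
            lines.append(
                f"{a.peak_mz:.4f}\t{a.intensity:g}\t{a.cluster}\t{a.fragment}\t"
                f"{a.split}\t{theo}\t{err}\t{';'.join(a.alternatives)}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def to_json(self, path=None) -> str:
        payload = {
            "precursor_mz": self.spectrum.precursor_mz,
            "hypothesis": {
                "class": self.hypothesis.lipid_class.value,
                "total": f"{self.hypothesis.total_carbons}:{self.hypothesis.total_double_bonds}",
            },
            "tolerance_da": self.tolerance,
            "dominant_split": self.dominant_split(),
            "cluster_intensity": self.cluster_intensity(),
            "assignments": [
                {
                    "peak_mz": a.peak_mz,
                    "intensity": a.intensity,
                    "cluster": a.cluster,
                    "fragment": a.fragment,
                    "split": a.split,
                    "theoretical_mz": a.theoretical_mz,
                    "mass_error_da": a.mass_error,
                    "alternatives": list(a.alternatives),
                }
                for a in self.assignments
            ],
        }
        text = json.dumps(payload, indent=2, ensure_ascii=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def annotate_spectrum(spectrum: Spectrum, hypothesis: SpeciesHypothesis,
                      tolerance: float = 0.5) -> AnnotationResult:
    """Assign each centroid to the nearest theoretical fragment within tolerance.

    Ties go to the smaller |mass error|, then the smaller FA carbon count;
    the losing candidates are recorded as alternatives.  Peaks without a
    candidate within tolerance are labeled unassigned.
    """
    theo_precursor = hypothesis.precursor_mz()
    if abs(spectrum.precursor_mz - theo_precursor) > max(tolerance, 0.5):
        raise ValueError(
            f"precursor m/z {spectrum.precursor_mz:.4f} inconsistent with hypothesis "
            f"{hypothesis.lipid_class.value} "
            f"{hypothesis.total_carbons}:{hypothesis.total_double_bonds} "
            f"(theoretical {theo_precursor:.4f})"
        )
    splits = isobaric_splits(hypothesis.lipid_class, hypothesis.total_carbons,
                             hypothesis.total_double_bonds, hypothesis.fa_range)
    # candidate list: (mz, cluster, fragment label, split label, fa carbons)
    candidates: list[tuple[float, str, str, str, int]] = []
    for fa, dfa in splits:
        split = f"{fa.name}/{dfa.name}"
        candidates.append((acylium_mz(fa), FA_CLUSTER, f"acylium {fa.name}", split, fa.carbons))
        candidates.append((diolfa_fragment_mz(dfa), DIOLFA_CLUSTER,
                           f"diolFA_dehydrated {dfa.name}", split, fa.carbons))

    assignments: list[PeakAssignment] = []
    for mz, inten in zip(spectrum.mz, spectrum.intensity):
        within = [c for c in candidates if abs(mz - c[0]) <= tolerance]
        if not within:
            assignments.append(PeakAssignment(float(mz), float(inten), UNASSIGNED))
            continue
        within.sort(key=lambda c: (abs(mz - c[0]), c[4]))
        best = within[0]
        alts = tuple(f"{c[2]} ({c[0]:.4f})" for c in within[1:])
        assignments.append(PeakAssignment(
            peak_mz=float(mz),
            intensity=float(inten),
            cluster=best[1],
            fragment=best[2],
            split=best[3],
            theoretical_mz=best[0],
            mass_error=float(mz - best[0]),
            alternatives=alts,
        ))
    return AnnotationResult(spectrum, hypothesis, tolerance, tuple(assignments))


# ---------------------------------------------------------------------------
# spectrum I/O

def read_mgf(path) -> list[Spectrum]:
    """Read centroided spectra from an MGF file (PEPMASS as precursor)."""
    from pyteomics import mgf

    spectra = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (None,))
            if pepmass[0] is None:
                raise ValueError(f"MGF spectrum without PEPMASS in {path}")
            order = np.argsort(entry["m/z array"])
            spectra.append(Spectrum(
                precursor_mz=float(pepmass[0]),
                mz=np.asarray(entry["m/z array"], dtype=float)[order],
                intensity=np.asarray(entry["intensity array"], dtype=float)[order],
            ))
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path, titles: Sequence[str] | None = None) -> None:
    from pyteomics import mgf

    entries = []
    for i, sp in enumerate(spectra):
        params = {"pepmass": sp.precursor_mz,
                  "title": titles[i] if titles else f"spectrum_{i}"}
        entries.append({"m/z array": sp.mz, "intensity array": sp.intensity,
                        "params": params})
    mgf.write(entries, str(path), file_mode="w")


def read_spectrum_csv(path, precursor_mz: float) -> Spectrum:
    """Read a plain two-column (m/z, intensity) CSV, header optional."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"expected two columns (m/z, intensity) in {path}")
    # tolerate header-less files whose first row parsed as header
    try:
        float(df.columns[0])
        import io as _io
        with open(path) as fh:
            df = pd.read_csv(_io.StringIO(fh.read()), header=None, comment="#")
    except ValueError:
        pass
    mz = df.iloc[:, 0].to_numpy(dtype=float)
    inten = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(mz)
    return Spectrum(precursor_mz, mz[order], inten[order])


def read_mzml(path) -> list[Spectrum]:
    """Read MS2 centroid spectra from an mzML file (optional ingestion path)."""
    from pyteomics import mzml

    spectra = []
    with mzml.read(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            order = np.argsort(entry["m/z array"])
            spectra.append(Spectrum(
                precursor_mz=float(ion["selected ion m/z"]),
                mz=np.asarray(entry["m/z array"], dtype=float)[order],
                intensity=np.asarray(entry["intensity array"], dtype=float)[order],
            ))
    return spectra
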