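"""Synthetic-data generation emulating the sebum MRM measurement structure.

Nothing here is a claim about real sebum: the generator reproduces the
*shape* of the study design — compositional orderings, n = 3 replicate
designs with multiplicative noise, ten-point calibration series, knockout
effect sizes, and cage co-housing cross-contamination — so that every
pipeline stage is testable end to end without instrument data.

Scenarios
---------
``WT``        wild-type-like profile: C16:0 the dominant WmE fatty acid,
              mono-unsaturated diol-FAs dominant in 2α-WdiEs,
              di-unsaturated dominant in 2ω-WdiEs and Chol-OAHFAs.
``Far2KO``    species whose fatty-alcohol/diol chain is very long
              (>= C21) multiplied by 0.12.
``Awat2KO``   WmE and 2ω-WdiE species with long-chain FAs (saturated
              <= C17, mono-unsaturated <= C19) multiplied by per-chain
              factors (C16:1 -> 0.22, C18:1 -> 0.09 by default).

All randomness flows through a single integer seed; identical seeds give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import Spectrum
from .chem import PROTON_MASS, WATER, monoisotopic_mass
from .fragments import acylium_mz, diolfa_fragment_mz
from .quantify import fit_calibration, quantify_external_array
from .species import (
    SEBUM_PRESETS,
    ChainKind,
    ChainMoiety,
    LipidClass,
    LipidSpecies,
    MoietyRange,
    SpeciesGrid,
    enumerate_grid,
)

__all__ = [
    "NoiseModel",
    "ScenarioParams",
    "MixingModel",
    "SCENARIOS",
    "make_truth_profile",
    "simulate_peak_table",
    "make_calibration_series",
    "simulate_cage_mixing",
    "simulate_product_ion_scan",
    "far2_recovery_experiment",
]

SCENARIOS = ("WT", "Far2KO", "Awat2KO")

#: per-class truth totals (pmol per 10 mg hair) for the WT-like template;
#: order-of-magnitude choices, documented in the methods note.
CLASS_TOTALS: Mapping[LipidClass, float] = {
    LipidClass.WME: 2000.0,
    LipidClass.WDIE_2A: 400.0,
    LipidClass.WDIE_2W: 600.0,
    LipidClass.CHOL_OAHFA: 150.0,
    LipidClass.CHOL_E: 3000.0,
}


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: area = slope * amount * LN(cv) + baseline.

    The multiplicative term is a mean-one lognormal with coefficient of
    variation ``cv`` (keeps areas positive, unlike additive Gaussian noise).
    """

    cv: float = 0.2
    baseline: float = 0.0
    response_slope: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclass(frozen=True)
class ScenarioParams:
    """Knockout effect sizes (multiplicative, applied to the WT template)."""

    far2_factor: float = 0.12
    far2_min_chain: int = 21           # very-long-chain threshold for FAl/diol
    awat2_sat_factor: float = 0.15
    awat2_sat_max_carbons: int = 17
    awat2_mono_factors: Mapping[int, float] = field(
        default_factory=lambda: {16: 0.22, 18: 0.09}
    )
    awat2_mono_default_factor: float = 0.15
    awat2_mono_max_carbons: int = 19


DEFAULT_SCENARIO_PARAMS = ScenarioParams()


@dataclass(frozen=True)
class MixingModel:
    """Cage co-housing contamination: observed = (1-α)·self + α·cage-mate mean."""

    alpha: float
    cages: Mapping[str, str]  # sample id -> cage id

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")


def _gauss(c: float, center: float, width: float) -> float:
    return math.exp(-0.5 * ((c - center) / width) ** 2)


# WT-like template weights.  Majors follow the reported abundance orderings;
# everything else gets a small flat floor.
_WME_FA_WEIGHTS = {(16, 0): 1.00, (18, 1): 0.75, (16, 1): 0.60, (17, 0): 0.45,
                   (20, 1): 0.40, (15, 0): 0.30, (18, 0): 0.25, (22, 1): 0.25,
                   (17, 1): 0.20, (14, 0): 0.18}
_WME_FA_FLOOR = 0.08


def _wme_weight(fa: ChainMoiety, fal: ChainMoiety) -> float:
    w_fa = _WME_FA_WEIGHTS.get((fa.carbons, fa.double_bonds), _WME_FA_FLOOR)
    if fal.double_bonds == 0:
        # saturated FAls are bimodal: long-chain C16 peak and a very-long-
        # chain C26 peak (C16-C28 overall)
        w_fal = 0.7 * _gauss(fal.carbons, 16.0, 2.5) + 0.6 * _gauss(fal.carbons, 26.0, 2.5)
    else:
        w_fal = 0.8 * _gauss(fal.carbons, 32.5, 2.0)  # mono-unsat mainly C31-C34
    return w_fa * max(w_fal, 1e-3)


def _even_bonus(carbons: int) -> float:
    return 1.5 if carbons % 2 == 0 else 1.0


def _wdie2a_weight(fa: ChainMoiety, dfa: ChainMoiety) -> float:
    w_fa = {(16, 1): 1.0, (16, 0): 0.9}.get((fa.carbons, fa.double_bonds), 0.05)
    w_sat = {0: 0.55, 1: 1.0, 2: 0.45, 3: 0.02}[dfa.double_bonds]
    return w_fa * w_sat * _gauss(dfa.carbons, 40.0, 2.5) * _even_bonus(dfa.carbons)


def _wdie2w_weight(fa: ChainMoiety, dfa: ChainMoiety) -> float:
    w_fa = {18: 0.5, 20: 1.0, 22: 1.0}.get(fa.carbons, 0.05)
    w_sat = {0: 0.15, 1: 0.35, 2: 1.0, 3: 0.05}[dfa.double_bonds]
    center = {18: 52.0, 20: 54.0, 22: 56.0}.get(fa.carbons, 54.0)
    return w_fa * w_sat * _gauss(dfa.carbons, center, 2.0) * _even_bonus(dfa.carbons)


def _chol_oahfa_weight(oahfa: ChainMoiety) -> float:
    w_sat = {1: 0.15, 2: 1.0, 3: 0.10}[oahfa.double_bonds]
    return w_sat * _gauss(oahfa.carbons, 56.0, 2.0) * _even_bonus(oahfa.carbons)


def _chol_e_weight(fa: ChainMoiety) -> float:
    w_sat = {0: 0.15, 1: 1.0, 2: 0.10}[fa.double_bonds]
    return w_sat * _gauss(fa.carbons, 34.0, 2.5) * _even_bonus(fa.carbons)


def _template_weight(sp: LipidSpecies) -> float:
    cls = sp.lipid_class
    if cls is LipidClass.WME:
        return _wme_weight(*sp.moieties)
    if cls is LipidClass.WDIE_2A:
        return _wdie2a_weight(*sp.moieties)
    if cls is LipidClass.WDIE_2W:
        return _wdie2w_weight(*sp.moieties)
    if cls is LipidClass.CHOL_OAHFA:
        return _chol_oahfa_weight(sp.moieties[0])
    if cls is LipidClass.CHOL_E:
        return _chol_e_weight(sp.moieties[0])
    raise ValueError(f"no WT template for class {cls.value}")


def _scenario_factor(sp: LipidSpecies, scenario: str, p: ScenarioParams) -> float:
    if scenario == "WT":
        return 1.0
    fa = sp.moieties[0]
    if scenario == "Far2KO":
        # chain length of the FAl / diol backbone; for a (FA, diol-FA) WdiE
        # the embedded FA is taken equal to the observed FA (symmetric split)
        if sp.lipid_class is LipidClass.WME:
            chain = sp.moieties[1].carbons
        elif sp.lipid_class in (LipidClass.WDIE_2A, LipidClass.WDIE_2W):
            chain = sp.moieties[1].carbons - fa.carbons
        else:
            return 1.0  # cholesteryl classes carry no FAl/diol
        return p.far2_factor if chain >= p.far2_min_chain else 1.0
    if scenario == "Awat2KO":
        if sp.lipid_class not in (LipidClass.WME, LipidClass.WDIE_2W):
            return 1.0
        if fa.double_bonds == 0 and fa.carbons <= p.awat2_sat_max_carbons:
            return p.awat2_sat_factor
        if fa.double_bonds == 1 and fa.carbons <= p.awat2_mono_max_carbons:
            return p.awat2_mono_factors.get(fa.carbons, p.awat2_mono_default_factor)
        return 1.0
    raise ValueError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")


def make_truth_profile(scenario: str,
                       grids: Sequence[SpeciesGrid] | None = None,
                       seed: int = 0,
                       params: ScenarioParams = DEFAULT_SCENARIO_PARAMS,
                       jitter_cv: float = 0.0,
                       class_totals: Mapping[LipidClass, float] = CLASS_TOTALS,
                       ) -> pd.DataFrame:
    """Ground-truth per-species amounts (pmol per 10 mg hair) for a scenario.

    Knockout scenarios are exact multiplicative modifications of the WT
    template, so effect sizes hold exactly at truth level.  ``jitter_cv``
    adds seeded mouse-to-mouse lognormal variation to the *WT template*
    (before scenario factors) when > 0.

    Columns: compound, class, fa, fa_carbons, fa_double_bonds, partner,
    partner_carbons, partner_double_bonds, amount_pmol, scenario.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")
    if grids is None:
        grids = [SEBUM_PRESETS["WmE"], SEBUM_PRESETS["2α-WdiE"],
                 SEBUM_PRESETS["2ω-WdiE"], SEBUM_PRESETS["Chol-OAHFA"],
                 SEBUM_PRESETS["Chol-E"]]
    rng = np.random.default_rng(seed)
    rows = []
    for grid in grids:
        species = enumerate_grid(grid)
        weights = np.array([_template_weight(sp) for sp in species])
        if jitter_cv > 0:
            sigma = math.sqrt(math.log(1 + jitter_cv**2))
            weights = weights * rng.lognormal(-sigma**2 / 2, sigma, size=weights.size)
        total = class_totals.get(grid.lipid_class, 100.0)
        amounts = total * weights / weights.sum()
        for sp, wt_amount in zip(species, amounts):
            fa = sp.moieties[0]
            partner = sp.moieties[1] if len(sp.moieties) > 1 else None
            rows.append({
                "compound": sp.shorthand,
                "class": sp.lipid_class.value,
                "fa": fa.name,
                "fa_carbons": fa.carbons,
                "fa_double_bonds": fa.double_bonds,
                "partner": partner.name if partner else "",
                "partner_carbons": partner.carbons if partner else 0,
                "partner_double_bonds": partner.double_bonds if partner else 0,
                "amount_pmol": wt_amount * _scenario_factor(sp, scenario, params),
                "scenario": scenario,
            })
    return pd.DataFrame(rows)


def _draw_areas(amounts: np.ndarray, n_replicates: int, noise: NoiseModel,
                rng: np.random.Generator) -> np.ndarray:
    """(n_species, n_replicates) peak areas under the noise model."""
    amounts = np.asarray(amounts, dtype=float)
    if noise.cv > 0:
        sigma = math.sqrt(math.log(1 + noise.cv**2))
        factor = rng.lognormal(-sigma**2 / 2, sigma, size=(amounts.size, n_replicates))
    else:
        factor = np.ones((amounts.size, n_replicates))
    return noise.response_slope * amounts[:, None] * factor + noise.baseline


def simulate_peak_table(truth: pd.DataFrame, n_replicates: int = 3,
                        noise: NoiseModel = NoiseModel(),
                        group: str | None = None,
                        basis: str = "10 mg hair",
                        branched_fraction: float = 0.0) -> pd.DataFrame:
    """Noisy replicate PeakTable for a truth profile.

    With ``branched_fraction`` > 0 every compound is emitted as an LC
    doublet: an early (branched) and a late (straight-chain) peak whose
    areas split the total in that proportion.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    group = group if group is not None else str(truth["scenario"].iloc[0])
    rng = np.random.default_rng(noise.seed)
    areas = _draw_areas(truth["amount_pmol"].to_numpy(), n_replicates, noise, rng)
    rows = []
    for rep in range(n_replicates):
        sample = f"{group}_{rep + 1}"
        for compound, area in zip(truth["compound"], areas[:, rep]):
            if branched_fraction > 0:
                rows.append({"sample": sample, "group": group, "compound": compound,
                             "peak": "early", "area": branched_fraction * area,
                             "basis": basis})
                rows.append({"sample": sample, "group": group, "compound": compound,
                             "peak": "late", "area": (1 - branched_fraction) * area,
                             "basis": basis})
            else:
                rows.append({"sample": sample, "group": group, "compound": compound,
                             "area": area, "basis": basis})
    return pd.DataFrame(rows)


def make_calibration_series(standard: str = "WmE 18:0/22:0",
                            amounts: Sequence[float] | None = None,
                            noise: NoiseModel = NoiseModel(cv=0.05),
                            intercept: float = 0.0) -> pd.DataFrame:
    """A ten-point external-standard series (amount_pmol, area).

    Standards are repeated injections of pure dilutions, so their default
    noise is the technical injection CV (5%), not the biological replicate
    CV of the samples.
    """
    if amounts is None:
        amounts = [2.5 * 2**k for k in range(10)]  # 2.5 ... 1280 pmol
    rng = np.random.default_rng(noise.seed)
    areas = _draw_areas(np.asarray(amounts, dtype=float), 1, noise, rng)[:, 0] + intercept
    return pd.DataFrame({"standard": standard, "amount_pmol": list(amounts),
                         "area": areas})


def simulate_cage_mixing(profiles: pd.DataFrame, mixing: MixingModel) -> pd.DataFrame:
    """Apply cage cross-contamination to per-sample truth profiles.

    ``profiles`` is wide: rows = samples, columns = compounds.  Each sample's
    observed profile is (1 − α)·own + α·mean of its cage-mates, which
    redistributes material within a cage but conserves the cage total.
    """
    missing = [s for s in profiles.index if s not in mixing.cages]
    if missing:
        raise ValueError(f"cage assignment missing for samples: {missing}")
    out = profiles.astype(float).copy()
    if mixing.alpha == 0:
        return out
    for cage in set(mixing.cages[s] for s in profiles.index):
        members = [s for s in profiles.index if mixing.cages[s] == cage]
        if len(members) < 2:
            raise ValueError(
                f"cage {cage!r} has {len(members)} sample(s); mixing needs >= 2"
            )
        block = profiles.loc[members].to_numpy(dtype=float)
        k = len(members)
        mates_mean = (block.sum(axis=0)[None, :] - block) / (k - 1)
        out.loc[members] = (1 - mixing.alpha) * block + mixing.alpha * mates_mean
    return out


def simulate_product_ion_scan(splits: Sequence[tuple[ChainMoiety, ChainMoiety]],
                              weights: Sequence[float] | None = None,
                              intensity_cv: float = 0.0,
                              seed: int = 0,
                              diolfa_channel_ratio: float = 0.8) -> Spectrum:
    """A centroided product-ion scan from known FA / diol-FA splits.

    Every split contributes its acylium and its dehydrated diol-FA fragment;
    intensities are proportional to split weights (diol-FA channel scaled by
    ``diolfa_channel_ratio``) with seeded lognormal noise.  All splits must
    share one precursor m/z within 0.02 Da.
    """
    if weights is None:
        weights = [1.0] * len(splits)
    if len(weights) != len(splits):
        raise ValueError("weights must match splits")
    if not splits:
        return Spectrum(0.0, np.array([]), np.array([]))
    precursors = []
    for fa, dfa in splits:
        if fa.kind is not ChainKind.FA or dfa.kind is not ChainKind.DIOL_FA:
            raise ValueError("each split must be (FA, diol-FA)")
        precursors.append(fa.formula.mass + dfa.formula.mass
                          - monoisotopic_mass(WATER)  # ester-bond water
                          + PROTON_MASS)
    if max(precursors) - min(precursors) > 0.02:
        raise ValueError(
            f"splits are not co-isobaric: precursor m/z span "
            f"{min(precursors):.4f}-{max(precursors):.4f} exceeds 0.02 Da"
        )
    rng = np.random.default_rng(seed)
    peaks = []
    for (fa, dfa), w in zip(splits, weights):
        for mz, scale in ((acylium_mz(fa), 1.0),
                          (diolfa_fragment_mz(dfa), diolfa_channel_ratio)):
            inten = w * scale
            if intensity_cv > 0:
                sigma = math.sqrt(math.log(1 + intensity_cv**2))
                inten *= rng.lognormal(-sigma**2 / 2, sigma)
            peaks.append((mz, inten))
    return Spectrum.from_peaks(float(np.mean(precursors)), peaks)


def far2_recovery_experiment(n_runs: int = 500, seed: int = 0,
                             n_replicates: int = 3, cv: float = 0.2,
                             calibration_cv: float = 0.05,
                             grid: SpeciesGrid | None = None,
                             params: ScenarioParams = DEFAULT_SCENARIO_PARAMS,
                             ) -> pd.DataFrame:
    """Monte-Carlo recovery of the Far2-KO very-long-chain-FAl effect.

    Per run: simulate WT and Far2-KO WmE peak tables (n replicates each,
    biological CV ``cv``) plus a ten-point calibration series (technical
    CV ``calibration_cv``), fit the calibration with the 1/x weighting
    appropriate for its three-decade amount span, quantify externally, and
    record the recovered total WT WmE amount and the KO
    percent-of-reference for the very-long-chain-FAl aggregate (truth:
    ``params.far2_factor``).

    The default grid is the C16:0-FA WmE family (C16-C40 FAls), the same
    single-FA panel design the knockout analysis profiles, which keeps the
    aggregated species at quantifiable amounts.

    Returns one row per run: run, percent_vlc, recovered_wt_total,
    truth_wt_total.
    """
    if grid is None:
        grid = SpeciesGrid(LipidClass.WME, (
            MoietyRange(ChainKind.FA, (16, 16), (0,)),
            MoietyRange(ChainKind.FAL, (16, 40), (0, 1)),
        ))
    truth_wt = make_truth_profile("WT", grids=[grid], params=params)
    truth_ko = make_truth_profile("Far2KO", grids=[grid], params=params)
    vlc = (truth_wt["partner_carbons"] >= params.far2_min_chain).to_numpy()
    wt_amounts = truth_wt["amount_pmol"].to_numpy()
    ko_amounts = truth_ko["amount_pmol"].to_numpy()
    truth_total = float(wt_amounts.sum())

    base = np.random.SeedSequence(seed)
    rows = []
    for run, child in enumerate(base.spawn(n_runs)):
        rng = np.random.default_rng(child)
        noise = NoiseModel(cv=cv)
        cal_noise = NoiseModel(cv=calibration_cv)
        cal = _draw_areas(np.array([2.5 * 2**k for k in range(10)]), 1, cal_noise, rng)[:, 0]
        curve = fit_calibration([2.5 * 2**k for k in range(10)], cal, weighting="1/x")
        areas_wt = _draw_areas(wt_amounts, n_replicates, noise, rng)
        areas_ko = _draw_areas(ko_amounts, n_replicates, noise, rng)
        q_wt = quantify_external_array(areas_wt, curve)  # (species, reps)
        q_ko = quantify_external_array(areas_ko, curve)
        wt_vlc = q_wt[vlc].sum(axis=0).mean()
        ko_vlc = q_ko[vlc].sum(axis=0).mean()
        rows.append({
            "run": run,
            "percent_vlc": 100.0 * ko_vlc / wt_vlc,
            "recovered_wt_total": float(q_wt.sum(axis=0).mean()),
            "truth_wt_total": truth_total,
        })
    return pd.DataFrame(rows)
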