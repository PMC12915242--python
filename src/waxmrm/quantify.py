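"""Peak areas -> amounts -> compositional summaries -> group statistics.

Tables are plain pandas DataFrames with documented columns.

PeakTable columns
    sample, group, compound, area [, peak ("early"/"late"), dilution, basis]
    ``early`` LC doublet peaks are iso/anteiso-branched chains, ``late``
    peaks straight chains; they are summed per compound with the branched
    fraction retained as an annotation.

QuantTable columns
    sample, group, compound, amount_pmol, mode ("external"/"internal"),
    basis [, flags]

Quantification is deliberately semi-quantitative: external calibration is
unweighted OLS (optionally 1/x-weighted) and internal-standard calculation
uses a unit response factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "merge_lc_doublets",
    "fit_calibration",
    "quantify_external",
    "quantify_external_array",
    "quantify_internal",
    "quantify_table",
    "composition_fractions",
    "compare_groups",
]

PEAKTABLE_COLUMNS = ["sample", "group", "compound", "area"]


@dataclass(frozen=True)
class CalibrationCurve:
    """An OLS line area = slope * amount + intercept over a standard series."""

    standard: str
    amounts: np.ndarray
    areas: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]  # amount bounds of the linear run

    @property
    def area_range(self) -> tuple[float, float]:
        return float(np.min(self.areas)), float(np.max(self.areas))


def merge_lc_doublets(table: pd.DataFrame) -> pd.DataFrame:
    """Sum early/late LC doublet areas per (sample, compound).

    Adds a ``branched_fraction`` column (early-peak share of the total;
    NaN when the merged area is zero).  Tables without a ``peak`` column
    pass through with ``branched_fraction`` NaN.
    """
    df = table.copy()
    if "peak" not in df.columns:
        df["branched_fraction"] = np.nan
        return df
    keys = [c for c in df.columns if c not in ("area", "peak")]
    early = df[df["peak"] == "early"].groupby(keys, dropna=False)["area"].sum()
    total = df.groupby(keys, dropna=False)["area"].sum()
    merged = total.reset_index()
    early_aligned = early.reindex(total.index, fill_value=0.0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["branched_fraction"] = np.where(
            total.to_numpy() > 0, early_aligned / total.to_numpy(), np.nan
        )
    return merged


def fit_calibration(amounts: Sequence[float], areas: Sequence[float],
                    standard: str = "", weighting: str | None = None,
                    linear_rel_tol: float = 0.15) -> CalibrationCurve:
    """Fit an external calibration line and locate its linear range.

    ``weighting=None`` is ordinary least squares; ``"1/x"`` weights each
    point by 1/amount.  The linear range is the amount span of the longest
    contiguous run of points whose relative residual is within
    ``linear_rel_tol`` of the fitted line.
    """
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("calibration needs >= 2 distinct amounts")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if weighting is None:
        fit = stats.linregress(x, y)
        slope, intercept, r = fit.slope, fit.intercept, fit.rvalue
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting needs strictly positive amounts")
        w = 1.0 / x
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        yhat = slope * x + intercept
        ybar = np.average(y, weights=w)
        r2 = 1 - np.sum(w * (y - yhat) ** 2) / np.sum(w * (y - ybar) ** 2)
        r = np.sqrt(max(r2, 0.0))
    else:
        raise ValueError(f"unknown weighting {weighting!r} (use None or '1/x')")

    pred = slope * x + intercept
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(y - pred) / np.where(np.abs(pred) > 0, np.abs(pred), np.nan)
    ok = np.nan_to_num(rel, nan=np.inf) <= linear_rel_tol
    best_lo = best_hi = 0  # [lo, hi) of the longest True run
    run_lo = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and run_lo is None:
            run_lo = i
        elif not flag and run_lo is not None:
            if i - run_lo > best_hi - best_lo:
                best_lo, best_hi = run_lo, i
            run_lo = None
    if best_hi > best_lo:
        lin = (float(x[best_lo]), float(x[best_hi - 1]))
    else:
        lin = (float("nan"), float("nan"))
    return CalibrationCurve(standard, x, y, float(slope), float(intercept),
                            float(r**2), lin)


def quantify_external(area: float, curve: CalibrationCurve,
                      dilution: float = 1.0) -> tuple[float, tuple[str, ...]]:
    """amount = dilution * (area - intercept) / slope, clipped at zero.

    Returns (pmol, flags); flags mark negative-amount clipping and areas
    outside the calibrated range (extrapolation).
    """
    if curve.slope <= 0:
        raise ValueError(f"calibration slope must be > 0, got {curve.slope}")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    flags: list[str] = []
    lo, hi = curve.area_range
    if not (lo <= area <= hi):
        flags.append("extrapolated")
    amount = dilution * (area - curve.intercept) / curve.slope
    if amount < 0:
        flags.append("negative_clipped")
        amount = 0.0
    return amount, tuple(flags)


def quantify_external_array(areas, curve: CalibrationCurve,
                            dilution: float = 1.0) -> np.ndarray:
    """Vectorized :func:`quantify_external` (clipped at zero, no flags)."""
    if curve.slope <= 0:
        raise ValueError(f"calibration slope must be > 0, got {curve.slope}")
    amounts = dilution * (np.asarray(areas, dtype=float) - curve.intercept) / curve.slope
    return np.clip(amounts, 0.0, None)


def quantify_internal(analyte_area: float, is_area: float,
                      is_amount_pmol: float) -> float:
    """Single-point internal-standard amount with unit response factor."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be > 0 (failed spike?)")
    if analyte_area < 0:
        raise ValueError("analyte area must be >= 0")
    return (analyte_area / is_area) * is_amount_pmol


def quantify_table(peak_table: pd.DataFrame,
                   curves: Mapping[str, CalibrationCurve] | CalibrationCurve,
                   default_dilution: float = 1.0) -> pd.DataFrame:
    """Externally quantify a whole PeakTable.

    ``curves`` maps compound shorthand to its calibration curve; a single
    curve is applied to every compound (the semi-quantitative class-standard
    case).  Returns a QuantTable.
    """
    df = merge_lc_doublets(peak_table)
    rows = []
    for rec in df.itertuples(index=False):
        rec_d = rec._asdict()
        if isinstance(curves, CalibrationCurve):
            curve = curves
        else:
            try:
                curve = curves[rec_d["compound"]]
            except KeyError:
                raise ValueError(f"no calibration curve for {rec_d['compound']!r}") from None
        dilution = float(rec_d.get("dilution", default_dilution) or default_dilution)
        amount, flags = quantify_external(rec_d["area"], curve, dilution)
        rows.append({
            "sample": rec_d["sample"],
            "group": rec_d.get("group", ""),
            "compound": rec_d["compound"],
            "amount_pmol": amount,
            "mode": "external",
            "basis": rec_d.get("basis", ""),
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)


def composition_fractions(quant: pd.DataFrame, group_by: str = "compound",
                          display_floor: float = 0.0) -> pd.Series:
    """Per-category fractions of summed amounts (a pie-chart profile).

    ``group_by`` is a QuantTable column; categories whose fraction falls
    below ``display_floor`` are pooled as ``"other"``.  Fractions sum to 1.
    """
    if group_by not in quant.columns:
        raise ValueError(f"no column {group_by!r} to group by")
    totals = quant.groupby(group_by)["amount_pmol"].sum()
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("all amounts are zero in the grouping scope")
    frac = totals / grand
    if display_floor > 0:
        small = frac[frac < display_floor]
        if len(small):
            frac = frac[frac >= display_floor]
            frac.loc["other"] = float(small.sum())
    return frac.sort_index()


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_groups(quant: pd.DataFrame, reference: str,
                   by: str = "compound") -> pd.DataFrame:
    """Group comparison per compound/category.

    Two groups: two-sided Welch's t test.  More than two: Tukey's HSD over
    all pairs.  Reports group means/SDs, percent-of-reference
    (100 x mean(test)/mean(reference)) and significance stars at 0.05 (*)
    and 0.01 (**), mirroring the usual figure convention.  Groups with
    fewer than two replicates skip the test (with a warning) but still
    report means.
    """
    groups = sorted(quant["group"].unique())
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in table ({groups})")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    rows = []
    for category, sub in quant.groupby(by):
        per_group = {
            g: sub.loc[sub["group"] == g, "amount_pmol"].to_numpy(dtype=float)
            for g in groups
        }
        ref_mean = float(np.mean(per_group[reference])) if len(per_group[reference]) else np.nan
        testable = all(len(v) >= 2 for v in per_group.values())
        if not testable:
            warnings.warn(
                f"{category}: a group has < 2 replicates; test skipped", stacklevel=2
            )
        if len(groups) == 2:
            g_test = next(g for g in groups if g != reference)
            stat = pval = np.nan
            if testable:
                stat, pval = _welch(per_group[g_test], per_group[reference])
            rows.append(_comparison_row(category, "Welch t", g_test, reference,
                                        per_group, ref_mean, stat, pval))
        else:
            tukey = None
            if testable:
                from statsmodels.stats.multicomp import pairwise_tukeyhsd
                values = sub["amount_pmol"].to_numpy(dtype=float)
                labels = sub["group"].to_numpy()
                tukey = pairwise_tukeyhsd(values, labels, alpha=0.05)
                summary = pd.DataFrame(tukey.summary().data[1:],
                                       columns=tukey.summary().data[0])
            for g1, g2 in [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]:
                stat = pval = np.nan
                if tukey is not None:
                    mask = ((summary["group1"] == g1) & (summary["group2"] == g2)) | \
                           ((summary["group1"] == g2) & (summary["group2"] == g1))
                    hit = summary[mask]
                    if len(hit):
                        pval = float(hit["p-adj"].iloc[0])
                        stat = float(hit["meandiff"].iloc[0])
                test_g = g2 if g1 == reference else g1
                rows.append(_comparison_row(category, "Tukey HSD", test_g,
                                            g1 if test_g == g2 else g2,
                                            per_group, ref_mean, stat, pval,
                                            pair=(g1, g2)))
    return pd.DataFrame(rows)


def _comparison_row(category, test_name, test_group, other_group, per_group,
                    ref_mean, stat, pval, pair=None) -> dict:
    def _mean(v):
        return float(np.mean(v)) if len(v) else np.nan

    def _sd(v):
        return float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan

    test_mean = _mean(per_group[test_group])
    pct = 100.0 * test_mean / ref_mean if ref_mean and np.isfinite(ref_mean) else np.nan
    sig = ""
    if np.isfinite(pval):
        sig = "**" if pval < 0.01 else ("*" if pval < 0.05 else "")
    row = {
        "category": category,
        "test": test_name,
        "group": test_group,
        "versus": other_group,
        "mean": test_mean,
        "sd": _sd(per_group[test_group]),
        "versus_mean": _mean(per_group[other_group]),
        "versus_sd": _sd(per_group[other_group]),
        "statistic": stat,
        "p_value": pval,
        "percent_of_reference": pct,
        "significance": sig,
    }
    if pair is not None:
        row["pair"] = f"{pair[0]} vs {pair[1]}"
    return row
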