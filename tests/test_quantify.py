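import numpy as np
import pandas as pd
import pytest
from scipy import stats

from waxmrm.quantify import (
    CalibrationCurve,
    compare_groups,
    composition_fractions,
    fit_calibration,
    merge_lc_doublets,
    quantify_external,
    quantify_external_array,
    quantify_internal,
    quantify_table,
)


def _curve(slope=2.0, intercept=0.0, amounts=(0.0, 1000.0)):
    x = np.asarray(amounts, dtype=float)
    return CalibrationCurve("std", x, slope * x + intercept, slope, intercept,
                            1.0, (float(x.min()), float(x.max())))


class TestDoublets:
    def test_early_late_merge(self):
        table = pd.DataFrame({
            "sample": ["s1", "s1"], "group": ["WT", "WT"],
            "compound": ["WmE 16:0/26:0"] * 2,
            "peak": ["early", "late"], "area": [30.0, 70.0],
        })
        merged = merge_lc_doublets(table)
        assert len(merged) == 1
        assert merged["area"].iloc[0] == 100.0
        assert merged["branched_fraction"].iloc[0] == pytest.approx(0.30)

    def test_single_peak_table_passthrough(self):
        table = pd.DataFrame({"sample": ["s1"], "group": ["WT"],
                              "compound": ["x"], "area": [5.0]})
        merged = merge_lc_doublets(table)
        assert merged["area"].iloc[0] == 5.0
        assert np.isnan(merged["branched_fraction"].iloc[0])

    def test_zero_doublet_flagged_undefined(self):
        table = pd.DataFrame({
            "sample": ["s1", "s1"], "group": ["WT", "WT"], "compound": ["x", "x"],
            "peak": ["early", "late"], "area": [0.0, 0.0],
        })
        merged = merge_lc_doublets(table)
        assert merged["area"].iloc[0] == 0.0
        assert np.isnan(merged["branched_fraction"].iloc[0])


class TestCalibration:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(1, 11, dtype=float)
        curve = fit_calibration(x, 2.0 * x)
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-10)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.linear_range == (1.0, 10.0)

    def test_intercept_recovered(self):
        x = np.arange(1, 11, dtype=float)
        curve = fit_calibration(x, 3.0 * x + 5.0)
        assert curve.intercept == pytest.approx(5.0, abs=1e-10)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(42)
        x = np.arange(1, 11, dtype=float)
        y = 2.0 * x + rng.normal(0, 0.5, size=x.size)
        curve = fit_calibration(x, y)
        se = stats.linregress(x, y).stderr
        assert abs(curve.slope - 2.0) <= 3 * se

    def test_identical_amounts_error(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_one_over_x_weighting(self):
        x = np.array([2.5 * 2**k for k in range(10)])
        curve = fit_calibration(x, 2.0 * x, weighting="1/x")
        assert curve.slope == pytest.approx(2.0, abs=1e-9)
        with pytest.raises(ValueError, match="weighting"):
            fit_calibration(x, 2.0 * x, weighting="1/x2")


class TestExternalQuantification:
    def test_basic_and_dilution(self):
        amount, flags = quantify_external(200.0, _curve(), dilution=1.0)
        assert amount == 100.0 and flags == ()
        amount, _ = quantify_external(200.0, _curve(), dilution=50.0)
        assert amount == 5000.0  # mirrors a 50-fold cholesteryl-ester dilution

    def test_negative_clipped_and_flagged(self):
        amount, flags = quantify_external(1.0, _curve(intercept=5.0))
        assert amount == 0.0
        assert "negative_clipped" in flags

    def test_out_of_range_flagged(self):
        _, flags = quantify_external(99999.0, _curve())
        assert "extrapolated" in flags

    def test_nonpositive_slope_rejected(self):
        bad = CalibrationCurve("s", np.array([0.0, 1.0]), np.array([0.0, -1.0]),
                               -1.0, 0.0, 1.0, (0.0, 1.0))
        with pytest.raises(ValueError, match="slope"):
            quantify_external(10.0, bad)

    def test_linearity_inverts_the_line(self):
        curve = _curve(slope=3.0, intercept=7.0)
        x = np.linspace(0, 500, 11)
        recovered = quantify_external_array(3.0 * x + 7.0, curve)
        np.testing.assert_allclose(recovered, x, atol=1e-10)


class TestInternalQuantification:
    def test_unit_response(self):
        assert quantify_internal(1000.0, 1000.0, 250.0) == 250.0
        assert quantify_internal(0.0, 1000.0, 250.0) == 0.0
        assert quantify_internal(2000.0, 1000.0, 1000.0) == 2000.0

    def test_failed_spike_rejected(self):
        with pytest.raises(ValueError, match="spike"):
            quantify_internal(100.0, 0.0, 250.0)


class TestComposition:
    def test_even_split(self):
        quant = pd.DataFrame({"compound": ["A", "B"], "amount_pmol": [50.0, 50.0]})
        frac = composition_fractions(quant)
        assert frac["A"] == 0.5 and frac["B"] == 0.5

    def test_single_category(self):
        quant = pd.DataFrame({"compound": ["X"], "amount_pmol": [7.0]})
        assert composition_fractions(quant)["X"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        quant = pd.DataFrame({"compound": [f"c{i}" for i in range(30)],
                              "amount_pmol": rng.uniform(0, 10, 30)})
        assert composition_fractions(quant).sum() == pytest.approx(1.0, abs=1e-9)
        floored = composition_fractions(quant, display_floor=0.05)
        assert floored.sum() == pytest.approx(1.0, abs=1e-9)
        assert "other" in floored.index

    def test_all_zero_scope_errors(self):
        quant = pd.DataFrame({"compound": ["A"], "amount_pmol": [0.0]})
        with pytest.raises(ValueError, match="zero"):
            composition_fractions(quant)


def _quant(groups_amounts: dict, compound="X") -> pd.DataFrame:
    rows = []
    for g, amounts in groups_amounts.items():
        for i, a in enumerate(amounts):
            rows.append({"sample": f"{g}_{i}", "group": g,
                         "compound": compound, "amount_pmol": a})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_give_null_result(self):
        quant = _quant({"WT": [1.0, 2.0, 3.0], "KO": [1.0, 2.0, 3.0]})
        row = compare_groups(quant, reference="WT").iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0, abs=1e-12)
        assert row["percent_of_reference"] == pytest.approx(100.0)
        assert row["significance"] == ""

    def test_welch_equals_student_for_equal_n_equal_variance(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 5.5]  # same spread
        quant = _quant({"WT": a, "KO": b})
        row = compare_groups(quant, reference="WT").iloc[0]
        student = stats.ttest_ind(b, a, equal_var=True)
        assert row["statistic"] == pytest.approx(student.statistic, abs=1e-12)
        assert row["p_value"] == pytest.approx(student.pvalue, abs=1e-12)

    def test_clear_difference_is_starred(self):
        quant = _quant({"WT": [100.0, 101.0, 99.0], "KO": [10.0, 11.0, 9.0]})
        row = compare_groups(quant, reference="WT").iloc[0]
        assert row["significance"] == "**"
        assert row["percent_of_reference"] == pytest.approx(10.0, rel=1e-3)

    def test_three_groups_use_tukey(self):
        quant = _quant({"WT": [100.0, 101.0, 99.0],
                        "KO1": [10.0, 11.0, 9.0],
                        "KO2": [99.0, 100.0, 101.0]})
        report = compare_groups(quant, reference="WT")
        assert set(report["test"]) == {"Tukey HSD"}
        assert len(report) == 3  # all pairs
        sig_pairs = set(report.loc[report["significance"] != "", "pair"])
        assert any("KO1" in p for p in sig_pairs)

    def test_single_replicate_skips_test_with_warning(self):
        quant = _quant({"WT": [1.0, 2.0], "KO": [5.0]})
        with pytest.warns(UserWarning, match="replicates"):
            report = compare_groups(quant, reference="WT")
        assert np.isnan(report["p_value"].iloc[0])
        assert report["mean"].iloc[0] == 5.0

    def test_power_for_large_fold_change(self):
        """An 8.3x difference at CV 20%, n=3, is detected in >=90% of runs."""
        rng = np.random.default_rng(2024)
        n_runs = 1000
        sigma = np.sqrt(np.log(1 + 0.2**2))
        wt = rng.lognormal(np.log(8.3), sigma, size=(n_runs, 3))
        ko = rng.lognormal(0.0, sigma, size=(n_runs, 3))
        p = stats.ttest_ind(wt, ko, axis=1, equal_var=False).pvalue
        assert (p < 0.05).mean() >= 0.90

    def test_welch_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(7)

        def perm_p(a, b, n=10000):
            pooled = np.concatenate([a, b])
            observed = abs(np.mean(a) - np.mean(b))
            count = 0
            for _ in range(n):
                perm = rng.permutation(pooled)
                if abs(perm[:len(a)].mean() - perm[len(a):].mean()) >= observed - 1e-12:
                    count += 1
            return count / n

        separated = ([100.0, 102.0, 98.0, 101.0], [10.0, 12.0, 9.0, 11.0])
        null = ([10.0, 12.0, 9.0, 11.0], [11.0, 9.5, 12.5, 10.0])
        for a, b, expect_reject in [(*separated, True), (*null, False)]:
            welch_p = stats.ttest_ind(a, b, equal_var=False).pvalue
            assert (welch_p < 0.05) == expect_reject
            assert (perm_p(np.array(a), np.array(b)) < 0.05) == expect_reject


def test_scale_equivariance():
    """Scaling all areas by c scales amounts by c, fractions unchanged."""
    peaks = pd.DataFrame({
        "sample": ["s1"] * 3, "group": ["WT"] * 3,
        "compound": ["A", "B", "C"], "area": [10.0, 30.0, 60.0],
    })
    curve = _curve(slope=2.0, intercept=0.0)
    q1 = quantify_table(peaks, curve)
    peaks2 = peaks.assign(area=peaks["area"] * 7.0)
    q2 = quantify_table(peaks2, curve)
    np.testing.assert_allclose(q2["amount_pmol"], 7.0 * q1["amount_pmol"])
    f1 = composition_fractions(q1)
    f2 = composition_fractions(q2)
    pd.testing.assert_series_equal(f1, f2)
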