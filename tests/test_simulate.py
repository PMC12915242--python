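import numpy as np
import pandas as pd
import pytest

from waxmrm.annotate import SpeciesHypothesis, annotate_spectrum
from waxmrm.quantify import fit_calibration
from waxmrm.simulate import (
    MixingModel,
    NoiseModel,
    ScenarioParams,
    far2_recovery_experiment,
    make_calibration_series,
    make_truth_profile,
    simulate_cage_mixing,
    simulate_peak_table,
    simulate_product_ion_scan,
)
from waxmrm.species import ChainKind, ChainMoiety, LipidClass, MoietyRange


class TestTruthProfiles:
    def test_wt_c16_0_is_dominant_wme_fa(self):
        truth = make_truth_profile("WT")
        wme = truth[truth["class"] == "WmE"]
        by_fa = wme.groupby("fa")["amount_pmol"].sum()
        assert by_fa.idxmax() == "16:0"

    def test_wt_saturation_orderings(self):
        truth = make_truth_profile("WT")
        w2a = truth[truth["class"] == "2α-WdiE"]
        by_db = w2a.groupby("partner_double_bonds")["amount_pmol"].sum()
        assert by_db.idxmax() == 1  # mono-unsaturated diol-FAs dominate 2α
        w2w = truth[truth["class"] == "2ω-WdiE"]
        assert w2w.groupby("partner_double_bonds")["amount_pmol"].sum().idxmax() == 2
        oahfa = truth[truth["class"] == "Chol-OAHFA"]
        assert oahfa.groupby("fa_double_bonds")["amount_pmol"].sum().idxmax() == 2

    def test_far2_vlc_ratio_exact_at_truth_level(self):
        wt = make_truth_profile("WT")
        ko = make_truth_profile("Far2KO")
        wme = wt["class"] == "WmE"
        vlc = wme & (wt["partner_carbons"] >= 21)
        ratio = ko.loc[vlc, "amount_pmol"].sum() / wt.loc[vlc, "amount_pmol"].sum()
        assert ratio == pytest.approx(0.12, abs=1e-12)
        # long-chain FAl species untouched
        lc = wme & (wt["partner_carbons"] < 21)
        pd.testing.assert_series_equal(ko.loc[lc, "amount_pmol"],
                                       wt.loc[lc, "amount_pmol"])

    def test_far2_factor_zero_removes_vlc_species(self):
        ko = make_truth_profile("Far2KO", params=ScenarioParams(far2_factor=0.0))
        vlc = (ko["class"] == "WmE") & (ko["partner_carbons"] >= 21)
        assert (ko.loc[vlc, "amount_pmol"] == 0).all()

    def test_awat2_reduces_long_chain_fa_species(self):
        wt = make_truth_profile("WT")
        ko = make_truth_profile("Awat2KO")
        w2w = wt["class"] == "2ω-WdiE"
        c18 = w2w & (wt["fa"] == "18:1")
        ratio_18 = ko.loc[c18, "amount_pmol"].sum() / wt.loc[c18, "amount_pmol"].sum()
        assert ratio_18 == pytest.approx(0.09, abs=1e-12)
        c20 = w2w & (wt["fa"] == "20:1")
        pd.testing.assert_series_equal(ko.loc[c20, "amount_pmol"],
                                       wt.loc[c20, "amount_pmol"])

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            make_truth_profile("Elovl4KO")

    def test_seeded_jitter_is_deterministic(self):
        a = make_truth_profile("WT", seed=3, jitter_cv=0.1)
        b = make_truth_profile("WT", seed=3, jitter_cv=0.1)
        pd.testing.assert_frame_equal(a, b)
        c = make_truth_profile("WT", seed=4, jitter_cv=0.1)
        assert not np.allclose(a["amount_pmol"], c["amount_pmol"])


class TestPeakTables:
    def test_noise_free_areas_are_linear(self):
        truth = make_truth_profile("WT")
        table = simulate_peak_table(truth, n_replicates=2,
                                    noise=NoiseModel(cv=0.0, baseline=0.0,
                                                     response_slope=2.0))
        merged = table[table["sample"] == "WT_1"].set_index("compound")["area"]
        expected = truth.set_index("compound")["amount_pmol"] * 2.0
        np.testing.assert_allclose(merged[expected.index], expected, rtol=1e-12)

    def test_same_seed_identical_tables(self):
        truth = make_truth_profile("WT")
        a = simulate_peak_table(truth, noise=NoiseModel(seed=11))
        b = simulate_peak_table(truth, noise=NoiseModel(seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_branched_doublets_split_area(self):
        truth = make_truth_profile("WT")
        table = simulate_peak_table(truth, n_replicates=1,
                                    noise=NoiseModel(cv=0.0),
                                    branched_fraction=0.3)
        one = table[table["compound"] == truth["compound"].iloc[0]]
        early = one.loc[one["peak"] == "early", "area"].iloc[0]
        late = one.loc[one["peak"] == "late", "area"].iloc[0]
        assert early / (early + late) == pytest.approx(0.3)


class TestCageMixing:
    def _profiles(self):
        return pd.DataFrame({"WmE 18:1/26:0": [100.0, 0.0]},
                            index=["WT_1", "KO_1"])

    def test_alpha_zero_is_identity(self):
        prof = self._profiles()
        mixed = simulate_cage_mixing(prof, MixingModel(0.0, {"WT_1": "c", "KO_1": "c"}))
        pd.testing.assert_frame_equal(mixed, prof)

    def test_cohoused_ko_appears_at_half_of_wt(self):
        mixed = simulate_cage_mixing(self._profiles(),
                                     MixingModel(0.5, {"WT_1": "c", "KO_1": "c"}))
        assert mixed.loc["KO_1"].iloc[0] == pytest.approx(50.0)

    def test_cage_totals_conserved(self):
        rng = np.random.default_rng(5)
        prof = pd.DataFrame(rng.uniform(0, 100, size=(6, 4)),
                            index=[f"m{i}" for i in range(6)],
                            columns=list("ABCD"))
        cages = {f"m{i}": ("c1" if i < 3 else "c2") for i in range(6)}
        mixed = simulate_cage_mixing(prof, MixingModel(0.37, cages))
        for cage in ("c1", "c2"):
            members = [s for s in prof.index if cages[s] == cage]
            np.testing.assert_allclose(mixed.loc[members].sum(),
                                       prof.loc[members].sum(), atol=1e-9)

    def test_separation_sweep_converges_to_truth(self):
        prof = self._profiles()
        cages = {"WT_1": "c", "KO_1": "c"}
        ratios = []
        for alpha in (0.5, 0.3, 0.1, 0.0):
            mixed = simulate_cage_mixing(prof, MixingModel(alpha, cages))
            ratios.append(mixed.loc["KO_1"].iloc[0] / mixed.loc["WT_1"].iloc[0])
        assert ratios == sorted(ratios, reverse=True)
        assert ratios[-1] == 0.0

    def test_singleton_cage_rejected(self):
        with pytest.raises(ValueError, match="cage"):
            simulate_cage_mixing(self._profiles(),
                                 MixingModel(0.5, {"WT_1": "a", "KO_1": "b"}))

    def test_missing_assignment_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            simulate_cage_mixing(self._profiles(), MixingModel(0.5, {"WT_1": "a"}))


class TestProductIonScan:
    def test_single_split_two_exact_peaks(self):
        splits = [(ChainMoiety(ChainKind.FA, 16, 1),
                   ChainMoiety(ChainKind.DIOL_FA, 40, 1))]
        scan = simulate_product_ion_scan(splits)
        assert len(scan) == 2
        np.testing.assert_allclose(scan.mz, [237.2213, 589.5918], atol=1e-3)

    def test_zero_splits_empty_spectrum(self):
        scan = simulate_product_ion_scan([])
        assert len(scan) == 0

    def test_non_coisobaric_splits_rejected(self):
        splits = [(ChainMoiety(ChainKind.FA, 16, 1), ChainMoiety(ChainKind.DIOL_FA, 40, 1)),
                  (ChainMoiety(ChainKind.FA, 18, 1), ChainMoiety(ChainKind.DIOL_FA, 40, 1))]
        with pytest.raises(ValueError, match="co-isobaric"):
            simulate_product_ion_scan(splits)

    def test_equal_weights_recovered_by_annotation(self):
        splits = [(ChainMoiety(ChainKind.FA, c, 1),
                   ChainMoiety(ChainKind.DIOL_FA, 74 - c, 2)) for c in (18, 20, 22)]
        scan = simulate_product_ion_scan(splits, intensity_cv=0.05, seed=9)
        assert len(scan) == 6
        hyp = SpeciesHypothesis(LipidClass.WDIE_2W, 74, 3,
                                MoietyRange(ChainKind.FA, (16, 24), (1,)))
        res = annotate_spectrum(scan, hyp, tolerance=0.3)
        assert res.recovered_splits() == {"18:1/56:2", "20:1/54:2", "22:1/52:2"}

    def test_seed_determinism(self):
        splits = [(ChainMoiety(ChainKind.FA, 20, 1),
                   ChainMoiety(ChainKind.DIOL_FA, 54, 2))]
        a = simulate_product_ion_scan(splits, intensity_cv=0.2, seed=3)
        b = simulate_product_ion_scan(splits, intensity_cv=0.2, seed=3)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestCalibrationSeries:
    def test_ten_points_by_default(self):
        cal = make_calibration_series(noise=NoiseModel(cv=0.0))
        assert len(cal) == 10
        curve = fit_calibration(cal["amount_pmol"], cal["area"])
        assert curve.slope == pytest.approx(2.0, abs=1e-9)


def test_recovery_experiment_smoke():
    df = far2_recovery_experiment(n_runs=50, seed=123)
    assert len(df) == 50
    assert ((df["percent_vlc"] > 5) & (df["percent_vlc"] < 25)).mean() > 0.9
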