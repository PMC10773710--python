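"""Tests for profile descriptives, VI ranking, sensitive-leaf screening
and linear inversion."""

import numpy as np
import pandas as pd
import pytest

from canopyspad import metrics, reference
from canopyspad.indices import build_vi_table
from canopyspad.inversion import (
    StageDataset,
    StageInversionModel,
    compare_models,
    describe_profiles,
    find_sensitive_leaf,
    fit_inversion,
    predict_spad_map,
    rank_vis,
)
from canopyspad.lorentz import LeafSPADProfile


def _profile(positions, spad, **meta):
    defaults = dict(plot_id="p1", stage="V6", n_treatment="N0", variety="C01")
    defaults.update(meta)
    return LeafSPADProfile(positions=tuple(positions), spad=tuple(spad), **defaults)


def _stage_dataset(profiles, reflectance, stage):
    vi = build_vi_table([r for r in reflectance if r.stage == stage], stage)
    return StageDataset.from_campaign(profiles, vi, stage)


class TestDescribe:
    def test_noiseless_v6_peaks_at_generating_position(self, noiseless_campaign):
        _, profiles, _, truth = noiseless_campaign
        summary = describe_profiles(profiles)
        row = summary.loc[("V6", "N0")]
        assert row["peak_position"] == truth.params["N0"]["V6"].n_m
        assert bool(row["bell_shaped"])

    def test_monotone_profile_is_not_bell_shaped(self):
        prof = _profile([1, 2, 3, 4], [10.0, 20.0, 30.0, 40.0])
        summary = describe_profiles([prof])
        assert not bool(summary.loc[("V6", "N0"), "bell_shaped"])

    def test_duplicated_plot_leaves_summary_unchanged(self):
        prof = _profile([1, 2, 3, 4], [20.0, 35.0, 30.0, 25.0])
        twin = _profile([1, 2, 3, 4], [20.0, 35.0, 30.0, 25.0], plot_id="p2")
        single = describe_profiles([prof])
        double = describe_profiles([prof, twin])
        assert double.loc[("V6", "N0"), "peak_position"] == \
            single.loc[("V6", "N0"), "peak_position"]
        assert double.loc[("V6", "N0"), "canopy_spad"] == pytest.approx(
            single.loc[("V6", "N0"), "canopy_spad"]
        )


class TestRanking:
    def test_red_edge_family_tops_the_ranking(self):
        # CCCI/NDRE are constructed from the canopy-linked contrast and
        # must occupy the top ranks; only other red-edge-driven indices
        # (e.g. mTVI, which also reads the contrast through Rre) may sit
        # between them — nuisance-band indices may not displace them.
        from canopyspad.synthetic import CampaignConfig, generate_campaign

        top_hits = 0
        for rep in range(100):
            cfg = CampaignConfig(seed=7000 + rep, reps=1, stages=("V9",))
            profiles, reflectance, _ = generate_campaign(cfg)
            ranking = rank_vis(_stage_dataset(profiles, reflectance, "V9"))
            if {"NDRE", "CCCI"} <= set(ranking.head(3)["vi"]):
                top_hits += 1
        assert top_hits >= 95

    def test_duplicated_index_gets_adjacent_alphabetical_ranks(self, noisy_campaign):
        _, profiles, reflectance, _ = noisy_campaign
        ds = _stage_dataset(profiles, reflectance, "R2")
        vi = ds.vi.copy()
        vi["AAA_copy"] = vi["NDVI"]
        ranking = rank_vis(StageDataset(ds.stage, ds.spad, vi, ds.canopy_spad))
        pair = ranking[ranking["vi"].isin(["AAA_copy", "NDVI"])]
        assert list(pair["rank"]) == sorted(pair["rank"])
        assert abs(pair["rank"].iloc[0] - pair["rank"].iloc[1]) == 1
        assert pair["vi"].iloc[0] == "AAA_copy"  # alphabetical tie-break

    def test_two_plots_insufficient(self, noisy_campaign):
        _, profiles, reflectance, _ = noisy_campaign
        ds = _stage_dataset(profiles, reflectance, "V6")
        with pytest.raises(ValueError, match="3"):
            rank_vis(ds.subset(list(ds.spad.index[:2])))


class TestSensitiveLeaf:
    def test_designated_position_recovered_at_default_noise(self):
        from canopyspad.synthetic import CampaignConfig, generate_campaign

        hits = 0
        for rep in range(100):
            cfg = CampaignConfig(seed=9000 + rep, reps=1, stages=("V6",))
            profiles, reflectance, truth = generate_campaign(cfg)
            ds = _stage_dataset(profiles, reflectance, "V6")
            pos, _ = find_sensitive_leaf(ds, "CCCI")
            if pos == truth.sensitive_leaf["V6"]:
                hits += 1
        assert hits >= 95

    def test_single_available_position_is_returned(self):
        spad = pd.DataFrame({4: [20.0, 25.0, 30.0]}, index=["a", "b", "c"])
        vi = pd.DataFrame({"CCCI": [0.1, 0.5, 0.9]}, index=["a", "b", "c"])
        ds = StageDataset("V9", spad, vi, spad.mean(axis=1))
        pos, profile = find_sensitive_leaf(ds, "CCCI")
        assert pos == 4
        assert profile.loc[4, "usable"]

    def test_constant_position_excluded_and_reported(self):
        spad = pd.DataFrame(
            {1: [30.0, 30.0, 30.0], 2: [20.0, 25.0, 33.0]}, index=["a", "b", "c"]
        )
        vi = pd.DataFrame({"CCCI": [0.1, 0.5, 0.9]}, index=["a", "b", "c"])
        ds = StageDataset("V9", spad, vi, spad.mean(axis=1))
        pos, profile = find_sensitive_leaf(ds, "CCCI")
        assert pos == 2
        assert not profile.loc[1, "usable"]

    def test_signed_maximum_not_absolute(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 20)
        spad = pd.DataFrame(
            {1: 40 - 30 * x + rng.normal(0, 0.1, 20),   # strongly negative r
             2: 20 + 5 * x + rng.normal(0, 1, 20)},     # moderate positive r
            index=[f"p{i}" for i in range(20)],
        )
        vi = pd.DataFrame({"CCCI": x}, index=spad.index)
        ds = StageDataset("R1", spad, vi, spad.mean(axis=1))
        pos, _ = find_sensitive_leaf(ds, "CCCI")
        assert pos == 2
        pos_abs, _ = find_sensitive_leaf(ds, "CCCI", use_abs=True)
        assert pos_abs == 1


class TestInversion:
    def _toy(self, x, y):
        spad = pd.DataFrame({6: y}, index=[f"p{i}" for i in range(len(x))])
        vi = pd.DataFrame({"CCCI": x}, index=spad.index)
        return StageDataset("V6", spad, vi, spad.mean(axis=1))

    def test_exact_line_recovered(self):
        ds = self._toy([0.0, 1.0, 2.0], [2.0, 5.0, 8.0])  # y = 2 + 3x
        model = fit_inversion(ds, "CCCI", 6)
        assert model.intercept == pytest.approx(2.0, abs=1e-10)
        assert model.slope == pytest.approx(3.0, abs=1e-10)
        assert model.train_metrics["r2"] == pytest.approx(1.0)
        assert model.train_metrics["rmse"] == pytest.approx(0.0, abs=1e-10)
        assert model.resubstitution

    def test_train_r2_equals_squared_pearson(self, noisy_campaign):
        _, profiles, reflectance, _ = noisy_campaign
        ds = _stage_dataset(profiles, reflectance, "R2")
        model = fit_inversion(ds, "CCCI", "canopy_mean")
        r = metrics.pearson_r(ds.vi["CCCI"], ds.canopy_spad).r
        assert model.train_metrics["r2"] == pytest.approx(r * r, abs=1e-10)

    def test_matches_normal_equations_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 50)
        y = 10 + 25 * x + rng.normal(0, 2, 50)
        model = fit_inversion(self._toy(x, y), "CCCI", 6)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)

    def test_overlapping_split_rejected(self):
        ds = self._toy([0.0, 1.0, 2.0, 3.0], [2.0, 5.0, 8.0, 11.0])
        with pytest.raises(ValueError, match="overlap"):
            fit_inversion(ds, "CCCI", 6,
                          train_plots=["p0", "p1", "p2"], test_plots=["p2", "p3"])

    def test_constant_vi_on_training_set_rejected(self):
        ds = self._toy([0.5, 0.5, 0.5], [2.0, 5.0, 8.0])
        with pytest.raises(ValueError, match="constant"):
            fit_inversion(ds, "CCCI", 6)

    def test_independent_test_dataset_evaluation(self, noisy_campaign):
        _, profiles, reflectance, _ = noisy_campaign
        ds = _stage_dataset(profiles, reflectance, "R1")
        ids = list(ds.spad.index)
        model = fit_inversion(ds, "CCCI", "canopy_mean",
                              train_plots=ids[0::2], test_plots=ids[1::2])
        assert not model.resubstitution
        assert model.test_metrics is not None
        assert set(model.train_plots).isdisjoint(model.test_plots)


class TestCompare:
    def _model(self, r2, rmse=3.0, **kw):
        base = dict(
            stage="V6", vi_name="CCCI", target="canopy_mean",
            intercept=0.0, slope=1.0,
            train_metrics={"r2": r2, "rmse": rmse, "n": 30},
            test_metrics={"r2": r2, "rmse": rmse, "n": 30},
            resubstitution=False, train_plots=("a",), test_plots=("b",),
        )
        base.update(kw)
        return StageInversionModel(**base)

    def test_identical_models_zero_improvement(self):
        m = self._model(0.5)
        assert compare_models(m, m)["r2_improvement_pct"] == 0

    @pytest.mark.parametrize(
        "r2_sens, r2_canopy, expected_pct",
        [(0.59, 0.44, 34), (0.67, 0.65, 3), (0.60, 0.50, 20), (0.76, 0.74, 3)],
    )
    def test_relative_gain_rounds_to_integer_percent(
        self, r2_sens, r2_canopy, expected_pct
    ):
        ms = self._model(r2_sens, target="sensitive_leaf:6")
        mc = self._model(r2_canopy)
        assert compare_models(ms, mc)["r2_improvement_pct"] == expected_pct

    def test_mismatched_test_sets_rejected(self):
        ms = self._model(0.6, test_plots=("a",))
        mc = self._model(0.5, test_plots=("z",))
        with pytest.raises(ValueError, match="test plots"):
            compare_models(ms, mc)


class TestPredictMap:
    def test_zero_vi_predicts_intercept_and_monotonicity(self):
        model = StageInversionModel(
            stage="R1", vi_name="CCCI", target="canopy_mean",
            intercept=12.5, slope=40.0,
            train_metrics={"r2": 1.0, "rmse": 0.0, "n": 3},
            test_metrics=None, resubstitution=True,
        )
        vi = pd.DataFrame({"CCCI": [0.0, 0.2, 0.8, np.nan]},
                          index=["a", "b", "c", "d"])
        out = predict_spad_map(model, vi)
        assert out.loc["a", "predicted_spad"] == pytest.approx(12.5)
        assert out.loc["c", "predicted_spad"] > out.loc["b", "predicted_spad"]
        assert np.isnan(out.loc["d", "predicted_spad"])

    def test_training_predictions_reproduce_fitted_values(self):
        x = np.array([0.1, 0.4, 0.9, 0.3])
        y = np.array([20.0, 30.0, 50.0, 26.0])
        spad = pd.DataFrame({6: y}, index=[f"p{i}" for i in range(4)])
        vi = pd.DataFrame({"CCCI": x}, index=spad.index)
        ds = StageDataset("V6", spad, vi, spad.mean(axis=1))
        model = fit_inversion(ds, "CCCI", 6)
        out = predict_spad_map(model, vi)
        assert out["predicted_spad"].to_numpy() == pytest.approx(
            model.intercept + model.slope * x
        )
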