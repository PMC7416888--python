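"""Analysis-chain tests: exclusion, weight regression, estimators, models."""

import numpy as np
import pandas as pd
import pytest

from cuecatch import (
    analyze_log,
    estimate_internal_noise,
    estimator_r2,
    exclude_outliers,
    fit_weights,
    generate_cohort,
    generate_control_session,
    model_mse,
    model_predictions,
    prior_only_summary,
    transfer_contrast,
)
from cuecatch.cohort import CohortParams


def _toy_log(errors, prior="narrow", lik="medium"):
    n = len(errors)
    return pd.DataFrame(
        {
            "subject_id": ["S001"] * n,
            "kind": ["main"] * n,
            "prior_id": [prior] * n,
            "likelihood_id": [lik] * n,
            "block": [1] * n,
            "target_x": 35.0,
            "centroid": np.linspace(30, 40, n),
            "response_x": 35.0 + np.asarray(errors),
            "error": np.asarray(errors, float),
            "abs_error": np.abs(errors).astype(float),
        }
    )


class TestOutlierExclusion:
    def test_constructed_extremes_are_dropped(self):
        errors = [0.1] * 198 + [50.0, 60.0]
        filtered, report = exclude_outliers(_toy_log(errors))
        assert report["n_dropped_total"] == 2
        assert len(filtered) == 198
        assert filtered.abs_error.max() == pytest.approx(0.1)

    def test_all_equal_errors_drop_nothing(self):
        filtered, report = exclude_outliers(_toy_log([0.5] * 100))
        assert report["n_dropped_total"] == 0 and len(filtered) == 100

    def test_never_drops_more_than_one_percent_per_pairing(self, internal_noise_cohort):
        log, _, _ = internal_noise_cohort
        _, report = exclude_outliers(log)
        per = report["per_pairing"]
        assert ((per.n_dropped / per.n_trials) <= 0.01 + 1e-12).all()

    def test_per_subject_drop_counts_reported(self, internal_noise_cohort):
        log, _, _ = internal_noise_cohort
        _, report = exclude_outliers(log)
        assert report["max_dropped_per_subject_pairing"] >= 1
        assert {"subject_id", "n_dropped"} <= set(report["per_subject"].columns)


class TestFitWeights:
    def test_noiseless_fixed_blend_recovered_exactly(self):
        # response = 0.7 c + 0.3 * 35  ->  slope 0.7, intercept 10.5
        c = np.linspace(30, 40, 50)
        log = _toy_log(np.zeros(50))
        log["centroid"] = c
        log["response_x"] = 0.7 * c + 0.3 * 35.0
        w = fit_weights(log, grain="pooled")
        assert w.slope.iloc[0] == pytest.approx(0.7, abs=1e-12)
        assert w.intercept.iloc[0] == pytest.approx(10.5, abs=1e-10)

    def test_identity_regression_slope_one(self):
        log = _toy_log(np.zeros(30))
        log["response_x"] = log["centroid"]
        w = fit_weights(log, grain="pooled")
        assert w.slope.iloc[0] == pytest.approx(1.0) and w.r2.iloc[0] == pytest.approx(1.0)

    def test_small_or_degenerate_cells_flagged_not_fitted(self):
        log = _toy_log(np.zeros(5))
        w = fit_weights(log, grain="pooled", min_trials=10)
        assert w.flagged.iloc[0] and np.isnan(w.slope.iloc[0])
        log = _toy_log(np.zeros(30))
        log["centroid"] = 35.0  # constant regressor
        w = fit_weights(log, grain="pooled")
        assert w.flagged.iloc[0] and np.isnan(w.slope.iloc[0])

    def test_grain_controls_table_shape(self, internal_noise_cohort):
        log, _, _ = internal_noise_cohort
        per_block = fit_weights(log)
        pooled = fit_weights(log, grain="pooled")
        assert "block" in per_block.columns and "block" not in pooled.columns
        assert len(per_block) > len(pooled)


class TestEstimatorComparison:
    @pytest.mark.parametrize("statistic", ["mean", "midrange"])
    def test_generating_statistic_ranks_first(self, statistic):
        rng = np.random.default_rng(0)
        n = 3000
        dots = rng.normal(50, 3, size=(n, 8))
        stat = dots.mean(axis=1) if statistic == "mean" else (
            dots.min(axis=1) + dots.max(axis=1)
        ) / 2
        log = pd.DataFrame(dots, columns=[f"dot_x_{i+1}" for i in range(8)])
        log["kind"] = "main"
        log["response_x"] = stat + rng.normal(0, 0.3, n)
        r2, best = estimator_r2(log)
        assert best == statistic

    def test_missing_dot_columns_rejected(self):
        with pytest.raises(ValueError):
            estimator_r2(pd.DataFrame({"kind": ["main"], "response_x": [1.0]}))


class TestPriorOnlySummary:
    def test_never_updating_observer_shows_initialization_bias(self):
        from cuecatch import Observer, ObserverParams, Trial, default_likelihoods, default_priors

        params = ObserverParams("fixed_weight", fixed_w=1.0, prior_only_sampling=False)
        obs = Observer(params, default_priors(), default_likelihoods())
        probe = Trial(1, 1, "prior_only", "narrow", None, 35.0)
        # before any feedback, probes sit at the screen-centre belief:
        # bias relative to the true prior mean is 50 - 35 = 15 psw
        resp = obs.respond(probe, np.random.default_rng(0))
        assert resp - 35.0 == pytest.approx(15.0)

    def test_learned_prior_probe_statistics(self, internal_noise_cohort):
        log, _, _ = internal_noise_cohort
        res = prior_only_summary(log)
        res = res.set_index("prior_id")
        assert abs(res.loc["wide", "mean_bias"]) < 0.3
        # probe response scatter tracks the learned prior SD
        assert res.loc["narrow", "median_response_sd"] == pytest.approx(1.0, abs=0.45)
        assert res.loc["wide", "median_response_sd"] == pytest.approx(2.5, abs=0.6)

    def test_zero_variance_responder(self):
        log = pd.DataFrame(
            {
                "subject_id": ["S1"] * 20,
                "kind": ["prior_only"] * 20,
                "prior_id": ["narrow"] * 20,
                "response_x": [35.0] * 20,
            }
        )
        res = prior_only_summary(log)
        assert res.median_response_sd.iloc[0] == 0.0


class TestInternalNoiseEstimation:
    def test_noiseless_estimate_zero(self):
        df = generate_control_session(50, {"low": 0.0, "medium": 0.0, "high": 0.0}, seed=0)
        est = estimate_internal_noise(df)
        assert (est.sigma_li_hat < 1e-12).all()

    def test_recovers_generating_noise(self):
        df = generate_control_session(4000, {"low": 1.5, "medium": 1.5, "high": 1.5}, seed=1)
        est = estimate_internal_noise(df, per_condition=False)
        assert est.sigma_li_hat.iloc[0] == pytest.approx(1.5, rel=0.03)

    def test_conflates_motor_and_centroiding_noise(self):
        df = generate_control_session(4000, {"low": 1.0, "medium": 1.0, "high": 1.0},
                                      sigma_m=1.0, seed=2)
        est = estimate_internal_noise(df, per_condition=False)
        assert est.sigma_li_hat.iloc[0] == pytest.approx(np.sqrt(2.0), rel=0.03)

    def test_too_few_trials_rejected(self):
        df = generate_control_session(2, {"low": 1.0}, seed=3)
        with pytest.raises(ValueError):
            estimate_internal_noise(df[df.likelihood_id == "low"].head(2))


class TestModelPredictionsAndMSE:
    def test_zero_internal_noise_limits(self):
        sig = pd.DataFrame({"subject_id": ["S1"] * 3,
                            "likelihood_id": ["low", "medium", "high"],
                            "sigma_li_hat": [0.0, 0.0, 0.0]})
        preds = model_predictions(sig)
        assert np.allclose(preds.w_internal, 1.0)
        assert np.allclose(preds.w_overall, preds.w_external)

    def test_internal_noise_lowers_overall_below_external(self, internal_noise_cohort):
        _, _, control = internal_noise_cohort
        preds = model_predictions(estimate_internal_noise(control))
        assert (preds.w_overall < preds.w_external).all()

    def test_perfect_predictions_give_zero_mse(self):
        preds = model_predictions(
            pd.DataFrame({"subject_id": ["S1"] * 3,
                          "likelihood_id": ["low", "medium", "high"],
                          "sigma_li_hat": [0.5, 1.0, 1.5]})
        )
        weights = preds.rename(columns={"w_internal": "slope"})[
            ["subject_id", "prior_id", "likelihood_id", "slope"]
        ]
        weights["flagged"] = False
        mse = model_mse(weights, preds).set_index("model")
        assert mse.loc["internal", "mse"] == pytest.approx(0.0, abs=1e-15)
        assert mse.loc["internal", "rank"] == 1

    def test_constant_shift_raises_mse_quadratically(self):
        preds = model_predictions(
            pd.DataFrame({"subject_id": ["S1"] * 3,
                          "likelihood_id": ["low", "medium", "high"],
                          "sigma_li_hat": [0.5, 1.0, 1.5]})
        )
        weights = preds.rename(columns={"w_internal": "slope"})[
            ["subject_id", "prior_id", "likelihood_id", "slope"]
        ].copy()
        weights["flagged"] = False
        weights["slope"] += 0.1
        mse = model_mse(weights, preds).set_index("model")
        assert mse.loc["internal", "mse"] == pytest.approx(0.01, abs=1e-12)

    def test_empty_intersection_rejected(self):
        preds = model_predictions(
            pd.DataFrame({"subject_id": ["S9"], "likelihood_id": ["low"], "sigma_li_hat": [1.0]})
        )
        weights = pd.DataFrame(
            {"subject_id": ["S1"], "prior_id": ["narrow"], "likelihood_id": ["low"],
             "slope": [0.5], "flagged": [False]}
        )
        with pytest.raises(ValueError):
            model_mse(weights, preds)


class TestTransferContrast:
    def test_identical_weights_give_zero_gap_and_slope(self):
        rows = []
        for s in ("S1", "S2", "S3"):
            for b in (4, 5):
                for lik in ("medium", "high"):
                    rows.append({"subject_id": s, "prior_id": "narrow",
                                 "likelihood_id": lik, "block": b, "slope": 0.8})
        tr = transfer_contrast(pd.DataFrame(rows), n_boot=200, seed=0)
        assert tr["immediate_gap"] == pytest.approx(0.0, abs=1e-12)
        assert tr["exposure_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_high_cells_rejected(self):
        df = pd.DataFrame({"subject_id": ["S1"], "prior_id": ["narrow"],
                           "likelihood_id": ["medium"], "block": [4], "slope": [0.5]})
        with pytest.raises(ValueError):
            transfer_contrast(df)


class TestFullChain:
    def test_analyze_log_emits_all_sections(self, internal_noise_cohort):
        log, _, control = internal_noise_cohort
        res = analyze_log(log, control, n_boot=500, seed=0)
        assert {"weights", "exclusion", "estimator_r2", "best_estimator",
                "prior_only", "sigma_li", "predictions", "model_mse", "transfer"} <= set(res)
        assert res["transfer"]["applicable"]

    def test_pipeline_deterministic(self):
        p = CohortParams(strategy="bayes_transfer")
        outs = []
        for _ in range(2):
            log, _ = generate_cohort("exp3", 2, p, seed=3)
            w = fit_weights(log, grain="pooled")
            outs.append(w.slope.to_numpy())
        assert np.array_equal(outs[0], outs[1])
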