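"""Cross-validation protocols, intervals, reliability tiers, method comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitrispec.evaluation import (
    ErrorPercentiles,
    SpectralPMIRegressor,
    SplitProtocol,
    assign_reliability,
    bootstrap_prediction_interval,
    build_prediction_record,
    compare_methods,
    comparison_variants,
    error_percentiles,
    fit_linear_method,
    loocv,
    loocv_pipeline,
    metrics,
    repeated_splits,
    residual_diagnostics,
    select_components,
)
from vitrispec.datasets import reference_cohort


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert metrics(y, y) == (0.0, 0.0, 1.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rmse, mae, r2 = metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        rmse, mae, r2 = metrics(np.array([0.0, 10.0]), np.array([5.0, 5.0]))
        assert (rmse, mae, r2) == (5.0, 5.0, 0.0)

    def test_zero_sst_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            metrics(np.ones(3), np.zeros(3))


class TestLOOCV:
    def test_constant_model_on_constant_target(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.linspace(1, 2, 6)
        out = loocv(X, y, lambda Xtr, ytr, Xte: np.full(1, ytr.mean()))
        assert out.rmse > 0  # mean predictor is not exact
        out2 = loocv(X, np.array([1, 1, 1, 2, 2, 2.0]),
                     lambda Xtr, ytr, Xte: np.full(1, 1.5))
        assert out2.rmse == pytest.approx(0.5)

    def test_hand_computable_rmse(self):
        y = np.arange(5.0)
        # predictor always returns the left-out index + 1 via shifted lookup
        shifted = np.roll(y, 1)
        calls = iter(shifted)
        out = loocv(np.zeros((5, 1)), y, lambda Xtr, ytr, Xte: [next(calls)])
        expected = np.sqrt(np.mean((y - shifted) ** 2))
        assert out.rmse == pytest.approx(expected)

    def test_order_invariance(self, default_cohort):
        cfg, m, meta, truth = default_cohort
        y = {r.sample_id: r.pmi_hours for r in meta if r.cohort == "known"}
        km = m.select_samples(list(y))
        a = loocv_pipeline(km, y, lambda: SpectralPMIRegressor("PLS", 2))
        rev = m.select_samples(list(reversed(list(y))))
        b = loocv_pipeline(rev, y, lambda: SpectralPMIRegressor("PLS", 2))
        pa = dict(zip(a.sample_ids, a.y_pred))
        pb = dict(zip(b.sample_ids, b.y_pred))
        for sid in pa:
            assert pa[sid] == pytest.approx(pb[sid], abs=1e-9)

    def test_leakage_sentinel(self, default_cohort):
        """Corrupting the held-out spectra cannot change its fold's prediction
        machinery: the fold model must be identical."""
        cfg, m, meta, truth = default_cohort
        y = {r.sample_id: r.pmi_hours for r in meta if r.cohort == "known"}
        ids = list(y)
        held = ids[0]
        train = m.select_samples(ids[1:])
        model = SpectralPMIRegressor("PLS", 2).fit(train, y)
        ref_before = model.preprocess_.emsc.reference.copy()
        center_before = model.preprocess_.center_mean.copy()
        # scale the held-out sample's replicates arbitrarily; refit on same train
        m2 = m.copy()
        rows = [i for i, s in enumerate(m2.sample_ids) if s == held]
        m2.X[rows] *= 100.0
        model2 = SpectralPMIRegressor("PLS", 2).fit(m2.select_samples(ids[1:]), y)
        np.testing.assert_array_equal(model2.preprocess_.emsc.reference, ref_before)
        np.testing.assert_array_equal(model2.preprocess_.center_mean, center_before)
        np.testing.assert_array_equal(model2.model_.B, model.model_.B)


class TestSelectComponents:
    def test_rank_two_response_selects_two(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=(30, 2))
        X = latent @ rng.normal(size=(2, 25)) + 1e-6 * rng.normal(size=(30, 25))
        y = latent @ np.array([3.0, -2.0])
        a_star, rmsecv = select_components(X, y, grid=range(1, 6))
        assert a_star == 2

    def test_singleton_grid(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        a_star, _ = select_components(X, y, grid=[3])
        assert a_star == 3

    def test_pure_noise_prefers_small_a(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 30))
        y = rng.normal(size=15)
        a_star, rmsecv = select_components(X, y, grid=range(1, 9))
        assert a_star <= 3  # overfit grows RMSECV; ties break small


class TestRepeatedSplits:
    def test_split_sizes_and_seed_determinism(self, default_cohort):
        cfg, m, meta, truth = default_cohort
        y = {r.sample_id: r.pmi_hours for r in meta if r.cohort == "known"}
        km = m.select_samples(list(y))
        protocol = SplitProtocol(n_splits=2, seed=4, component_grid=(1, 2, 3))
        df1 = repeated_splits(km, y, protocol)
        df2 = repeated_splits(km, y, protocol)
        assert (df1.n_train == 15).all() and (df1.n_test == 5).all()
        pd.testing.assert_frame_equal(df1, df2)
        assert df1.attrs["summary"]["rmse_mean"] > 0

    def test_split_rmse_within_band_of_loocv(self, default_cohort):
        cfg, m, meta, truth = default_cohort
        y = {r.sample_id: r.pmi_hours for r in meta if r.cohort == "known"}
        km = m.select_samples(list(y))
        cv = loocv_pipeline(km, y, lambda: SpectralPMIRegressor("PLS", 2))
        df = repeated_splits(km, y, SplitProtocol(n_splits=3, seed=5, component_grid=(2,)))
        assert df.rmse.mean() < 2.5 * cv.rmse


class TestDiagnostics:
    def test_normal_sample_calibration(self):
        hits = 0
        for seed in range(20):
            res = np.random.default_rng(seed).normal(size=50)
            rep = residual_diagnostics(res, predicted=np.arange(50.0))
            hits += rep.shapiro_p > 0.05
        assert hits >= 18

    def test_skewed_residuals_flagged(self):
        hits = 0
        for seed in range(20):
            res = np.random.default_rng(seed).exponential(size=30)
            rep = residual_diagnostics(res, predicted=np.arange(30.0))
            hits += rep.shapiro_p < 0.05
        assert hits >= 18

    def test_mirrored_groups_equal_variance(self):
        res = np.array([-3.0, -1.0, 1.0, 3.0, -3.0, -1.0, 1.0, 3.0])
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rep = residual_diagnostics(res, groups=groups)
        assert rep.levene_p == pytest.approx(1.0)

    def test_small_sample_marked_unavailable(self):
        rep = residual_diagnostics(np.array([0.1, -0.2, 0.3]))
        assert rep.shapiro_p is None and rep.levene_p is None


class TestIntervals:
    def test_percentile_examples(self):
        assert error_percentiles(np.array([7.0, 7.0, 7.0])) == ErrorPercentiles(7, 7, 7)
        p = error_percentiles(np.arange(1.0, 11.0))
        assert p.q50 == pytest.approx(5.5)
        assert p.q50 <= p.q75 <= p.q90

    def test_constant_magnitude_residuals(self):
        res = np.array([2.5, -2.5, 2.5, -2.5, 2.5, -2.5])
        assert bootstrap_prediction_interval(res, n_boot=50, seed=0) == pytest.approx(2.5)

    def test_seed_reproducibility(self):
        res = np.random.default_rng(6).normal(size=30)
        a = bootstrap_prediction_interval(res, seed=9)
        b = bootstrap_prediction_interval(res, seed=9)
        assert a == b

    def test_normal_quantile_oracle(self):
        """Half-width approaches 1.96*sigma for normal residuals (n=200).

        A single n=200 draw leaves ~7% sampling noise on the 95th percentile
        itself, so the convergence statement is checked in expectation over
        independent residual vectors.
        """
        sigma = 12.0
        halves = [
            bootstrap_prediction_interval(
                np.random.default_rng(s).normal(scale=sigma, size=200),
                n_boot=1000, seed=1,
            )
            for s in range(10)
        ]
        assert np.mean(halves) == pytest.approx(stats.norm.ppf(0.975) * sigma, rel=0.05)

    def test_aggregation_switch(self):
        res = np.random.default_rng(8).normal(size=40)
        mean_h = bootstrap_prediction_interval(res, n_boot=200, seed=2)
        pct_h = bootstrap_prediction_interval(res, n_boot=200, seed=2, aggregation="percentile")
        assert pct_h >= mean_h


class TestPredictionRecords:
    def test_interval_arithmetic(self):
        pct = ErrorPercentiles(7.0, 16.0, 20.0)
        rec = build_prediction_record("205", 67.0, pct, 36.1, estimate=15.0)
        assert tuple(round(x) for x in rec.interval_50) == (60, 74)
        assert tuple(round(x) for x in rec.interval_75) == (51, 83)
        assert tuple(round(x) for x in rec.interval_90) == (47, 87)

    def test_tier_assignment(self):
        pct = ErrorPercentiles(7.0, 16.0, 20.0)
        assert build_prediction_record("x", 29.6, pct, 36.1, 12.0).agreement == "consistent_90"
        assert build_prediction_record("x", 28.9, pct, 36.1, 19.0).agreement == "consistent_75"
        assert build_prediction_record("x", 27.1, pct, 36.1, 33.0).agreement == "consistent_50"
        assert build_prediction_record("x", 50.0, pct, 36.1, 50.0).agreement == "consistent_50"
        assert build_prediction_record("x", 37.7, pct, 36.1, 17.0).agreement == "discrepant"
        assert build_prediction_record("x", 80.1, pct, 36.1, 179.28).agreement == "large_discrepancy"
        assert build_prediction_record("x", 40.0, pct, 36.1).agreement == "not_evaluable"

    def test_intervals_nested(self):
        rec = build_prediction_record("x", 50.0, ErrorPercentiles(5, 10, 15), 30.0, 48.0)
        assert rec.interval_50[0] >= rec.interval_75[0] >= rec.interval_90[0]
        assert rec.interval_50[1] <= rec.interval_75[1] <= rec.interval_90[1]


class TestReliability:
    def test_boundaries(self):
        tiers = assign_reliability(
            {"a": 0.1, "b": 15.82, "c": 36.1, "d": 31.64}, rmse=15.82
        )
        by_id = {t.sample_id: t.tier for t in tiers}
        assert by_id == {
            "a": "reliable", "b": "borderline", "c": "problematic", "d": "borderline"
        }

    def test_rmse_must_be_positive(self):
        with pytest.raises(ValueError):
            assign_reliability({"a": 1.0}, rmse=0.0)


class TestLinearMethods:
    def test_clean_linear_data_all_agree_with_ols(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + 4.0
        preds = {}
        for name in ("OLS", "Huber", "TheilSen", "RANSAC"):
            preds[name] = fit_linear_method(name, X, y, seed=0).predict(X)
        for name in ("Huber", "TheilSen", "RANSAC"):
            np.testing.assert_allclose(preds[name], preds["OLS"], atol=1e-6)

    def test_theilsen_falls_back_to_ols_when_wide(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 551))
        y = rng.normal(size=20)
        ts = fit_linear_method("TheilSen", X, y)
        ols = fit_linear_method("OLS", X, y)
        assert ts.flags.get("theilsen_ols_fallback") is True
        np.testing.assert_allclose(ts.predict(X), ols.predict(X), atol=1e-10)

    def test_ransac_excludes_planted_outlier(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        y[7] += 50.0  # gross outlier
        fitted = fit_linear_method("RANSAC", X, y, seed=3)
        assert fitted.flags["ransac_inlier_mask"][7] is False
        ols = fit_linear_method("OLS", X, y)
        # OLS is dragged by the outlier; RANSAC is not
        clean = np.delete(np.arange(30), 7)
        assert (
            np.abs(fitted.predict(X[clean]) - y[clean]).max()
            < np.abs(ols.predict(X[clean]) - y[clean]).max()
        )


class TestCompareMethods:
    def test_reference_cohort_variant_sizes(self):
        meta = reference_cohort()
        variants = comparison_variants(meta, pls_problematic=["490", "718"])
        assert len(variants["full"]) == 20
        assert len(variants["excl_confounders"]) == 17
        assert len(variants["excl_pls_problematic"]) == 18
        assert len(variants["forensic_lt72"]) == 13

    def test_small_variant_refused(self, default_cohort):
        cfg, m, meta, truth = default_cohort
        known = [r.sample_id for r in meta if r.cohort == "known"]
        with pytest.raises(ValueError, match="refused"):
            compare_methods(
                m.select_samples(known), meta, methods=("OLS",),
                variants={"tiny": known[:3]},
            )

    def test_confounder_exclusion_improves_ols(self):
        """Injected confounders hurt OLS; dropping them recovers accuracy."""
        import vitrispec as v
        from vitrispec.synth import SyntheticConfig, generate_cohort

        cfg = SyntheticConfig(
            seed=6, outliers=((1, "carb_shift"), (5, "protein_shift"), (9, "carb_shift"))
        )
        m, meta, truth = generate_cohort(cfg)
        known = [r.sample_id for r in meta if r.cohort == "known"]
        flagged = [r.sample_id for r in meta if r.confounder_flag]
        variants = {
            "full": known,
            "excl_confounders": [s for s in known if s not in flagged],
        }
        cmp = compare_methods(
            m.select_samples(known), meta, methods=("OLS",), variants=variants
        )
        res = cmp.results.set_index("variant")
        assert res.loc["excl_confounders", "rmse"] < res.loc["full", "rmse"]
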