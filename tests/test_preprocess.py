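"""EMSC, Savitzky-Golay derivative and centering: oracles and leakage contracts."""

import numpy as np
import pytest

from vitrispec.preprocess import (
    apply_emsc,
    apply_preprocess,
    average_replicates,
    fit_center,
    fit_emsc,
    fit_preprocess,
    offset_correct,
    second_derivative,
)
from vitrispec.spectra import SpectraMatrix, WavenumberGrid


def _bandspec(grid, center=1200.0, amp=0.4, sigma=12.0):
    return amp * np.exp(-0.5 * ((grid.values - center) / sigma) ** 2)


@pytest.fixture()
def grid():
    return WavenumberGrid.regular(1800.0, 700.0, 2.0)


def _mat(grid, rows, sids=None):
    rows = np.atleast_2d(rows)
    sids = sids or [f"s{i+1}" for i in range(rows.shape[0])]
    return SpectraMatrix(rows, grid, sids, [1] * rows.shape[0])


class TestEMSC:
    def test_reference_is_mean(self, grid):
        s = _bandspec(grid)
        model = fit_emsc(_mat(grid, np.vstack([s, 3 * s])))
        np.testing.assert_allclose(model.reference, 2 * s)

    def test_reference_ignores_heldout_rows(self, grid):
        rng = np.random.default_rng(1)
        X = rng.normal(0.3, 0.02, size=(20, len(grid)))
        fit_rows = _mat(grid, X[:15])
        model_a = fit_emsc(fit_rows)
        X2 = X.copy()
        X2[15:] += 10.0  # perturb rows never given to the fit
        model_b = fit_emsc(_mat(grid, X2[:15]))
        np.testing.assert_array_equal(model_a.reference, model_b.reference)

    def test_self_correction_identity(self, grid):
        s = _bandspec(grid)
        model = fit_emsc(_mat(grid, np.vstack([s, s])))
        corrected, params = apply_emsc(model, _mat(grid, s))
        assert params[0].a == pytest.approx(0, abs=1e-10)
        assert params[0].c == pytest.approx(0, abs=1e-10)
        assert params[0].b == pytest.approx(1, abs=1e-10)
        np.testing.assert_allclose(corrected.X[0], s, atol=1e-10)

    def test_constructed_params_recovered(self, grid):
        """Spectrum built inside the model space: 2*ref + 0.5 + 0.3*vt."""
        ref = _bandspec(grid)
        model = fit_emsc(_mat(grid, np.vstack([ref, ref])))
        vt = grid.scaled()
        s = 2.0 * ref + 0.5 + 0.3 * vt
        corrected, params = apply_emsc(model, _mat(grid, s))
        assert params[0].a == pytest.approx(0.5, abs=1e-10)
        assert params[0].b == pytest.approx(2.0, abs=1e-10)
        assert params[0].c == pytest.approx(0.3, abs=1e-10)
        np.testing.assert_allclose(corrected.X[0], ref, atol=1e-10)

    def test_orthogonal_residual_preserved(self):
        """Small-grid normal-equations oracle: e orthogonal to basis -> b=1."""
        grid = WavenumberGrid.regular(1100.0, 1000.0, 10.0)
        rng = np.random.default_rng(2)
        ref = rng.normal(0.3, 0.05, len(grid))
        model = fit_emsc(_mat(grid, np.vstack([ref, ref])))
        e = rng.normal(0, 0.01, len(grid))
        basis = model.basis
        e -= basis @ np.linalg.lstsq(basis, e, rcond=None)[0]  # orthogonalize
        corrected, params = apply_emsc(model, _mat(grid, ref + e))
        assert params[0].b == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(corrected.X[0], ref + e, atol=1e-10)

    def test_idempotent_correction(self, grid):
        rng = np.random.default_rng(3)
        X = rng.normal(0.3, 0.02, size=(6, len(grid)))
        m = _mat(grid, X)
        model = fit_emsc(m)
        once, _ = apply_emsc(model, m)
        twice, params = apply_emsc(model, once)
        for p in params:
            assert p.b == pytest.approx(1, abs=1e-6)
            assert abs(p.a) < 1e-6 and abs(p.c) < 1e-6
        np.testing.assert_allclose(twice.X, once.X, atol=1e-8)

    def test_inverts_generator_artifacts_at_zero_noise(self, default_cohort):
        """Artifacted and clean versions of the same chemistry correct identically."""
        import vitrispec as v
        from vitrispec.synth import SyntheticConfig, generate_cohort

        cfg = SyntheticConfig(seed=4, replicate_noise_sd=0.0)
        m, meta, truth = generate_cohort(cfg)
        known = [r.sample_id for r in meta if r.cohort == "known"]
        km = m.select_samples(known)
        model = fit_emsc(km)
        clean_rows = np.repeat(
            truth.clean.X[[truth.clean.sample_ids.index(s) for s in known]], 4, axis=0
        )
        clean_m = SpectraMatrix(clean_rows, m.grid, km.sample_ids, km.replicate_ids)
        corr_obs, _ = apply_emsc(model, km)
        corr_clean, _ = apply_emsc(model, clean_m)
        assert np.abs(corr_obs.X - corr_clean.X).max() < 1e-8

    def test_near_zero_scale_rejected(self, grid):
        ref = _bandspec(grid)
        model = fit_emsc(_mat(grid, np.vstack([ref, ref])))
        vt = grid.scaled()
        with pytest.raises(ValueError, match="scale coefficient"):
            apply_emsc(model, _mat(grid, 0.1 + 0.05 * vt))  # no reference content


class TestSecondDerivative:
    def test_exact_on_polynomials(self, grid):
        v = grid.values
        quadratic = v**2
        cubic = 1.0 + 0.5 * v - 2e-3 * v**2 + 1e-6 * v**3
        m = _mat(grid, np.vstack([quadratic, np.full_like(v, 3.0), cubic]))
        d2 = second_derivative(m)
        np.testing.assert_allclose(d2.X[0], 2.0, rtol=1e-8)
        np.testing.assert_allclose(d2.X[1], 0.0, atol=1e-10)
        np.testing.assert_allclose(d2.X[2], -4e-3 + 6e-6 * v, rtol=1e-6)

    def test_gaussian_curvature_narrow_window(self):
        """-A/sigma^2 at the center, once the window is narrow vs the band."""
        grid = WavenumberGrid.regular(1300.0, 1100.0, 0.25)
        A, sigma, c0 = 0.4, 12.0, 1200.0
        m = _mat(grid, A * np.exp(-0.5 * ((grid.values - c0) / sigma) ** 2))
        d2 = second_derivative(m)
        idx = grid.index_of(c0)
        assert d2.X[0, idx] == pytest.approx(-A / sigma**2, rel=0.01)

    def test_linearity(self, grid):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, len(grid)))
        d2 = lambda arr: second_derivative(_mat(grid, arr)).X[0]
        np.testing.assert_allclose(
            d2(3.0 * x - 1.5 * y), 3.0 * d2(x) - 1.5 * d2(y), atol=1e-10
        )

    def test_non_uniform_grid_rejected(self):
        vals = np.sort(np.random.default_rng(5).uniform(700, 1800, 40))[::-1]
        g = WavenumberGrid(vals)
        with pytest.raises(ValueError, match="align_to_grid"):
            second_derivative(_mat(g, np.zeros(len(g))))


class TestCenteringAndPipeline:
    def test_fit_center_examples(self, grid):
        s = _bandspec(grid)
        np.testing.assert_array_equal(fit_center(_mat(grid, s)), s)
        np.testing.assert_allclose(fit_center(_mat(grid, np.vstack([s, -s]))), 0, atol=1e-15)

    def test_pipeline_centers_its_fitting_set(self, default_cohort):
        cfg, m, meta, truth = default_cohort
        known = m.select_samples([r.sample_id for r in meta if r.cohort == "known"])
        model = fit_preprocess(known)
        z = apply_preprocess(model, known)
        assert np.abs(z.X.mean(axis=0)).max() < 1e-12

    def test_heldout_reference_spectrum_composes_stages(self, grid):
        rng = np.random.default_rng(6)
        X = 0.3 + 0.05 * rng.standard_normal((8, len(grid)))
        fit_m = _mat(grid, X)
        model = fit_preprocess(fit_m)
        out = apply_preprocess(model, _mat(grid, model.emsc.reference, ["held"]))
        oracle = second_derivative(_mat(grid, model.emsc.reference)).X[0] - model.center_mean
        np.testing.assert_allclose(out.X[0], oracle, atol=1e-10)

    def test_leakage_contract(self, default_cohort):
        """Held-out outputs are invariant to other held-out spectra."""
        cfg, m, meta, truth = default_cohort
        ids = m.unique_samples()
        model = fit_preprocess(m.select_samples(ids[:15]))
        target = m.select_samples([ids[20]])
        out1 = apply_preprocess(model, target).X
        # corrupt a different held-out sample and refit on the same 15
        m2 = m.copy()
        rows = [i for i, s in enumerate(m2.sample_ids) if s == ids[21]]
        m2.X[rows] *= 7.5
        model2 = fit_preprocess(m2.select_samples(ids[:15]))
        out2 = apply_preprocess(model2, target).X
        np.testing.assert_array_equal(out1, out2)

    def test_equal_chemistry_equal_output(self, quiet_cohort):
        """With dispersions off, equal effective PMI implies equal output."""
        cfg, m, meta, truth = quiet_cohort
        known = [r.sample_id for r in meta if r.cohort == "known"]
        km = m.select_samples(known)
        model = fit_preprocess(km)
        # rebuild one sample's spectrum with injected artifacts only
        sid = known[3]
        rows = [i for i, s in enumerate(km.sample_ids) if s == sid]
        altered = km.copy()
        vt = km.grid.scaled()
        altered.X[rows] = 1.3 * altered.X[rows] + 0.05 - 0.02 * vt
        z0 = apply_preprocess(model, km.select_rows(rows))
        z1 = apply_preprocess(model, altered.select_rows(rows))
        np.testing.assert_allclose(z1.X, z0.X, atol=1e-9)

    def test_serialization_round_trip(self, tmp_path, default_cohort):
        cfg, m, meta, truth = default_cohort
        known = m.select_samples([r.sample_id for r in meta if r.cohort == "known"])
        model = fit_preprocess(known)
        path = tmp_path / "model.json"
        model.save(path)
        from vitrispec.preprocess import PreprocessPipelineModel

        back = PreprocessPipelineModel.load(path)
        np.testing.assert_array_equal(back.center_mean, model.center_mean)
        np.testing.assert_array_equal(back.emsc.reference, model.emsc.reference)
        z1 = apply_preprocess(model, known).X
        z2 = apply_preprocess(back, known).X
        np.testing.assert_array_equal(z1, z2)


class TestOffsetAndReplicates:
    def test_offset_zeroes_anchor(self, grid):
        rng = np.random.default_rng(7)
        m = _mat(grid, rng.normal(0.3, 0.05, size=(3, len(grid))))
        out = offset_correct(m, 1800.0)
        np.testing.assert_allclose(out.X[:, 0], 0.0)

    def test_constant_spectrum_goes_to_zero(self, grid):
        out = offset_correct(_mat(grid, np.full(len(grid), 0.7)))
        np.testing.assert_allclose(out.X, 0.0)

    def test_subtraction_arithmetic(self, grid):
        s = np.zeros(len(grid))
        s[grid.index_of(1800.0)] = 0.02
        s[grid.index_of(1041.0)] = 0.35
        out = offset_correct(_mat(grid, s))
        assert out.X[0, grid.index_of(1041.0)] == pytest.approx(0.33)

    def test_average_replicates(self, grid):
        s = _bandspec(grid)
        m = SpectraMatrix(
            np.vstack([s, s, s, s, s, -s]), grid,
            ["a", "a", "a", "a", "b", "b"], [1, 2, 3, 4, 1, 2],
        )
        out = average_replicates(m)
        assert out.sample_ids == ["a", "b"]
        np.testing.assert_allclose(out.X[0], s)
        np.testing.assert_allclose(out.X[1], 0.0, atol=1e-15)

    def test_cohort_counts(self, default_cohort):
        cfg, m, meta, truth = default_cohort
        known = m.select_samples([r.sample_id for r in meta if r.cohort == "known"])
        assert average_replicates(known).n_spectra == 20
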