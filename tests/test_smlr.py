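import numpy as np
import pytest

from nircal import (
    AbsorbanceMatrix,
    GeneratorConfig,
    fit_ols,
    generate_dataset,
    partial_f_test,
    predict,
    smlr_fit,
    to_absorbance,
)
from nircal.datasets import recovery_study_config
from nircal.errors import (
    CollinearDesignError,
    InvalidParametersError,
    ModelMismatchError,
)


def _matrix(values, wavelengths=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavelengths is None:
        wavelengths = 1000.0 + np.arange(values.shape[1], dtype=float)
    return AbsorbanceMatrix(values, wavelengths)


class TestOLS:
    def test_exact_affine_recovery(self, rng):
        x = rng.normal(size=(20, 1))
        y = 2.5 + 1.75 * x[:, 0]
        fit = fit_ols(x, y)
        assert fit.intercept == pytest.approx(2.5, abs=1e-10)
        assert fit.coefficients[0] == pytest.approx(1.75, abs=1e-10)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(size=15)
        fit = fit_ols(np.empty((15, 0)), y)
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        fit = fit_ols(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], ref.params, atol=1e-8
        )
        np.testing.assert_allclose(
            np.r_[fit.se_intercept, fit.se_coefficients], ref.bse, atol=1e-8
        )
        np.testing.assert_allclose(
            fit.coefficient_p_values(), ref.pvalues[1:], atol=1e-8
        )

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=(12, 2))
        design = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.raises(CollinearDesignError):
            fit_ols(design, rng.normal(size=12))


class TestPartialF:
    def test_orthogonal_candidate(self, rng):
        x = rng.normal(size=(40, 2))
        y = 1.0 + x @ [2.0, -1.0] + rng.normal(size=40)
        fit = fit_ols(x, y)
        resid = y - fit.intercept - x @ fit.coefficients
        # candidate orthogonal to the residual and to the design
        z = rng.normal(size=40)
        basis = np.column_stack([np.ones(40), x, resid])
        z -= basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        f, p = partial_f_test(x, z, y)
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_residual_candidate_is_perfect(self, rng):
        x = rng.normal(size=(25, 2))
        y = x @ [1.0, 2.0] + rng.normal(size=25)
        fit = fit_ols(x, y)
        resid = y - fit.intercept - x @ fit.coefficients
        f, p = partial_f_test(x, resid, y)
        assert np.isinf(f) and p == 0.0

    def test_equals_squared_t_in_enlarged_fit(self, rng):
        for _ in range(20):
            x = rng.normal(size=(25, 3))
            z = rng.normal(size=25)
            y = rng.normal(size=25)
            f, p = partial_f_test(x, z, y)
            enlarged = fit_ols(np.column_stack([x, z]), y)
            t = enlarged.coefficients[-1] / enlarged.se_coefficients[-1]
            assert f == pytest.approx(t**2, abs=1e-8)


class TestStepwise:
    def test_single_informative_channel(self, rng):
        x = rng.normal(size=(20, 8))
        y = 4.0 + 3.0 * x[:, 5]
        model = smlr_fit(_matrix(x), y)
        assert [k for k, _, _ in model.terms] == [5]
        assert model.intercept == pytest.approx(4.0, abs=1e-8)

    def test_null_response_gives_intercept_only(self):
        """Channels of a real (mutually correlated) spectrum against a
        permuted response: no term should enter in >= 90% of runs."""
        hits = 0
        for seed in range(50):
            ds, _ = generate_dataset(GeneratorConfig(seed=seed))
            mat = to_absorbance(
                ds.transflectance.mean(axis=1), ds.wavelengths
            )
            j0 = int(np.argmin(np.abs(ds.wavelengths - 1950.0)))
            x = mat.values[:, j0 : j0 + 20]
            y = np.random.default_rng(seed).permutation(ds.concentrations)
            model = smlr_fit(x, y)
            hits += model.n_terms == 0 and model.intercept_only_warning
        assert hits >= 45

    def test_noiseless_recovery_is_exact(self, noiseless_config):
        """With every disturbance off, the planted three-band design is
        recovered with zero residual (one channel per compound group)."""
        cfg = noiseless_config.with_(band_weight_sd=0.2)
        ds, truth = generate_dataset(cfg)
        mat = to_absorbance(ds.transflectance[:, 0, :], ds.wavelengths)
        x = mat.values[:, truth.band_center_channels]
        model = smlr_fit(x, ds.concentrations, p_enter=0.05, p_remove=0.10)
        assert model.n_terms == 3
        pred = model.intercept + x[:, [k for k, _, _ in model.terms]] @ [
            b for _, _, b in model.terms
        ]
        np.testing.assert_allclose(pred, ds.concentrations, atol=1e-6)

    def test_enter_threshold_zero_blocks_everything(self, rng):
        x = rng.normal(size=(15, 6))
        y = 3.0 * x[:, 0] + rng.normal(size=15)
        model = smlr_fit(x, y, p_enter=0.0, p_remove=0.5)
        assert model.n_terms == 0

    def test_greedy_until_df_exhaustion(self, rng):
        """p_enter = p_remove = 1 adds until N - m - 1 would drop below 2."""
        n = 12
        x = rng.normal(size=(n, 30))
        y = rng.normal(size=n)
        model = smlr_fit(x, y, p_enter=1.0, p_remove=1.0)
        assert model.n_terms == n - 3

    def test_threshold_ordering_enforced(self, rng):
        with pytest.raises(InvalidParametersError):
            smlr_fit(rng.normal(size=(10, 3)), rng.normal(size=10),
                     p_enter=0.5, p_remove=0.1)

    def test_forward_rss_non_increasing(self, rng):
        x = rng.normal(size=(20, 10))
        y = x @ rng.normal(size=10) + rng.normal(size=20)
        model = smlr_fit(x, y, p_enter=0.9, p_remove=0.95)
        rss = [t["rss"] for t in model.trace if t["action"] == "add"]
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))

    def test_entry_decisions_match_exhaustive_oracle(self, rng):
        """On 5-channel instances, replay the trace and verify every entry
        was the smallest-p candidate among all channels not yet included."""
        for _ in range(10):
            x = rng.normal(size=(14, 5))
            y = x @ rng.normal(size=5) + 0.5 * rng.normal(size=14)
            model = smlr_fit(x, y, p_enter=0.3, p_remove=0.35)
            included = []
            for step in model.trace:
                if step["action"] != "add":
                    included.remove(step["channel"])
                    continue
                best = None
                for k in range(5):
                    if k in included:
                        continue
                    f, p = partial_f_test(x[:, included], x[:, k], y)
                    key = (p, -f, k)
                    if best is None or key < best:
                        best = key
                assert best[2] == step["channel"]
                assert best[0] == pytest.approx(step["p"], abs=1e-9)
                included.append(step["channel"])

    def test_recovery_study_localizes_to_planted_bands(self):
        """On the high-SNR recovery fixture the first three selected
        wavelengths each land inside a distinct planted band support."""
        from nircal import PipelineConfig, run_pipeline

        centers = np.array([1830.0, 1917.0, 2189.0])
        step = 1700.0 / 920.0
        good = 0
        for seed in range(20):
            ds, _ = generate_dataset(recovery_study_config(seed))
            res = run_pipeline(ds, PipelineConfig())
            adds = [t["wavelength"] for t in res.model.trace if t["action"] == "add"][:3]
            if len(adds) < 3:
                continue
            nearest = [int(np.argmin(np.abs(centers - w))) for w in adds]
            offsets = [abs(w - centers[b]) / step for w, b in zip(adds, nearest)]
            good += len(set(nearest)) == 3 and max(offsets) <= 8.0
        assert good >= 16


class TestPredict:
    def test_intercept_only_constant(self, rng):
        model = smlr_fit(rng.normal(size=(10, 3)), np.zeros(10), p_enter=0.0, p_remove=0.5)
        out = predict(model, _matrix(rng.normal(size=(4, 3))))
        np.testing.assert_allclose(out, model.intercept)

    def test_training_predictions_exact_for_perfect_fit(self, rng):
        x = rng.normal(size=(15, 4))
        y = 1.0 + x @ [0.0, 2.0, 0.0, -1.0]
        mat = _matrix(x)
        model = smlr_fit(mat, y)
        np.testing.assert_allclose(predict(model, mat), y, atol=1e-8)

    def test_linearity_in_spectra(self, rng):
        x1, x2 = rng.normal(size=(2, 6, 5))
        y = 2.0 * x1[:, 1][:1]  # irrelevant; build model from x1
        mat1 = _matrix(x1)
        model = smlr_fit(mat1, 1.0 + 2.0 * x1[:, 2])
        alpha = 0.3
        mixed = predict(model, _matrix(alpha * x1 + (1 - alpha) * x2))
        split = alpha * predict(model, mat1) + (1 - alpha) * predict(model, _matrix(x2))
        np.testing.assert_allclose(mixed, split, atol=1e-9)

    def test_missing_wavelength_rejected(self, rng):
        x = rng.normal(size=(12, 4))
        model = smlr_fit(_matrix(x), 2.0 * x[:, 0])
        other = AbsorbanceMatrix(rng.normal(size=(3, 2)), np.array([1.0, 2.0]))
        with pytest.raises(ModelMismatchError):
            predict(model, other)
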