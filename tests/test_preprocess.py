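import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nircal import (
    AbsorbanceMatrix,
    GeneratorConfig,
    cv_per_wavelength,
    generate_dataset,
    msc,
    msc_coefficients,
    remove_noisy_bands,
    savitzky_golay,
    sg_coefficients,
    snv,
    to_absorbance,
)
from nircal.errors import (
    DegenerateSpectrumError,
    DivisionDegenerateError,
    InvalidParametersError,
    NonPositiveSignalError,
)


def _matrix(values, wavelengths=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavelengths is None:
        wavelengths = 1000.0 + np.arange(values.shape[1], dtype=float)
    return AbsorbanceMatrix(values, wavelengths)


class TestAbsorbance:
    @pytest.mark.parametrize(
        "x,expected", [(1.0, 0.0), (0.01, 2.0), (200.0, -np.log10(200.0))]
    )
    def test_log_reciprocal(self, x, expected):
        out = to_absorbance(np.array([[x]]), np.array([1500.0]))
        assert out.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_signal_names_indices(self):
        with pytest.raises(NonPositiveSignalError, match=r"\[1, 1\]"):
            to_absorbance(np.array([[1.0, 2.0], [3.0, 0.0]]), np.array([1.0, 2.0]))


class TestCV:
    def test_constant_replicates_zero(self, default_dataset):
        ds, _ = default_dataset
        from nircal.datasets import SpectraDataset

        const = ds.transflectance.copy()
        const[:] = const[:, :1, :]
        cv = cv_per_wavelength(SpectraDataset(const, ds.wavelengths, ds.concentrations))
        assert np.all(cv < 1e-10)

    def test_known_cv_value(self):
        """Replicates engineered to mean 100, SD 10 give CV = 10% there."""
        from nircal.datasets import SpectraDataset

        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=5)
        base = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1 exactly
        t = np.full((3, 5, 2), 50.0)
        t[:, :, 0] = 100.0 + 10.0 * base
        ds = SpectraDataset(t, np.array([1000.0, 1001.0]), np.arange(3.0))
        cv = cv_per_wavelength(ds)
        assert cv[0] == pytest.approx(10.0, abs=1e-9)
        assert cv[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, default_dataset):
        ds, _ = default_dataset
        cv = cv_per_wavelength(ds)
        t = ds.transflectance
        acc = np.zeros(t.shape[2])
        for v in range(t.shape[2]):
            per_sample = []
            for i in range(t.shape[0]):
                per_sample.append(
                    100.0 * t[i, :, v].std(ddof=1) / t[i, :, v].mean()
                )
            acc[v] = np.mean(per_sample)
        np.testing.assert_allclose(cv, acc, atol=1e-10)

    def test_zero_mean_rejected(self):
        from nircal.datasets import SpectraDataset

        t = np.full((1, 2, 1), 1.0)
        t[0, :, 0] = [1.0, 1.0]
        ds = SpectraDataset(t, np.array([1000.0]), np.array([1.0]))
        ds.transflectance = np.array([[[1.0], [-1.0]]])  # bypass positivity
        with pytest.raises(DivisionDegenerateError):
            cv_per_wavelength(ds)


class TestBandFilter:
    def test_threshold_is_mean(self):
        res = remove_noisy_bands(np.array([1.0, 1.0, 10.0]))
        assert res.threshold == pytest.approx(4.0)
        assert res.retained_mask.tolist() == [True, True, False]

    def test_all_equal_keeps_everything(self):
        res = remove_noisy_bands(np.full(5, 3.3))
        assert res.retained_mask.all()

    def test_planted_noisy_band_recovered(self):
        """The 2240-2600 nm band planted at 10x noise is removed exactly."""
        hits = 0
        for seed in range(10):
            ds, truth = generate_dataset(GeneratorConfig(seed=seed))
            res = remove_noisy_bands(cv_per_wavelength(ds))
            hits += np.array_equal(res.removed_indices, truth.planted_noisy_channels)
        assert hits >= 9


class TestSNV:
    def test_three_point_row(self):
        out = snv(_matrix([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.values[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_rows_standardized(self, rng):
        out = snv(_matrix(rng.normal(size=(6, 40))))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_constant_row_rejected(self):
        with pytest.raises(DegenerateSpectrumError, match="0"):
            snv(_matrix(np.ones(5)))

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=(1, 30))
        out = snv(_matrix(x))
        expected = (x[0] - x[0].mean()) / x[0].std(ddof=1)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)

    def test_idempotent(self, rng):
        m = _matrix(rng.normal(size=(4, 50)))
        once = snv(m)
        twice = snv(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)

    @settings(max_examples=40, derandomize=True)
    @given(
        alpha=st.floats(0.1, 50.0),
        beta=st.floats(-100.0, 100.0),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, alpha, beta, seed):
        """SNV output does not change under x -> alpha*x + beta, alpha > 0."""
        x = np.random.default_rng(seed).normal(size=(1, 25))
        base = snv(_matrix(x)).values
        shifted = snv(_matrix(alpha * x + beta)).values
        np.testing.assert_allclose(shifted, base, atol=1e-7)


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.normal(size=30)
        m = _matrix(np.vstack([ref, ref + 1.0]))
        a, b, _ = msc_coefficients(m, reference=ref)
        assert a[0] == pytest.approx(0.0, abs=1e-10)
        assert b[0] == pytest.approx(1.0, abs=1e-10)
        out = msc(m, reference=ref)
        np.testing.assert_allclose(out.values[0], ref, atol=1e-10)

    def test_affine_row_inverted(self, rng):
        ref = rng.normal(size=40)
        m = _matrix(np.vstack([ref, 3.0 + 2.0 * ref]))
        out = msc(m, reference=ref)
        np.testing.assert_allclose(out.values[1], ref, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=(8, 60))
        m = _matrix(x)
        a, b, ref = msc_coefficients(m)
        for i in range(8):
            design = np.column_stack([np.ones(60), ref])
            coef = np.linalg.solve(design.T @ design, design.T @ x[i])
            assert a[i] == pytest.approx(coef[0], abs=1e-10)
            assert b[i] == pytest.approx(coef[1], abs=1e-10)

    def test_idempotent_with_fixed_reference(self, rng):
        x = rng.normal(size=(5, 50))
        m = _matrix(x)
        ref = x.mean(axis=0)
        once = msc(m, reference=ref)
        twice = msc(once, reference=ref)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)


class TestSavitzkyGolay:
    def test_smoothing_coefficients_window5(self):
        """Quadratic smoothing over 5 points has the classical weights."""
        np.testing.assert_allclose(
            sg_coefficients(5, 2, 0), np.array([-3, 12, 17, 12, -3]) / 35.0, atol=1e-12
        )

    def test_coefficients_match_design_matrix_oracle(self):
        """Convolution weights equal the first row of the polynomial
        least-squares hat matrix, for several window/degree/derivative."""
        from math import factorial

        for window, degree, deriv in [(5, 2, 0), (7, 2, 1), (11, 2, 1), (9, 3, 2)]:
            half = window // 2
            z = np.arange(-half, half + 1, dtype=float)
            design = np.vander(z, degree + 1, increasing=True)
            pinv = np.linalg.pinv(design)
            expected = pinv[deriv] * factorial(deriv)
            np.testing.assert_allclose(
                sg_coefficients(window, degree, deriv), expected, atol=1e-10
            )

    def test_first_derivative_of_ramp(self):
        x = np.arange(30.0) * 2.5
        out = savitzky_golay(_matrix(x), 11, 2, 1)
        np.testing.assert_allclose(out.values[0], 2.5, atol=1e-10)

    def test_quadratic_reproduced_by_smoothing(self):
        t = np.arange(40.0)
        x = 0.3 * t**2 - 2.0 * t + 5.0
        out = savitzky_golay(_matrix(x), 9, 2, 0)
        np.testing.assert_allclose(out.values[0], x[4:-4], atol=1e-10)

    def test_edges_dropped(self, rng):
        m = _matrix(rng.normal(size=(3, 50)))
        out = savitzky_golay(m, 11, 2, 1)
        assert out.values.shape == (3, 40)
        np.testing.assert_array_equal(out.wavelengths, m.wavelengths[5:-5])

    def test_full_degree_smoothing_is_identity(self, rng):
        x = rng.normal(size=(2, 30))
        out = savitzky_golay(_matrix(x), 5, 4, 0)
        np.testing.assert_allclose(out.values, x[:, 2:-2], atol=1e-8)

    @pytest.mark.parametrize("window,degree,deriv", [(4, 2, 1), (5, 5, 0), (5, 2, 3)])
    def test_invalid_parameters(self, window, degree, deriv):
        with pytest.raises(InvalidParametersError):
            sg_coefficients(window, degree, deriv)


def test_operators_are_row_local(rng):
    """Permuting sample order permutes outputs identically."""
    x = rng.normal(size=(6, 40))
    perm = rng.permutation(6)
    for op in (snv, lambda m: savitzky_golay(m, 5, 2, 1)):
        direct = op(_matrix(x)).values[perm]
        permuted = op(_matrix(x[perm])).values
        np.testing.assert_allclose(direct, permuted, atol=1e-12)
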