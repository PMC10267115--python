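"""Regression-DCM core: frequency transform, design construction, and the
variational inversion, each checked against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crossconn.datatypes import RoiTimeSeries
from crossconn.rdcm import (
    RdcmPrior,
    build_region_regression,
    invert_rdcm,
    invert_region,
    to_frequency_domain,
)


def _ts(data, tr=2.0):
    data = np.asarray(data, float)
    return RoiTimeSeries(data, tr, [f"r{i}" for i in range(data.shape[1])])


def naive_dft(x):
    """O(T^2) direct-summation DFT, the oracle for the fft-based transform."""
    T = len(x)
    m = np.arange(T)
    return np.array([np.sum(x * np.exp(-2j * np.pi * k * m / T)) for k in range(T)])


class TestFrequencyTransform:
    def test_matches_naive_dft_and_derivative_operator(self, rng):
        T, tr = 32, 2.0
        data = rng.normal(size=(T, 2))
        spectra, targets, _ = to_frequency_domain(_ts(data, tr))
        for j in range(2):
            x = data[:, j] - data[:, j].mean()
            ref = naive_dft(x)
            np.testing.assert_allclose(spectra[:, j], ref, atol=1e-9)
            d = (np.exp(2j * np.pi * np.arange(T) / T) - 1.0) / tr
            np.testing.assert_allclose(targets[:, j], ref * d, atol=1e-9)

    def test_constant_series_has_empty_spectrum(self):
        data = np.column_stack([np.full(16, 3.7), np.arange(16.0)])
        spectra, targets, _ = to_frequency_domain(_ts(data))
        np.testing.assert_allclose(spectra[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(targets[:, 0], 0.0, atol=1e-12)

    def test_sinusoid_energy_at_its_own_bin(self):
        T, tr, cycles = 64, 2.0, 4
        t = np.arange(T)
        data = np.column_stack([np.sin(2 * np.pi * cycles * t / T), np.cos(t)])
        spectra, targets, _ = to_frequency_domain(_ts(data, tr))
        mags = np.abs(targets[:, 0])
        assert set(np.argsort(mags)[-2:]) == {cycles, T - cycles}

    @given(st.integers(0, 2**32 - 1))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(24, 3)), r.normal(size=(24, 3))
        sx, tx, _ = to_frequency_domain(_ts(x))
        sy, ty, _ = to_frequency_domain(_ts(y))
        sxy, txy, _ = to_frequency_domain(_ts(x + y))
        np.testing.assert_allclose(sxy, sx + sy, atol=1e-8)
        np.testing.assert_allclose(txy, tx + ty, atol=1e-8)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="8"):
            to_frequency_domain(_ts(np.random.default_rng(0).normal(size=(6, 1))))


class TestRegressionConstruction:
    def test_single_region_design_is_stacked_spectrum(self, rng):
        data = rng.normal(size=(16, 1))
        spectra, targets, keep = to_frequency_domain(_ts(data))
        design, response = build_region_regression(spectra, targets, 0, keep)
        np.testing.assert_allclose(
            design[:, 0],
            np.concatenate([spectra[keep, 0].real, spectra[keep, 0].imag]),
        )
        assert response.shape == (design.shape[0],)

    def test_noise_free_identity_ols_recovers_generator(self, rng):
        # Spectra drawn freely; derivative targets defined exactly by the
        # coupling relation. Ordinary least squares must then return the
        # generating matrix row by row to machine precision.
        A = np.array([[-0.5, 0.2, -0.1], [0.0, -0.4, 0.3], [0.1, -0.2, -0.6]])
        spectra = rng.normal(size=(20, 3)) + 1j * rng.normal(size=(20, 3))
        targets = spectra @ A.T
        keep = np.ones(20, bool)
        for i in range(3):
            design, response = build_region_regression(spectra, targets, i, keep)
            coef, *_ = np.linalg.lstsq(design, response, rcond=None)
            np.testing.assert_allclose(coef, A[i], atol=1e-9)

    def test_region_permutation_permutes_columns(self, rng):
        data = rng.normal(size=(32, 4))
        perm = [2, 0, 3, 1]
        s1, t1, keep = to_frequency_domain(_ts(data))
        s2, t2, _ = to_frequency_domain(_ts(data[:, perm]))
        d1, _ = build_region_regression(s1, t1, 0, keep)
        d2, _ = build_region_regression(s2, t2, 0, keep)
        np.testing.assert_allclose(d2, d1[:, perm], atol=1e-10)

    def test_empty_keep_mask_rejected(self, rng):
        data = rng.normal(size=(16, 2))
        spectra, targets, _ = to_frequency_domain(_ts(data))
        with pytest.raises(ValueError, match="keep_mask"):
            build_region_regression(spectra, targets, 0, np.zeros(16, bool))


class TestVariationalInversion:
    def test_tight_prior_pins_posterior_to_prior_mean(self, rng):
        design = rng.normal(size=(50, 3))
        response = rng.normal(size=50)
        prior = RdcmPrior(mean_offdiag=0.3, var_offdiag=1e-12,
                          mean_self=-0.7, var_self=1e-12)
        post = invert_region(design, response, prior, self_index=1)
        np.testing.assert_allclose(post.mean, [0.3, -0.7, 0.3], atol=1e-6)

    def test_fixed_tau_matches_ridge_closed_form(self, rng):
        # With the Gamma posterior pinned at tau0 the weight posterior is the
        # conjugate Gaussian; compare against the ridge solution computed
        # independently.
        design = rng.normal(size=(40, 4))
        response = rng.normal(size=40)
        tau0 = 2.7
        prior = RdcmPrior(tau_shape=1e8, tau_rate=1e8 / tau0)
        post = invert_region(design, response, prior, self_index=2)
        mu0, v0 = prior.vectors(4, 2)
        p0 = np.diag(1.0 / v0)
        expected = np.linalg.solve(
            p0 + tau0 * design.T @ design,
            p0 @ mu0 + tau0 * design.T @ response,
        )
        np.testing.assert_allclose(post.mean, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_free_energy_nondecreasing(self, seed):
        r = np.random.default_rng(seed)
        design = r.normal(size=(30, 5))
        response = design @ r.normal(size=5) + r.normal(size=30)
        post = invert_region(design, response, RdcmPrior(), self_index=0)
        f = np.array(post.free_energy_history)
        assert np.all(np.diff(f) >= -1e-6)
        assert post.converged

    def test_posterior_covariance_symmetric_positive_definite(self, rng):
        design = rng.normal(size=(30, 4))
        response = rng.normal(size=30)
        post = invert_region(design, response, RdcmPrior(), self_index=0)
        np.testing.assert_allclose(post.covariance, post.covariance.T)
        assert np.all(np.linalg.eigvalsh(post.covariance) > 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            invert_region(np.array([[np.nan]]), np.array([1.0]), RdcmPrior())


class TestWholeBrainInversion:
    def test_region_permutation_equivariance(self, rng):
        data = rng.normal(size=(80, 5))
        perm = np.array([3, 1, 4, 0, 2])
        a1 = invert_rdcm(_ts(data)).a
        a2 = invert_rdcm(_ts(data[:, perm])).a
        np.testing.assert_allclose(a2, a1[np.ix_(perm, perm)], atol=1e-8)

    def test_invariant_under_common_rescaling(self, rng):
        data = rng.normal(size=(60, 4))
        a1 = invert_rdcm(_ts(data)).a
        a2 = invert_rdcm(_ts(data * 37.5)).a
        np.testing.assert_allclose(a1, a2, atol=1e-10)

    def test_self_connections_negative_on_simulated_data(self, small_study):
        ec = invert_rdcm(small_study.sessions[0])
        assert np.all(np.diag(ec.a) < 0)

    def test_connectome_rows_are_region_posterior_means(self, rng):
        data = rng.normal(size=(40, 3))
        ec = invert_rdcm(_ts(data))
        for i, post in enumerate(ec.per_region):
            np.testing.assert_array_equal(ec.a[i], post.mean)
        assert ec.n_parameters == 9
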