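"""Noise-covariance estimation, shrinkage, spatial filters and readout."""

import numpy as np
import pytest

from cuedmotion.containers import LOCALIZER_DIRECTIONS, angular_difference
from cuedmotion.decoder import (
    DegenerateCovarianceError,
    apply_decoder,
    build_filters,
    decode_channels,
    demean_training,
    estimate_noise_cov,
    readout_direction,
    shrink,
    train_decoder,
)
from cuedmotion.encoding import channel_amplitudes, fit_weights


def _training_set(basis, n_sensors=10, n_trials=120, noise=0.5, seed=3):
    rng = np.random.default_rng(seed)
    dirs = rng.choice(LOCALIZER_DIRECTIONS, n_trials)
    C = channel_amplitudes(basis, dirs)
    W_true = rng.standard_normal((n_sensors, basis.n_channels))
    B = W_true @ C + noise * rng.standard_normal((n_sensors, n_trials))
    return B, C, W_true


class TestDemean:
    def test_zero_mean_rows_and_idempotence(self, basis):
        B, C, _ = _training_set(basis)
        dem = demean_training(B, C)
        assert np.allclose(dem.B0.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(dem.C0.mean(axis=1), 0.0, atol=1e-12)
        again = demean_training(dem.B0, dem.C0)
        assert np.allclose(again.B0, dem.B0)
        assert np.allclose(again.b_mean, 0.0, atol=1e-12)

    def test_constant_row_becomes_zero(self, basis):
        B, C, _ = _training_set(basis)
        B[2] = 4.2
        assert np.allclose(demean_training(B, C).B0[2], 0.0)


class TestNoiseCov:
    def test_matches_two_pass_loop_oracle(self, basis):
        B, C, _ = _training_set(basis, n_sensors=6, n_trials=40)
        dem = demean_training(B, C)
        weights = fit_weights(dem.B0, dem.C0)
        ncov = estimate_noise_cov(dem, weights)
        n = dem.B0.shape[1]
        for i in (0, 7, 20):  # brute-force residual covariance
            E = np.empty_like(dem.B0)
            for t in range(n):
                E[:, t] = dem.B0[:, t] - weights.W[:, i] * dem.C0[i, t]
            sigma = np.zeros((6, 6))
            for t in range(n):
                sigma += np.outer(E[:, t], E[:, t])
            assert np.allclose(ncov.sigmas[i], sigma / (n - 1))

    def test_rank_one_noise_free_residual_is_zero(self, basis):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(8)
        c = rng.standard_normal(50)
        B = np.outer(w, c)
        C = np.zeros((basis.n_channels, 50))
        C[4] = c
        dem_B0 = B - B.mean(axis=1, keepdims=True)
        dem_c = C - C.mean(axis=1, keepdims=True)
        from cuedmotion.decoder import Demeaned
        from cuedmotion.encoding import EncodingWeights

        W = np.zeros((8, basis.n_channels))
        W[:, 4] = w
        ncov = estimate_noise_cov(
            Demeaned(dem_B0, dem_c, B.mean(axis=1), C.mean(axis=1)),
            EncodingWeights(W, "per_channel", 50),
        )
        assert np.allclose(ncov.sigmas[4], 0.0, atol=1e-20)

    def test_white_noise_converges_to_scaled_identity(self, basis):
        rng = np.random.default_rng(5)
        n, p, sig = 20000, 4, 1.5
        C = channel_amplitudes(basis, rng.choice(LOCALIZER_DIRECTIONS, n))
        B = sig * rng.standard_normal((p, n))  # no signal at all
        dem = demean_training(B, C)
        weights = fit_weights(dem.B0, dem.C0)
        ncov = estimate_noise_cov(dem, weights)
        assert np.allclose(ncov.sigmas[0], sig**2 * np.eye(p), atol=0.1)

    def test_all_channels_mode_removes_full_prediction(self, basis):
        B, C, _ = _training_set(basis)
        dem = demean_training(B, C)
        weights = fit_weights(dem.B0, dem.C0, fit_mode="joint")
        ncov = estimate_noise_cov(dem, weights, residual_mode="all_channels")
        E = dem.B0 - weights.W @ dem.C0
        expected = E @ E.T / (dem.B0.shape[1] - 1)
        assert np.allclose(ncov.sigmas[0], expected)
        assert np.allclose(ncov.sigmas[10], expected)


class TestShrinkage:
    def _ncov(self, basis, n_trials=40, n_sensors=10):
        B, C, _ = _training_set(basis, n_sensors=n_sensors, n_trials=n_trials)
        dem = demean_training(B, C)
        weights = fit_weights(dem.B0, dem.C0)
        return estimate_noise_cov(dem, weights)

    def test_forced_full_shrinkage_gives_scaled_identity(self, basis):
        ncov = self._ncov(basis)
        sigmas, lams, nus = shrink(ncov, lambda_=1.0)
        p = sigmas.shape[1]
        for i in (0, 5):
            assert np.allclose(sigmas[i], nus[i] * np.eye(p))

    def test_forced_zero_shrinkage_is_identity_operation(self, basis):
        ncov = self._ncov(basis)
        sigmas, lams, _ = shrink(ncov, lambda_=0.0)
        assert np.allclose(sigmas, ncov.sigmas)

    def test_singular_sample_covariance_becomes_well_conditioned(self, basis):
        ncov = self._ncov(basis, n_trials=25, n_sensors=40)  # n < p
        raw_eigs = np.linalg.eigvalsh(ncov.sigmas[0])
        assert raw_eigs.min() < 1e-10  # rank-deficient
        sigmas, lams, _ = shrink(ncov)
        eigs = np.linalg.eigvalsh(sigmas[0])
        assert eigs.min() > 0 and lams[0] > 0
        assert eigs.max() / eigs.min() < 1e4

    def test_condition_number_monotone_in_lambda(self, basis):
        ncov = self._ncov(basis)
        conds = []
        for lam in (0.0, 0.2, 0.5, 0.8, 1.0):
            sigmas, _, _ = shrink(ncov, lambda_=lam)
            conds.append(np.linalg.cond(sigmas[3]))
        assert all(a >= b - 1e-9 for a, b in zip(conds, conds[1:]))

    def test_matches_sklearn_intensity(self, basis):
        from sklearn.covariance import ledoit_wolf_shrinkage

        ncov = self._ncov(basis)
        _, lams, _ = shrink(ncov)
        for i in (0, 11):
            expected = ledoit_wolf_shrinkage(ncov.residuals[i].T, assume_centered=True)
            assert lams[i] == pytest.approx(float(expected))

    def test_zero_residuals_raise(self, basis):
        ncov = self._ncov(basis)
        ncov.sigmas[:] = 0.0
        with pytest.raises(DegenerateCovarianceError):
            shrink(ncov)


class TestFilters:
    def test_identity_covariance_gives_normalized_matched_filter(self, basis):
        B, C, _ = _training_set(basis)
        dem = demean_training(B, C)
        weights = fit_weights(dem.B0, dem.C0)
        k, p = basis.n_channels, B.shape[0]
        filters = build_filters(weights, np.broadcast_to(np.eye(p), (k, p, p)))
        for i in range(k):
            w = weights.W[:, i]
            assert np.allclose(filters.V[:, i], w / (w @ w))

    def test_normalization_contract_unit_gain_on_own_pattern(self, basis):
        B, C, _ = _training_set(basis)
        dem = demean_training(B, C)
        weights = fit_weights(dem.B0, dem.C0)
        ncov = estimate_noise_cov(dem, weights)
        sigmas, lams, nus = shrink(ncov)
        filters = build_filters(weights, sigmas, lams, nus)
        gains = np.einsum("si,si->i", filters.V, weights.W)
        assert np.allclose(gains, 1.0)
        # consequence: decoding a channel's own pattern returns 1 there
        est = decode_channels(filters, weights.W)
        assert np.allclose(np.diag(est), 1.0)

    def test_noise_aware_filter_snr_at_least_matched_filter(self, basis):
        # strongly correlated noise: covariance-aware filtering must not lose
        rng = np.random.default_rng(8)
        p = 12
        w = rng.standard_normal(p)
        idx = np.arange(p)
        cov = 0.95 ** np.abs(idx[:, None] - idx[None, :])
        chol = np.linalg.cholesky(cov)
        noise = chol @ rng.standard_normal((p, 4000))
        sigma = np.cov(noise)
        from cuedmotion.encoding import EncodingWeights

        W = np.tile(w[:, None], (1, basis.n_channels))
        weights = EncodingWeights(W, "per_channel", 4000)
        sigmas = np.broadcast_to(sigma, (basis.n_channels, p, p)).copy()
        filt = build_filters(weights, sigmas)
        v = filt.V[:, 0]
        snr_v = (v @ w) ** 2 / (v @ cov @ v)
        m = w / (w @ w)
        snr_m = (m @ w) ** 2 / (m @ cov @ m)
        assert snr_v >= snr_m

    def test_sensor_mismatch_error_names_counts(self, basis):
        B, C, _ = _training_set(basis)
        model = train_decoder(B, np.random.default_rng(0).choice(LOCALIZER_DIRECTIONS, B.shape[1]), basis)
        with pytest.raises(ValueError, match="10.*12|12.*10"):
            decode_channels(model.filters, np.zeros((12, 5)))


class TestReadout:
    def test_one_hot_estimate_decodes_to_center(self, basis):
        for k in (0, 10, 20):
            est = np.zeros((basis.n_channels, 1))
            est[k] = 1.0
            dec, flags = readout_direction(est, basis)
            assert not flags[0]
            assert abs(angular_difference(dec[0], basis.centers[k], 180)) <= basis.readout_grid_step

    def test_two_adjacent_equal_weights_decode_to_midpoint(self, basis):
        est = np.zeros((basis.n_channels, 1))
        est[7] = est[8] = 1.0
        dec, _ = readout_direction(est, basis)
        mid = 0.5 * (basis.centers[7] + basis.centers[8])
        assert abs(dec[0] - mid) <= basis.readout_grid_step

    def test_matches_fine_grid_bruteforce_argmax(self, basis):
        rng = np.random.default_rng(2)
        est = rng.random((basis.n_channels, 6))
        dec, _ = readout_direction(est, basis)
        fine = np.arange(-45.0, 135.0, 0.001)  # refinement oracle
        F = basis.evaluate(fine)
        ref = fine[np.argmax(F.T @ est, axis=0)]
        assert np.all(np.abs(angular_difference(dec, ref, 180)) <= basis.readout_grid_step)

    def test_scale_invariance(self, basis):
        rng = np.random.default_rng(4)
        est = rng.random((basis.n_channels, 8))
        d1, _ = readout_direction(est, basis)
        d2, _ = readout_direction(17.3 * est, basis)
        assert np.array_equal(d1, d2)

    def test_flat_curve_flagged_and_returns_midpoint(self, basis):
        with pytest.warns(RuntimeWarning, match="flat"):
            dec, flags = readout_direction(np.zeros((basis.n_channels, 2)), basis)
        assert flags.all()
        assert np.allclose(dec, 45.0)

    def test_decode_additivity(self, basis):
        B, C, _ = _training_set(basis)
        dirs = np.random.default_rng(0).choice(LOCALIZER_DIRECTIONS, B.shape[1])
        model = train_decoder(B, dirs, basis)
        b1 = np.random.default_rng(1).standard_normal((B.shape[0], 5))
        b2 = np.random.default_rng(2).standard_normal((B.shape[0], 5))
        e12 = decode_channels(model.filters, b1 + b2)
        assert np.allclose(e12, decode_channels(model.filters, b1) + decode_channels(model.filters, b2))


class TestEndToEnd:
    def test_noise_free_training_patterns_recover_directions(self, basis):
        rng = np.random.default_rng(9)
        dirs = rng.choice(LOCALIZER_DIRECTIONS, 120)
        C = channel_amplitudes(basis, dirs)
        W_true = rng.standard_normal((16, basis.n_channels))
        B = W_true @ C
        model = train_decoder(B, dirs, basis)
        dec, _ = apply_decoder(model, B)
        err = np.abs(angular_difference(dec, dirs, 180))
        assert err.max() <= 180.0 / 21.0 + basis.readout_grid_step
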