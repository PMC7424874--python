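"""Inversion of the encoding model into noise-aware spatial filters.

The decoder inverts the forward model by, per channel i, estimating the
sensor noise covariance Sigma_i from training residuals, regularizing it by
analytic shrinkage toward a scaled identity, and forming the filter
v_i = (Sigma_i*)^-1 w_i, rescaled to unit gain on the channel's own weight
pattern (v_i . w_i = 1). Filters are collected column-wise into the decoding
matrix V; channel responses of new data are V^T B, and the decoded direction
is the argmax of the channel-weighted sum of basis functions on a dense grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage

from .encoding import BasisSet, EncodingWeights


class DegenerateCovarianceError(ValueError):
    """All-zero residuals: no noise to estimate a covariance from."""


@dataclass
class Demeaned:
    """Trial-demeaned training data with the removed means kept for reuse."""

    B0: np.ndarray
    C0: np.ndarray
    b_mean: np.ndarray  # (sensors,)
    c_mean: np.ndarray  # (channels,)


def demean_training(B: np.ndarray, C: np.ndarray) -> Demeaned:
    """Remove the across-trial mean from every sensor row and channel row."""
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if B.shape[1] != C.shape[1]:
        raise ValueError("B and C must have the same number of trials")
    if B.shape[1] < 2:
        raise ValueError("need at least 2 trials to demean")
    b_mean = B.mean(axis=1)
    c_mean = C.mean(axis=1)
    return Demeaned(B - b_mean[:, None], C - c_mean[:, None], b_mean, c_mean)


@dataclass
class NoiseCovariances:
    """Per-channel residual covariances plus the residuals that produced them.

    ``sigmas[i]`` is the (n-1)-normalized covariance of the channel-i
    residual E_i; residuals are retained because the analytic shrinkage
    intensity is a function of the sample, not of Sigma alone.
    """

    sigmas: np.ndarray  # (channels, sensors, sensors)
    residuals: np.ndarray  # (channels, sensors, trials)
    residual_mode: str = "own_channel"

    @property
    def n_channels(self) -> int:
        return self.sigmas.shape[0]


def estimate_noise_cov(
    dem: Demeaned, weights: EncodingWeights, residual_mode: str = "own_channel"
) -> NoiseCovariances:
    """Estimate the sensor noise covariance Sigma_i for each channel i.

    ``own_channel`` (default): the residual for channel i removes only that
    channel's rank-one prediction, E_i = B0 - w_i c0_i. ``all_channels``:
    the full model prediction is removed, E = B0 - W C0 (identical for all
    channels).
    """
    B0, C0, W = dem.B0, dem.C0, weights.W
    n_trials = B0.shape[1]
    if n_trials < 2:
        raise ValueError("need at least 2 trials to estimate a covariance")
    k = W.shape[1]
    if residual_mode == "own_channel":
        # E[i] = B0 - outer(w_i, c0_i), stacked over channels
        resid = B0[None, :, :] - W.T[:, :, None] * C0[:, None, :]
    elif residual_mode == "all_channels":
        resid = np.broadcast_to(B0 - W @ C0, (k,) + B0.shape).copy()
    else:
        raise ValueError(f"unknown residual_mode {residual_mode!r}")
    sigmas = np.einsum("ipt,iqt->ipq", resid, resid) / (n_trials - 1)
    return NoiseCovariances(sigmas=sigmas, residuals=resid, residual_mode=residual_mode)


def shrink(ncov: NoiseCovariances, lambda_: float | None = None):
    """Shrink each Sigma_i toward nu_i*I with analytic (Ledoit-Wolf) intensity.

    Sigma_i* = (1-lambda_i) Sigma_i + lambda_i nu_i I, nu_i = tr(Sigma_i)/p.
    ``lambda_`` forces a common intensity (0 disables shrinkage, 1 yields the
    scaled identity); by default the intensity is computed per channel from
    the residual sample. Returns ``(sigmas_star, lambdas, nus)``.
    """
    k, p, _ = ncov.sigmas.shape
    sigmas_star = np.empty_like(ncov.sigmas)
    lambdas = np.empty(k)
    nus = np.empty(k)
    for i in range(k):
        sigma = ncov.sigmas[i]
        nu = np.trace(sigma) / p
        if nu <= 0:
            raise DegenerateCovarianceError(f"channel {i}: all-zero residuals")
        if lambda_ is None:
            lam = float(ledoit_wolf_shrinkage(ncov.residuals[i].T, assume_centered=True))
        else:
            lam = float(lambda_)
        lam = min(max(lam, 0.0), 1.0)
        sigmas_star[i] = (1.0 - lam) * sigma + lam * nu * np.eye(p)
        lambdas[i] = lam
        nus[i] = nu
    return sigmas_star, lambdas, nus


@dataclass
class SpatialFilters:
    """Decoding matrix V (sensors x channels) with shrinkage diagnostics."""

    V: np.ndarray
    lambdas: np.ndarray
    nus: np.ndarray
    solver: str = "solve"
    meta: dict = field(default_factory=dict)


def build_filters(
    weights: EncodingWeights, sigmas_star: np.ndarray,
    lambdas: np.ndarray | None = None, nus: np.ndarray | None = None,
    solver: str = "solve",
) -> SpatialFilters:
    """Form v_i = (Sigma_i*)^-1 w_i and normalize to unit own-pattern gain.

    ``solver='pinv'`` uses the Moore-Penrose pseudo-inverse instead of a
    linear solve, the documented fallback when shrinkage is disabled and the
    raw covariance is singular (n_trials < n_sensors).
    """
    W = weights.W
    k = W.shape[1]
    V = np.empty_like(W)
    for i in range(k):
        if solver == "solve":
            v = np.linalg.solve(sigmas_star[i], W[:, i])
        elif solver == "pinv":
            v = np.linalg.pinv(sigmas_star[i], hermitian=True) @ W[:, i]
        else:
            raise ValueError(f"unknown solver {solver!r}")
        gain = v @ W[:, i]
        if gain == 0:
            raise np.linalg.LinAlgError(f"channel {i}: filter has zero gain on its own pattern")
        V[:, i] = v / gain
    return SpatialFilters(
        V=V,
        lambdas=np.zeros(k) if lambdas is None else np.asarray(lambdas, dtype=float),
        nus=np.ones(k) if nus is None else np.asarray(nus, dtype=float),
        solver=solver,
    )


def decode_channels(filters: SpatialFilters, B_test: np.ndarray) -> np.ndarray:
    """Estimated channel responses V^T B_test, shape (channels, trials)."""
    B_test = np.asarray(B_test, dtype=float)
    if B_test.shape[0] != filters.V.shape[0]:
        raise ValueError(
            f"sensor mismatch: filters have {filters.V.shape[0]} sensors, "
            f"data has {B_test.shape[0]}"
        )
    return filters.V.T @ B_test


def readout_direction(estimates: np.ndarray, basis: BasisSet):
    """Decoded direction per trial: argmax of the basis-weighted tuning curve.

    The curve ``sum_i estimate_i f_i(theta)`` is evaluated on a dense grid
    over the design span at ``basis.readout_grid_step``; ties break toward
    the smallest angle (first grid hit). All-zero estimate columns yield the
    span midpoint and are flagged degenerate.

    Returns ``(directions, degenerate)`` arrays of length n_trials.
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    if not np.all(np.isfinite(estimates)):
        raise ValueError("channel estimates must be finite")
    grid = np.arange(basis.span[0], basis.span[1], basis.readout_grid_step)
    F = basis.evaluate(grid)  # (channels, n_grid)
    n = estimates.shape[1]
    decoded = np.empty(n)
    degenerate = np.empty(n, dtype=bool)
    chunk = 4096  # cap the n_trials x n_grid intermediate
    for lo in range(0, n, chunk):
        curves = estimates[:, lo:lo + chunk].T @ F  # (trials, n_grid), row-major argmax
        decoded[lo:lo + chunk] = grid[np.argmax(curves, axis=1)]
        degenerate[lo:lo + chunk] = np.ptp(curves, axis=1) == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} trial(s) produced a flat readout curve; "
            "returning the grid midpoint", RuntimeWarning, stacklevel=2,
        )
        decoded = np.where(degenerate, 0.5 * (basis.span[0] + basis.span[1]), decoded)
    return decoded, degenerate


@dataclass
class DecodingModel:
    """A trained decoder: filters plus the training means needed at test time."""

    basis: BasisSet
    weights: EncodingWeights
    filters: SpatialFilters
    b_mean: np.ndarray
    c_mean: np.ndarray
    meta: dict = field(default_factory=dict)


def train_decoder(
    B: np.ndarray,
    directions,
    basis: BasisSet,
    fit_mode: str = "per_channel",
    residual_mode: str = "own_channel",
    lambda_: float | None = None,
    solver: str = "solve",
) -> DecodingModel:
    """Full training path: demean, fit W, estimate/shrink Sigma_i, build V."""
    from .encoding import channel_amplitudes, fit_weights

    C = channel_amplitudes(basis, directions)
    dem = demean_training(B, C)
    weights = fit_weights(dem.B0, dem.C0, fit_mode=fit_mode)
    ncov = estimate_noise_cov(dem, weights, residual_mode=residual_mode)
    if lambda_ == 0.0 and solver == "solve":
        solver = "pinv"  # raw covariance may be singular
    sigmas_star, lambdas, nus = shrink(ncov, lambda_=lambda_)
    filters = build_filters(weights, sigmas_star, lambdas, nus, solver=solver)
    return DecodingModel(basis=basis, weights=weights, filters=filters,
                         b_mean=dem.b_mean, c_mean=dem.c_mean)


def apply_decoder(model: DecodingModel, B_test: np.ndarray, restore_mean: bool = True):
    """Decode test data with a trained model.

    Test data is demeaned with the *training* sensor means; by default the
    training-mean channel amplitudes are added back to the estimates so the
    readout curve is built from amplitudes on the same scale as the
    hypothesized tuning curves. Returns ``(directions, degenerate)``.
    """
    est = decode_channels(model.filters, np.asarray(B_test, dtype=float) - model.b_mean[:, None])
    if restore_mean:
        est = est + model.c_mean[:, None]
    return readout_direction(est, model.basis)
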