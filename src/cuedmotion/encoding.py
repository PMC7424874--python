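"""Forward encoding model: direction-tuned channel basis and weight estimation.

The encoding model expresses each presented motion direction as the response
of 21 hypothetical direction-tuned channels whose idealized tuning curve is a
half-wave rectified sinusoid raised to the sixth power, with channel centers
evenly spaced over the 180 deg design span [-45, 135). The sensors x channels
weight matrix W mapping channel space to sensor space is then estimated by
least squares from training trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SPAN = (-45.0, 135.0)


class DegenerateChannelError(ValueError):
    """A channel has zero hypothesized amplitude on every training trial."""


@dataclass(frozen=True)
class BasisSet:
    """The hypothetical direction channels.

    ``period_mode`` controls the period of the tuning sinusoid:

    * ``half_circle_doubled`` (default) — the 180 deg design span is treated
      as one full cycle, f_i(theta) = max(0, cos(2*pi*(theta-phi_i)/180))**k;
    * ``full_circle`` — motion direction is treated as 360-periodic,
      f_i(theta) = max(0, cos(2*pi*(theta-phi_i)/360))**k.
    """

    centers: np.ndarray
    exponent: int = 6
    period_mode: str = "half_circle_doubled"
    span: tuple = DEFAULT_SPAN
    readout_grid_step: float = 0.1

    @property
    def n_channels(self) -> int:
        return len(self.centers)

    @property
    def spacing(self) -> float:
        return (self.span[1] - self.span[0]) / self.n_channels

    def evaluate(self, directions) -> np.ndarray:
        """Tuning-curve values, shape (n_channels, n_directions)."""
        theta = np.atleast_1d(np.asarray(directions, dtype=float))
        delta = theta[None, :] - np.asarray(self.centers)[:, None]
        period = 180.0 if self.period_mode == "half_circle_doubled" else 360.0
        resp = np.cos(2.0 * np.pi * delta / period)
        return np.maximum(resp, 0.0) ** self.exponent


def make_basis(
    n_channels: int = 21,
    span: tuple = DEFAULT_SPAN,
    exponent: int = 6,
    period_mode: str = "half_circle_doubled",
    readout_grid_step: float = 0.1,
) -> BasisSet:
    """Build an evenly spaced channel basis over ``span``.

    Channel centers are ``span[0] + i * width/n_channels`` for i = 0..n-1, so
    the half-open span is tiled exactly (21 channels over [-45, 135) sit at
    -45, -45+180/21, ...).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if exponent <= 0 or exponent % 2:
        raise ValueError("exponent must be a positive even integer")
    width = span[1] - span[0]
    if period_mode == "half_circle_doubled" and not np.isclose(width, 180.0):
        raise ValueError("half_circle_doubled requires a 180 deg span")
    if period_mode not in ("half_circle_doubled", "full_circle"):
        raise ValueError(f"unknown period_mode {period_mode!r}")
    centers = span[0] + np.arange(n_channels) * width / n_channels
    return BasisSet(centers=centers, exponent=exponent, period_mode=period_mode,
                    span=tuple(span), readout_grid_step=readout_grid_step)


def channel_amplitudes(basis: BasisSet, directions) -> np.ndarray:
    """Design matrix C (channels x trials) of hypothesized channel amplitudes."""
    directions = np.asarray(directions, dtype=float)
    if not np.all(np.isfinite(directions)):
        raise ValueError("directions must be finite")
    return basis.evaluate(directions)


@dataclass
class EncodingWeights:
    """Sensors x channels weight matrix with fit provenance."""

    W: np.ndarray
    fit_mode: str
    n_trials: int
    meta: dict = field(default_factory=dict)

    @property
    def n_sensors(self) -> int:
        return self.W.shape[0]

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def fit_weights(B: np.ndarray, C: np.ndarray, fit_mode: str = "per_channel") -> EncodingWeights:
    """Least-squares estimate of the forward weights W from training data.

    Parameters
    ----------
    B
        Sensor data, sensors x trials.
    C
        Hypothesized channel amplitudes, channels x trials (trial-aligned
        with ``B``).
    fit_mode
        ``per_channel`` (default): each channel's weight column is the simple
        regression of every sensor on that channel's amplitude vector,
        w_i = B c_i / (c_i . c_i).  ``joint``: multivariate normal equations,
        W = B C^T (C C^T)^-1.
    """
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if B.shape[1] != C.shape[1]:
        raise ValueError(f"trial mismatch: B has {B.shape[1]} trials, C has {C.shape[1]}")
    n_channels, n_trials = C.shape
    if n_trials < n_channels:
        raise ValueError(f"need at least {n_channels} trials, got {n_trials}")
    norms = np.einsum("it,it->i", C, C)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise DegenerateChannelError(
            f"channel(s) {dead.tolist()} have all-zero amplitudes across training trials"
        )
    if fit_mode == "per_channel":
        W = (B @ C.T) / norms[None, :]
    elif fit_mode == "joint":
        # normal equations W = B C^T (C C^T)^-1, via least squares so a
        # rank-deficient design (fewer distinct directions than channels)
        # yields the minimum-norm solution instead of noise amplification
        W = np.linalg.lstsq(C.T, B.T, rcond=None)[0].T
    else:
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    if not np.all(np.isfinite(W)):
        raise FloatingPointError("non-finite weights")
    return EncodingWeights(W=W, fit_mode=fit_mode, n_trials=n_trials)
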