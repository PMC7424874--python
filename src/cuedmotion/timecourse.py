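"""Time-resolved decoding: baseline correction, sliding-window averaging,
leave-one-run-out cross-validation, training-peak selection, and application
of the final localizer-trained model to the main task.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EpochSet, check_alignment
from .decoder import DecodingModel, apply_decoder, train_decoder
from .encoding import BasisSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters for time-resolved decoding.

    The window width in samples is round(width_ms * rate / 1000), decremented
    by one if even so the window can be centered symmetrically (600 Hz, 28.3
    ms -> 17 samples; the a-priori 30 ms window gives 18 and is likewise
    reduced to 17).
    """

    step_ms: float = 5.0
    width_ms: float = 28.3

    def step_samples(self, sampling_rate: float) -> int:
        step = round(self.step_ms * sampling_rate / 1000.0)
        return max(int(step), 1)

    def width_samples(self, sampling_rate: float) -> int:
        width = int(round(self.width_ms * sampling_rate / 1000.0))
        if width % 2 == 0:
            logger.info("window of %d samples is even; using %d", width, width - 1)
            width -= 1
        return max(width, 1)


@dataclass
class DecodedTimecourse:
    """Time x trials decoded directions, with provenance."""

    decoded: np.ndarray  # (n_times, n_trials)
    times: np.ndarray  # ms
    training_peak_ms: float | None = None
    meta: dict = field(default_factory=dict)


def baseline_correct(epochs: EpochSet, interval) -> EpochSet:
    """Subtract, per trial and sensor, the mean over ``interval`` (ms)."""
    lo, hi = interval
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not mask.any():
        raise ValueError(f"baseline interval {interval} contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def window_average(epochs: EpochSet, spec: WindowSpec = WindowSpec()) -> EpochSet:
    """Centered sliding-window mean on a coarser (step_ms) time grid.

    Each output time point is the mean of ``width_samples`` consecutive input
    samples centered on it; only windows fully inside the epoch are kept.
    """
    width = spec.width_samples(epochs.sampling_rate)
    step = spec.step_samples(epochs.sampling_rate)
    n = epochs.n_samples
    if width > n:
        raise ValueError(f"window of {width} samples exceeds epoch length {n}")
    half = width // 2
    valid = np.arange(half, n - half)
    # prefer centers that sit on the round step_ms grid (…, -5, 0, 5, … ms)
    rem = np.abs(epochs.times[valid] / spec.step_ms - np.round(epochs.times[valid] / spec.step_ms))
    aligned = valid[rem < 1e-6]
    centers = aligned if aligned.size else valid[::step]
    # cumulative-sum windowed mean over the samples axis
    cs = np.concatenate(
        [np.zeros(epochs.data.shape[:2] + (1,)), np.cumsum(epochs.data, axis=2)], axis=2
    )
    out = (cs[:, :, centers + half + 1] - cs[:, :, centers - half]) / width
    return EpochSet(
        data=out, times=epochs.times[centers],
        sampling_rate=1000.0 / (step * 1000.0 / epochs.sampling_rate),
        sensor_ids=list(epochs.sensor_ids),
    )


def crossval_localizer(
    epochs: EpochSet,
    table: pd.DataFrame,
    basis: BasisSet,
    spec: WindowSpec = WindowSpec(),
    times_sel=None,
    pre_windowed: bool = False,
    **decoder_kwargs,
) -> DecodedTimecourse:
    """Leave-one-run-out decoding of the localizer, per time step.

    For every held-out run and window-averaged time step, a decoder is
    trained on the remaining runs at that step and applied to the held-out
    trials; decoded directions are assembled in original trial order.
    ``times_sel`` optionally restricts decoding to times (ms) within a
    (lo, hi) interval.
    """
    check_alignment(epochs, table)
    runs = table["run"].to_numpy()
    unique_runs = pd.unique(runs)
    if len(unique_runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    wa = epochs if pre_windowed else window_average(epochs, spec)
    times = wa.times
    keep = np.ones(len(times), dtype=bool)
    if times_sel is not None:
        keep = (times >= times_sel[0]) & (times <= times_sel[1])
    t_idx = np.flatnonzero(keep)
    decoded = np.full((len(t_idx), epochs.n_trials), np.nan)
    for run in unique_runs:
        test = runs == run
        train = ~test
        train_dirs = table.loc[train, "presented_dir"].to_numpy()
        missing = set(np.unique(table["presented_dir"])) - set(np.unique(train_dirs))
        if missing:
            warnings.warn(f"fold {run}: training folds miss directions {sorted(missing)}",
                          RuntimeWarning, stacklevel=2)
        for j, ti in enumerate(t_idx):
            model = train_decoder(wa.data[train, :, ti].T, train_dirs, basis, **decoder_kwargs)
            decoded[j, test], _ = apply_decoder(model, wa.data[test, :, ti].T)
    return DecodedTimecourse(decoded=decoded, times=times[t_idx],
                            meta={"cv": "leave-one-run-out", "n_folds": len(unique_runs)})


def localizer_performance(
    decoded: np.ndarray,
    presented: np.ndarray,
    method: str = "pearson",
    period: float | None = 180.0,
) -> np.ndarray:
    """Per-time correlation between the presented directions and the mean
    decoded direction per presented direction.

    ``decoded`` is (n_times, n_trials) or (n_trials,); returns r per time.

    ``period`` makes the metric consistent with the circular topology of the
    decoder's output space: presented directions are collapsed modulo the
    basis period (under the 180-deg convention -45 and 135 label the same
    design point), and per-level decoded directions are averaged circularly,
    with every level mean represented in the fixed design window starting at
    the smallest presented direction. The representative window is fixed --
    not centered on each level -- so the metric stays unbiased on pure noise.
    ``period=None`` disables this and reproduces the plain arithmetic-mean
    correlation over the raw levels.
    """
    decoded = np.atleast_2d(np.asarray(decoded, dtype=float))
    presented = np.asarray(presented, dtype=float)
    if period is not None:
        lo = presented.min()
        canon = (presented - lo) % period + lo
        levels = np.unique(canon)
        if len(levels) < 3:
            raise ValueError(f"correlation undefined with {len(levels)} distinct directions")
        ang = decoded * (2.0 * np.pi / period)
        means = np.empty((decoded.shape[0], len(levels)))
        for j, lc in enumerate(levels):
            sel = canon == lc
            mean_ang = np.angle(np.exp(1j * ang[:, sel]).mean(axis=1))
            circ_mean = mean_ang * period / (2.0 * np.pi)
            offset = (circ_mean - lo) % period
            offset = np.where(offset > period - 1e-6, 0.0, offset)  # edge snap
            means[:, j] = lo + offset
    else:
        levels = np.unique(presented)
        if len(levels) < 3:
            raise ValueError(f"correlation undefined with {len(levels)} distinct directions")
        M = (presented[None, :] == levels[:, None]).astype(float)
        M /= M.sum(axis=1, keepdims=True)
        means = decoded @ M.T  # (n_times, n_levels)
    if method == "pearson":
        x = levels
        y = means
    elif method == "spearman":
        x = sps.rankdata(levels)
        y = sps.rankdata(means, axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    x0 = x - x.mean()
    y0 = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((x0 @ x0) * np.sum(y0**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (y0 @ x0) / denom
    return r


def select_training_peak(group_r: np.ndarray, times: np.ndarray, window=(90.0, 110.0)) -> np.ndarray:
    """Per-participant decoding peak (ms) within the group-level window.

    ``group_r`` is (n_participants, n_times); the peak is the argmax of each
    participant's performance curve restricted to ``window`` (the significant
    group cluster; 90-110 ms in the reference configuration).
    """
    group_r = np.atleast_2d(np.asarray(group_r, dtype=float))
    times = np.asarray(times, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"peak window {window} contains no decoded time steps")
    sub = group_r[:, mask]
    return times[mask][np.argmax(sub, axis=1)]


def train_final_model(
    epochs: EpochSet,
    table: pd.DataFrame,
    basis: BasisSet,
    peak_ms: float,
    spec: WindowSpec = WindowSpec(),
    n_neighbors: int = 2,
    pre_windowed: bool = False,
    **decoder_kwargs,
) -> DecodingModel:
    """Train the final decoder on the individual peak step plus its
    ``n_neighbors`` neighboring steps on either side, pooled as extra
    observations (a single demeaning over the pooled sample)."""
    check_alignment(epochs, table)
    wa = epochs if pre_windowed else window_average(epochs, spec)
    idx = int(np.argmin(np.abs(wa.times - peak_ms)))
    steps = np.arange(idx - n_neighbors, idx + n_neighbors + 1)
    if steps[0] < 0 or steps[-1] >= len(wa.times):
        raise ValueError("peak window extends beyond the decoded time axis")
    B = np.concatenate([wa.data[:, :, s] for s in steps], axis=0).T  # sensors x (trials*steps)
    dirs = np.tile(table["presented_dir"].to_numpy(), len(steps))
    model = train_decoder(B, dirs, basis, **decoder_kwargs)
    model.meta.update(peak_ms=float(wa.times[idx]), pooled_steps_ms=wa.times[steps].tolist())
    return model


def decode_main(
    model: DecodingModel,
    epochs: EpochSet,
    table: pd.DataFrame | None = None,
    spec: WindowSpec = WindowSpec(),
    pre_windowed: bool = False,
) -> DecodedTimecourse:
    """Apply a localizer-trained model to (main-task) epochs at every window
    step, yielding a time x trials decoded-direction matrix."""
    if table is not None:
        check_alignment(epochs, table)
    if epochs.n_sensors != model.filters.V.shape[0]:
        raise ValueError(
            f"sensor mismatch: model trained on {model.filters.V.shape[0]} sensors, "
            f"data has {epochs.n_sensors}"
        )
    wa = epochs if pre_windowed else window_average(epochs, spec)
    n_times, n_trials = len(wa.times), wa.n_trials
    # one batched decode over all (time, trial) columns
    B_all = wa.data.transpose(1, 0, 2).reshape(wa.n_sensors, n_trials * n_times)
    flat, _ = apply_decoder(model, B_all)
    decoded = flat.reshape(n_trials, n_times).T
    return DecodedTimecourse(
        decoded=decoded, times=wa.times,
        training_peak_ms=model.meta.get("peak_ms"),
        meta={"window": {"step_ms": spec.step_ms, "width_ms": spec.width_ms}},
    )
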