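"""Synthetic experiment generator.

Emulates the statistical structure the decoding pipeline assumes: a
localizer task (11 equiprobable full-coherence directions, 88 trials per
block), a cued main task (two auditory cues predicting 27 or 63 deg with 60%
validity, the four other directions at 10% each, 60 trials per run),
direction-tuned evoked sensor responses B = W.C scaled by an evoked time
profile, spatially correlated / temporally white sensor noise, an optional
cue-locked "expectation template" (the cued direction's sensor pattern
re-activated in a fixed post-stimulus window), and behavioral reports that
mix the presented and cued directions.

All generation is a pure function of (design, ground truth, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CUE_DIRECTIONS,
    LOCALIZER_DIRECTIONS,
    MAIN_DIRECTIONS,
    TRIAL_COLUMNS,
    EpochSet,
    validate_trial_table,
)
from .encoding import BasisSet, channel_amplitudes, make_basis

#: P(presented = cued | cue) in the main task.
CUE_VALIDITY = 0.6
#: P(presented = d | cue) for each of the four non-cued directions.
FOIL_PROBABILITY = 0.1
#: Trials per localizer block: 8 repetitions of each of the 11 directions.
LOCALIZER_BLOCK_TRIALS = 88


class InvalidDesignError(ValueError):
    pass


@dataclass
class ExpectationTemplate:
    """Cue-locked reactivation of a direction's sensor pattern.

    ``direction=None`` injects each trial's own cued direction (the study
    condition); a number restricts injection to trials cued with that
    direction.
    """

    amplitude: float
    direction: float | None = None
    onset_ms: float = 135.0
    offset_ms: float = 180.0


@dataclass
class Behavior:
    """Report model: reported = (1-w)*presented + w*cued + N(0, sd^2).

    ``cue_weight`` w > 0 models attraction toward the cued direction; small
    negative values model the repelled minority of participants.
    """

    cue_weight: float = 0.03
    report_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.cue_weight <= 1.0:
            raise ValueError("cue_weight must be in [-1, 1]")
        if self.report_noise_sd < 0:
            raise ValueError("report_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Generative parameters of one simulated participant."""

    n_sensors: int = 272
    sampling_rate: float = 600.0
    true_weights: np.ndarray | None = None  # (sensors, channels)
    noise_covariance: np.ndarray | None = None  # (sensors, sensors), SPD
    evoked_peak_ms: float = 100.0
    expectation_template: ExpectationTemplate | None = None
    behavior: Behavior = field(default_factory=Behavior)
    basis: BasisSet = field(default_factory=make_basis)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_weights is not None:
            self.true_weights = np.asarray(self.true_weights, dtype=float)
        if self.noise_covariance is not None:
            cov = np.asarray(self.noise_covariance, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError("noise_covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("noise_covariance must be positive-definite")
            self.noise_covariance = cov

    def evoked_profile(self, times_ms) -> np.ndarray:
        """Unitless evoked gain g(t): 0 before onset, unit peak at evoked_peak_ms.

        A gamma-like bump g(t) = (t/tp) exp(1 - t/tp) for t >= 0.
        """
        t = np.asarray(times_ms, dtype=float)
        tp = self.evoked_peak_ms
        g = np.where(t >= 0, (t / tp) * np.exp(1.0 - t / tp), 0.0)
        return np.maximum(g, 0.0)


def make_ground_truth(
    n_sensors: int = 272,
    sampling_rate: float = 600.0,
    noise_sd: float = 1.0,
    noise_corr: float = 0.6,
    signal_gain: float = 1.0,
    expectation_template: ExpectationTemplate | None = None,
    behavior: Behavior | None = None,
    basis: BasisSet | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a random participant: random channel patterns and an AR(1)-style
    spatially correlated noise covariance (corr ``noise_corr**|i-j|`` between
    sensors i and j, per-sensor SD ``noise_sd``)."""
    rng = np.random.default_rng(seed)
    basis = basis or make_basis()
    W = rng.standard_normal((n_sensors, basis.n_channels))
    W *= signal_gain / np.sqrt(n_sensors)
    idx = np.arange(n_sensors)
    corr = noise_corr ** np.abs(idx[:, None] - idx[None, :])
    cov = (noise_sd**2) * corr
    return GroundTruth(
        n_sensors=n_sensors, sampling_rate=sampling_rate, true_weights=W,
        noise_covariance=cov, expectation_template=expectation_template,
        behavior=behavior or Behavior(), basis=basis, seed=seed,
    )


def _allocate_counts(n: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer counts summing to n with expectation n*probs (largest-remainder,
    random tie-breaking so no direction is systematically favored)."""
    raw = n * probs
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short:
        frac = raw - np.floor(raw)
        order = np.lexsort((rng.random(len(probs)), -frac))
        counts[order[:short]] += 1
    return counts


def make_main_design(n_runs: int, trials_per_run: int = 60, seed: int = 0) -> pd.DataFrame:
    """Cued main-task design: balanced cues, 60/10/10/10/10 direction marginals.

    Within each run the two cues occur equally often in pseudo-random order;
    within each cue the presented direction is the cued one with probability
    0.6 and each of the four others with probability 0.1 (exact counts where
    divisible, randomized remainders otherwise).
    """
    if n_runs < 1:
        raise InvalidDesignError("n_runs must be >= 1")
    if trials_per_run % 2:
        raise InvalidDesignError("trials_per_run must be even so cues can be balanced")
    rng = np.random.default_rng(seed)
    dirs = np.array(MAIN_DIRECTIONS)
    rows = []
    for run in range(n_runs):
        per_cue = trials_per_run // 2
        cells = []
        for cue, cued_dir in CUE_DIRECTIONS.items():
            probs = np.where(dirs == cued_dir, CUE_VALIDITY, FOIL_PROBABILITY)
            counts = _allocate_counts(per_cue, probs, rng)
            for d, c in zip(dirs, counts):
                cells.extend([(cue, d)] * c)
        order = rng.permutation(len(cells))
        for cue, d in (cells[i] for i in order):
            rows.append(("main%02d" % (run + 1), "main", cue, d))
    table = pd.DataFrame(rows, columns=["run", "task", "cue", "presented_dir"])
    table.insert(0, "trial_id", np.arange(len(table)))
    table["reported_dir"] = np.nan
    table["coherence"] = 0.2
    return validate_trial_table(table[list(TRIAL_COLUMNS)])


def make_localizer_design(n_blocks: int, seed: int = 0) -> pd.DataFrame:
    """Localizer design: per 88-trial block, 8 pseudo-random repetitions of
    each of the 11 directions at full coherence."""
    if n_blocks < 1:
        raise InvalidDesignError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    per_dir = LOCALIZER_BLOCK_TRIALS // len(LOCALIZER_DIRECTIONS)
    rows = []
    for block in range(n_blocks):
        dirs = np.repeat(LOCALIZER_DIRECTIONS, per_dir)
        rng.shuffle(dirs)
        for d in dirs:
            rows.append(("loc%02d" % (block + 1), "localizer", "none", d))
    table = pd.DataFrame(rows, columns=["run", "task", "cue", "presented_dir"])
    table.insert(0, "trial_id", np.arange(len(table)))
    table["reported_dir"] = np.nan
    table["coherence"] = 1.0
    return validate_trial_table(table[list(TRIAL_COLUMNS)])


def simulate_epochs(design: pd.DataFrame, gt: GroundTruth, t_range=(-250.0, 500.0)) -> EpochSet:
    """Generate sensor epochs for a design.

    data[trial, :, t] = W f(presented) g(t) + template + spatially correlated
    white-in-time Gaussian noise. The expectation template adds
    ``amplitude * W f(cued)`` between its onset and offset on matching
    main-task trials.
    """
    design = validate_trial_table(design)
    if not len(design):
        raise InvalidDesignError("design is empty")
    if not (t_range[0] <= 0.0 <= t_range[1]):
        raise ValueError("t_range must contain stimulus onset (0 ms)")
    if gt.true_weights is None or gt.noise_covariance is None:
        raise ValueError("ground truth must carry true_weights and noise_covariance")
    dt = 1000.0 / gt.sampling_rate
    times = np.arange(np.ceil(t_range[0] / dt), np.floor(t_range[1] / dt) + 1) * dt
    n_trials, n_sensors, n_samples = len(design), gt.n_sensors, len(times)

    C = channel_amplitudes(gt.basis, design["presented_dir"].to_numpy())
    patterns = gt.true_weights @ C  # (sensors, trials)
    gain = gt.evoked_profile(times)  # (samples,)
    data = patterns.T[:, :, None] * gain[None, None, :]

    tpl = gt.expectation_template
    if tpl is not None:
        is_main = (design["task"] == "main").to_numpy()
        cued = design["cue"].map(CUE_DIRECTIONS).to_numpy(dtype=float)
        match = is_main & ~np.isnan(cued)
        if tpl.direction is not None:
            match &= cued == tpl.direction
        if match.any():
            in_win = (times >= tpl.onset_ms) & (times <= tpl.offset_ms)
            cue_patterns = gt.true_weights @ channel_amplitudes(gt.basis, cued[match])
            data[match] += tpl.amplitude * cue_patterns.T[:, :, None] * in_win[None, None, :]

    task_code = 1 if (design["task"] == "main").any() else 0
    rng = np.random.default_rng([gt.seed, n_trials, task_code])
    chol = np.linalg.cholesky(gt.noise_covariance)
    noise = rng.standard_normal((n_trials, n_samples, n_sensors)) @ chol.T
    data += noise.transpose(0, 2, 1)
    return EpochSet(data=data, times=times, sampling_rate=gt.sampling_rate)


def simulate_behavior(design: pd.DataFrame, gt: GroundTruth) -> pd.DataFrame:
    """Fill in reported directions for main-task trials.

    reported = (1-w)*presented + w*cued + Gaussian(report_noise_sd). The
    directions used in the main task (9-81 deg) sit far from the span edges,
    so the mix is computed linearly without circular wrapping.
    """
    design = validate_trial_table(design).copy()
    is_main = (design["task"] == "main").to_numpy()
    if not is_main.any():
        return design
    w = gt.behavior.cue_weight
    sd = gt.behavior.report_noise_sd
    cued = design.loc[is_main, "cue"].map(CUE_DIRECTIONS).to_numpy(dtype=float)
    presented = design.loc[is_main, "presented_dir"].to_numpy(dtype=float)
    rng = np.random.default_rng([gt.seed, 7, int(is_main.sum())])
    noise = rng.standard_normal(is_main.sum()) * sd
    design.loc[is_main, "reported_dir"] = (1.0 - w) * presented + w * cued + noise
    return design


def ground_truth_to_json(gt: GroundTruth) -> str:
    """Serialize a GroundTruth to JSON (arrays as nested lists)."""
    d = asdict(gt)
    for key in ("true_weights", "noise_covariance"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["basis"] = {
        "n_channels": gt.basis.n_channels,
        "span": list(gt.basis.span),
        "exponent": gt.basis.exponent,
        "period_mode": gt.basis.period_mode,
        "readout_grid_step": gt.basis.readout_grid_step,
    }
    return json.dumps(d)


def ground_truth_from_json(text: str) -> GroundTruth:
    d = json.loads(text)
    basis_cfg = d.pop("basis")
    basis = make_basis(
        n_channels=basis_cfg["n_channels"], span=tuple(basis_cfg["span"]),
        exponent=basis_cfg["exponent"], period_mode=basis_cfg["period_mode"],
        readout_grid_step=basis_cfg["readout_grid_step"],
    )
    tpl = d.pop("expectation_template")
    beh = d.pop("behavior")
    for key in ("true_weights", "noise_covariance"):
        if d[key] is not None:
            d[key] = np.asarray(d[key], dtype=float)
    return GroundTruth(
        expectation_template=None if tpl is None else ExpectationTemplate(**tpl),
        behavior=Behavior(**beh), basis=basis, **d,
    )
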