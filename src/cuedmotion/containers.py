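"""Core data containers shared by all pipeline stages.

The pipeline operates on epoched multi-sensor recordings (trials x sensors x
samples) plus a per-trial metadata table. Containers are deliberately thin:
an :class:`EpochSet` is a validated bundle of a numpy array with its time
axis, and the trial table is a plain :class:`pandas.DataFrame` with a fixed
column schema so it round-trips through TSV unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Motion directions (deg) shown in localizer runs, 100% coherence.
LOCALIZER_DIRECTIONS = (-45.0, -27.0, -9.0, 9.0, 27.0, 45.0, 63.0, 81.0, 99.0, 117.0, 135.0)

#: Motion directions (deg) shown in the main (cued) task.
MAIN_DIRECTIONS = (9.0, 27.0, 45.0, 63.0, 81.0)

#: Direction (deg) predicted by each auditory cue, with 60% validity.
CUE_DIRECTIONS = {"cue27": 27.0, "cue63": 63.0}

#: Column schema of the trial table (TSV column order).
TRIAL_COLUMNS = ("trial_id", "run", "task", "cue", "presented_dir", "reported_dir", "coherence")


def angular_difference(a, b, period: float = 180.0):
    """Signed angular difference ``a - b`` wrapped to ``(-period/2, period/2]``.

    The design space of the experiment is the 180 deg span [-45, 135), so the
    default period is 180.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.where(d > period / 2, d - period, d)


@dataclass
class EpochSet:
    """Epoched sensor data: ``data[trial, sensor, sample]``.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_sensors, n_samples), arbitrary units.
    times
        Sample time stamps in ms relative to stimulus onset, uniformly
        spaced at 1000/sampling_rate (a coarser uniform grid is permitted
        after sliding-window averaging).
    sampling_rate
        Acquisition rate in Hz.
    sensor_ids
        One label per sensor.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    sensor_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, sensors, samples), got {self.data.shape}")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must equal the number of samples")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], atol=1e-6):
                raise ValueError("times must be uniformly spaced")
        if not self.sensor_ids:
            self.sensor_ids = [f"S{i:03d}" for i in range(self.data.shape[1])]
        if len(self.sensor_ids) != self.data.shape[1]:
            raise ValueError("sensor_ids length must equal the number of sensors")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.sampling_rate, list(self.sensor_ids))


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table schema and per-task invariants; return the table.

    localizer rows must have cue 'none', coherence 1.0 and a localizer
    direction; main rows must have a real cue and a main-task direction.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    bad_task = set(table["task"].unique()) - {"localizer", "main"}
    if bad_task:
        raise ValueError(f"unknown task labels: {sorted(bad_task)}")
    loc = table[table["task"] == "localizer"]
    if len(loc):
        if not (loc["cue"] == "none").all():
            raise ValueError("localizer trials must have cue='none'")
        if not np.allclose(loc["coherence"], 1.0):
            raise ValueError("localizer trials must have coherence 1.0")
        if not loc["presented_dir"].isin(LOCALIZER_DIRECTIONS).all():
            raise ValueError("localizer direction outside the 11 localizer directions")
    main = table[table["task"] == "main"]
    if len(main):
        if not main["cue"].isin(CUE_DIRECTIONS).all():
            raise ValueError("main-task trials must have cue 'cue27' or 'cue63'")
        if not main["presented_dir"].isin(MAIN_DIRECTIONS).all():
            raise ValueError("main-task direction outside {9,27,45,63,81}")
    return table


def check_alignment(epochs: EpochSet, table: pd.DataFrame) -> None:
    """Raise if the epochs and trial table do not describe the same trials."""
    if epochs.n_trials != len(table):
        raise ValueError(
            f"epoch/trial-table misalignment: {epochs.n_trials} epochs vs {len(table)} table rows"
        )
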