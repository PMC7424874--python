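"""Persistence: HDF5 epoch containers, TSV trial tables, JSON results.

Every writer embeds the producing configuration hash and master seed as
attributes/fields so any output file can be traced to the run that made it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import TRIAL_COLUMNS, EpochSet, check_alignment, validate_trial_table
from .stats import Cluster, ClusterResult


class SchemaError(ValueError):
    pass


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_epochs(path, epochs: EpochSet, config: dict | None = None, seed: int | None = None):
    """Write an EpochSet to HDF5 (/data, /times, /sensor_ids; attrs:
    sampling_rate, config_hash, seed)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("sensor_ids", data=np.asarray(epochs.sensor_ids, dtype="S"))
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["config_hash"] = config_hash(config or {})
        if seed is not None:
            f.attrs["seed"] = int(seed)


def read_epochs(path, table_path=None):
    """Read an EpochSet (and optionally its aligned trial table).

    Raises :class:`SchemaError` naming any missing dataset/attribute and an
    alignment error if the table row count does not match the trial axis.
    """
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "sensor_ids"):
            if name not in f:
                raise SchemaError(f"epoch container {path} is missing dataset '{name}'")
        if "sampling_rate" not in f.attrs:
            raise SchemaError(f"epoch container {path} is missing attribute 'sampling_rate'")
        epochs = EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            sensor_ids=[s.decode() for s in f["sensor_ids"][()]],
        )
    if table_path is None:
        return epochs
    table = read_trial_table(table_path)
    check_alignment(epochs, table)
    return epochs, table


def write_trial_table(path, table: pd.DataFrame) -> None:
    validate_trial_table(table)
    table[list(TRIAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_trial_table(table)


def write_filters(path, filters, weights=None, config: dict | None = None,
                  seed: int | None = None) -> None:
    """Persist spatial filters (and optionally the forward weights) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("filters", data=filters.V)
        f.create_dataset("lambdas", data=filters.lambdas)
        if weights is not None:
            f.create_dataset("weights", data=weights.W)
            f.attrs["fit_mode"] = weights.fit_mode
        f.attrs["solver"] = filters.solver
        f.attrs["config_hash"] = config_hash(config or {})
        if seed is not None:
            f.attrs["seed"] = int(seed)


def write_decoded(path, tc) -> None:
    """Decoded timecourse as TSV in long format (trial_id, time_ms, decoded_dir)."""
    n_times, n_trials = tc.decoded.shape
    frame = pd.DataFrame({
        "trial_id": np.tile(np.arange(n_trials), n_times),
        "time_ms": np.repeat(tc.times, n_trials),
        "decoded_dir": tc.decoded.ravel(),
    })
    frame.to_csv(path, sep="\t", index=False)


def cluster_result_to_dict(res: ClusterResult) -> dict:
    return {
        "clusters": [dataclasses.asdict(c) for c in res.clusters],
        "n_permutations": res.n_permutations,
        "threshold_p": res.threshold_p,
        "tail": res.tail,
        "seed": res.seed,
    }


def cluster_result_from_dict(d: dict) -> ClusterResult:
    return ClusterResult(
        clusters=[Cluster(**c) for c in d["clusters"]],
        n_permutations=d["n_permutations"], threshold_p=d["threshold_p"],
        tail=d["tail"], seed=d.get("seed"),
    )


def write_json(path, payload: dict, config: dict | None = None, seed: int | None = None) -> None:
    payload = dict(payload)
    payload.setdefault("_provenance", {})
    payload["_provenance"].update({"config_hash": config_hash(config or {}), "seed": seed})
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
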