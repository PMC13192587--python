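"""Serialization: model archives (HDF5), observation archives, run configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from . import __version__
from .dag import CausalDag, NoisyOrParams, ObservationSequence
from .model import RnnParams, TrainConfig
from .task import TaskConfig

SCHEMA_VERSION = 1


def task_config_to_dict(task: TaskConfig) -> dict:
    d = dataclasses.asdict(task)
    d["params"] = dataclasses.asdict(task.params)
    return d


def task_config_from_dict(d: dict) -> TaskConfig:
    d = dict(d)
    d["params"] = NoisyOrParams(**d["params"])
    return TaskConfig(**d)


def save_model(
    path,
    params: RnnParams,
    task: Optional[TaskConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Write weights plus provenance (configs, seed, package version) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["package_version"] = __version__
        if seed is not None:
            f.attrs["seed"] = int(seed)
        g = f.create_group("params")
        g.create_dataset("W", data=params.W)
        g.create_dataset("B", data=params.B)
        g.create_dataset("C", data=params.C)
        g.attrs["tau"] = params.tau
        g.attrs["dt"] = params.dt
        if task is not None:
            f.attrs["task_config"] = json.dumps(task_config_to_dict(task))
        if train_cfg is not None:
            f.attrs["train_config"] = json.dumps(dataclasses.asdict(train_cfg))


def load_model(path):
    """Read a model archive; returns (RnnParams, TaskConfig | None, TrainConfig | None).

    Raises ValueError on schema mismatch and OSError on unreadable/truncated
    files, leaving no partial state behind.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {version} (expected {SCHEMA_VERSION})"
            )
        g = f["params"]
        params = RnnParams(
            W=g["W"][()], B=g["B"][()], C=g["C"][()],
            tau=float(g.attrs["tau"]), dt=float(g.attrs["dt"]),
        )
        task = None
        if "task_config" in f.attrs:
            task = task_config_from_dict(json.loads(f.attrs["task_config"]))
        train_cfg = None
        if "train_config" in f.attrs:
            train_cfg = TrainConfig(**json.loads(f.attrs["train_config"]))
    return params, task, train_cfg


def save_observations(
    path, obs: ObservationSequence, params: Optional[NoisyOrParams] = None,
    seed: Optional[int] = None,
) -> None:
    """Compressed array archive with a JSON sidecar recording provenance."""
    path = Path(path)
    np.savez_compressed(path, activity=obs.activity)
    meta = {
        "dag": None if obs.source_dag is None else json.loads(obs.source_dag.to_json()),
        "params": None if params is None else dataclasses.asdict(params),
        "seed": seed,
        "package_version": __version__,
    }
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix == ".npz" else Path(str(path) + ".npz.json")
    sidecar.write_text(json.dumps(meta, indent=2))


def save_trial_batch(path, batch, task: TaskConfig, seed=None) -> None:
    """Store a generated trial batch (inputs, labels, queries, DAG indices,
    observations) as a compressed archive with JSON metadata."""
    np.savez_compressed(
        path,
        inputs=batch.inputs,
        labels=batch.labels,
        queries=batch.queries,
        dag_indices=batch.dag_indices,
        observations=batch.observations,
        meta=np.frombuffer(
            json.dumps(
                {"task": task_config_to_dict(task), "seed": seed,
                 "package_version": __version__}
            ).encode(), dtype=np.uint8,
        ),
    )


def load_trial_batch(path):
    """Inverse of save_trial_batch; returns (TrialBatch, TaskConfig, seed)."""
    from .task import TrialBatch

    with np.load(path) as f:
        batch = TrialBatch(
            inputs=f["inputs"], labels=f["labels"], queries=f["queries"],
            dag_indices=f["dag_indices"], observations=f["observations"],
        )
        meta = json.loads(bytes(f["meta"]).decode())
    return batch, task_config_from_dict(meta["task"]), meta["seed"]


def load_observations(path) -> ObservationSequence:
    path = Path(path)
    with np.load(path) as f:
        activity = f["activity"]
    sidecar = path.with_suffix(path.suffix + ".json")
    dag = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("dag"):
            dag = CausalDag(meta["dag"]["n_nodes"], [tuple(e) for e in meta["dag"]["edges"]])
    return ObservationSequence(activity=activity, source_dag=dag)
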