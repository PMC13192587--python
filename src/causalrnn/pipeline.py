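"""End-to-end reproduction driver: train, probe behavior, analyze dynamics.

All randomness derives from one master seed via numpy SeedSequence spawning
(documented order: train, evaluate, behavior, dynamics, readout), so a run is
reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .dag import CausalDag, ObservationSequence, categorize_dag, enumerate_dags, sample_observations
from .task import Query, TaskConfig, all_queries
from .model import RnnParams, TrainConfig, evaluate_accuracy, train
from .behavior import (
    category_accuracies,
    implicit_graph_readout,
    marginal_shuffle_control,
    randomization_test,
    transitivity_bias,
)
from .dynamics import (
    attractor_geometry,
    build_line_attractor,
    find_fixed_points,
    interior_points,
)
from .io import save_model, task_config_to_dict


@dataclass
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    master_seed: int = 0
    out_dir: str = "causalrnn_run"
    run_behavior: bool = True
    run_dynamics: bool = True
    n_eval_trials: int = 2000
    n_fp_seeds: int = 512
    n_shuffles: int = 100
    n_randomization_trials: int = 500


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Train a model and run the behavioral and dynamical analysis suites.

    Writes model archive, history CSV, and a JSON summary of every check to
    the output directory; returns the summary dict.
    """
    out = Path(config.out_dir)
    plan = {
        "task": task_config_to_dict(config.task),
        "train": dataclasses.asdict(config.train),
        "master_seed": config.master_seed,
        "stages": ["train", "evaluate"]
        + (["behavior"] if config.run_behavior else [])
        + (["dynamics"] if config.run_dynamics else []),
    }
    if dry_run:
        return {"plan": plan, "dry_run": True}

    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.master_seed)
    train_ss, eval_ss, behav_ss, dyn_ss, readout_ss = ss.spawn(5)
    summary: dict = {"plan": plan, "checks": {}}
    t0 = time.time()

    train_cfg = dataclasses.replace(
        config.train, seed=int(train_ss.generate_state(1)[0] % (2**31))
    )
    params, history = train(config.task, train_cfg)
    history.to_csv(out / "training_history.csv", index=False)
    save_model(out / "model.h5", params, config.task, train_cfg, seed=config.master_seed)

    acc, table = evaluate_accuracy(params, config.task, config.n_eval_trials, eval_ss)
    table.to_csv(out / "evaluation.csv", index=False)
    summary["checks"]["holdout_accuracy"] = {"value": acc, "pass": acc >= 0.9}

    if config.run_behavior:
        b1, b2, b3, b4 = behav_ss.spawn(4)
        cats = category_accuracies(params, config.task, 300, b1)
        cats.to_csv(out / "category_accuracy.csv")
        summary["checks"]["chain_is_hardest_category"] = {
            "value": cats.to_dict(),
            "pass": cats.idxmin() == "chain",
        }
        fork = CausalDag(3, [(2, 0), (2, 1)])
        rt = randomization_test(
            params, fork, Query(0, 1), 2, config.n_randomization_trials,
            config.task, b2,
        )
        summary["checks"]["fork_randomization_degrades"] = {
            "value": rt, "pass": rt["difference"] > 0,
        }
        tb = transitivity_bias(params, config.task, 600, b3)
        summary["checks"]["transitivity_bias"] = {
            "value": tb, "pass": tb["transitive_true_rate"] > tb["chance"],
        }
        dag = CausalDag(3, [(0, 1)])
        obs = sample_observations(dag, config.task.n_obs, config.task.params, b4)
        sims = marginal_shuffle_control(
            params, obs, config.task, config.n_shuffles, b4
        )
        summary["checks"]["shuffle_similarity_below_1"] = {
            "value": float(sims.mean()), "pass": sims.mean() < 1.0,
        }

    if config.run_dynamics:
        attractors = {}
        fp_report = {}
        for q, s in zip(all_queries(config.task.n_nodes),
                        dyn_ss.spawn(len(all_queries(config.task.n_nodes)))):
            fps = find_fixed_points(
                params, q, config.task, s, n_seeds=config.n_fp_seeds
            )
            fp_report[f"{q.cause}->{q.effect}"] = len(fps)
            if len(fps) >= 3:
                attractors[q] = build_line_attractor(fps, params)
        summary["checks"]["fixed_points_per_query"] = {
            "value": fp_report, "pass": all(v >= 3 for v in fp_report.values()),
        }
        if attractors:
            eigs = []
            for attr in attractors.values():
                eigs += [float(p.top_eigenvalue.real) for p in interior_points(attr)]
            summary["checks"]["interior_top_eigenvalues"] = {
                "value": {"mean": float(np.mean(eigs)), "n": len(eigs)},
                "pass": bool(eigs) and 0.95 <= float(np.mean(eigs)) <= 1.05,
            }
            geom = attractor_geometry(attractors)
            geom["distances"].to_csv(out / "attractor_geometry.csv")
            summary["checks"]["same_cause_clustering"] = {
                "value": {k: v for k, v in geom.items() if k != "distances"},
                "pass": geom["same_cause_mean"] < geom["different_cause_mean"],
            }

    summary["elapsed_s"] = time.time() - t0
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
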