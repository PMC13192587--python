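"""Behavioral probes of trained networks.

These analyses characterize *what* a trained network computes, before asking
how: category-wise accuracy, the transitivity bias on chain graphs, circular
shuffle controls that destroy cross-node covariance while preserving
marginals, the implicit whole-graph readout obtained by cycling every query
over one fixed observation sequence, and a correlation control showing the
readout is not a thresholded correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .dag import CausalDag, ObservationSequence, enumerate_dags, categorize_dag
from .task import (
    Query,
    TaskConfig,
    all_queries,
    build_input_sequence,
    circular_shuffle_all,
    circular_shuffle_node,
    generate_batch,
)
from .model import RnnParams, batch_decisions, simulate
from .dag import _as_rng


@dataclass
class AdjacencyEstimate:
    """Thresholded judgments for every ordered query on one observation sequence."""

    matrix: np.ndarray  # N x N booleans, row cause / column effect, zero diagonal
    judgments: dict  # (cause, effect) -> output probability

    @classmethod
    def from_judgments(cls, judgments: dict, n_nodes: int) -> "AdjacencyEstimate":
        m = np.zeros((n_nodes, n_nodes), dtype=bool)
        for (i, j), p in judgments.items():
            m[i, j] = p > 0.5
        return cls(matrix=m, judgments=dict(judgments))


def implicit_graph_readout(
    params: RnnParams,
    obs: ObservationSequence,
    task: TaskConfig,
    window: float = 0.1,
    judge: Optional[Callable[[ObservationSequence, Query], float]] = None,
) -> AdjacencyEstimate:
    """Cycle through all N(N-1) queries with the observations held fixed.

    Although the network is only ever trained on one query per sequence, the
    six judgments assemble into an estimate of the full adjacency matrix.  A
    custom ``judge`` callable (e.g. the ideal observer's edge marginal) may be
    substituted for the network.
    """
    n = obs.n_nodes
    judgments = {}
    for q in all_queries(n):
        if judge is not None:
            p = judge(obs, q)
        else:
            traj = simulate(params, build_input_sequence(obs, q, task))
            n_win = max(1, int(round(window * len(traj.outputs))))
            p = float(traj.outputs[-n_win:].mean())
        judgments[(q.cause, q.effect)] = p
    return AdjacencyEstimate.from_judgments(judgments, n)


def graph_similarity(a: AdjacencyEstimate, b: AdjacencyEstimate) -> float:
    """Fraction of off-diagonal ordered pairs on which two estimates agree."""
    ma, mb = a.matrix, b.matrix
    if ma.shape != mb.shape:
        raise ValueError("adjacency estimates have different sizes")
    off = ~np.eye(ma.shape[0], dtype=bool)
    return float((ma[off] == mb[off]).mean())


def marginal_shuffle_control(
    params: RnnParams,
    obs: ObservationSequence,
    task: TaskConfig,
    n_shuffles: int,
    seed,
    window: float = 0.1,
) -> np.ndarray:
    """Similarity of the implicit readout under per-node circular shuffles.

    Each shuffle preserves every node's marginal activity exactly but
    destroys cross-node covariance; the returned array holds the
    graph_similarity of each shuffled readout to the unshuffled one.
    """
    rng = _as_rng(seed)
    ref = implicit_graph_readout(params, obs, task, window)
    sims = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = circular_shuffle_all(obs, rng)
        est = implicit_graph_readout(params, shuffled, task, window)
        sims[s] = graph_similarity(ref, est)
    return sims


def correlation_control(obs: ObservationSequence) -> np.ndarray:
    """Pearson correlation between node rows (symmetric; constant rows give 0)."""
    v = obs.activity.astype(float)
    if obs.n_obs < 2:
        raise ValueError("need at least 2 observations for correlations")
    sd = v.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant observation row: correlation set to 0")
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(v)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return c


def randomization_test(
    params: RnnParams,
    dag: CausalDag,
    query: Query,
    shuffle_node: int,
    n_trials: int,
    task: TaskConfig,
    seed,
    window: float = 0.1,
    block: int = 50,
) -> dict:
    """Paired accuracy with vs without circular-shuffling a non-queried node.

    Each trial is judged twice on the same observation draw: once intact and
    once with ``shuffle_node``'s row circularly rotated.  Per-trial
    correctness is aggregated into blocks and compared with a Wilcoxon
    signed-rank test (block aggregation avoids degenerate all-0/1 pairs).
    """
    if shuffle_node in (query.cause, query.effect):
        raise ValueError("shuffle_node must not be part of the query")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    gen_ss, shuf_ss = ss.spawn(2)
    batch = generate_batch(task, n_trials, gen_ss, fixed_dag=dag, fixed_query=query)
    label = dag.has_edge(query.cause, query.effect)
    rng = np.random.default_rng(shuf_ss)

    control_inputs = batch.inputs
    shuffled_inputs = np.empty_like(control_inputs)
    for i in range(n_trials):
        o = ObservationSequence(batch.observations[i], source_dag=dag)
        o2 = circular_shuffle_node(o, shuffle_node, rng)
        shuffled_inputs[i] = build_input_sequence(o2, query, task)

    correct_c = batch_decisions(params, control_inputs, window) == label
    correct_s = batch_decisions(params, shuffled_inputs, window) == label

    n_blocks = n_trials // block
    bc = correct_c[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    bs = correct_s[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    if np.allclose(bc, bs):
        stat, pval = np.nan, 1.0
    else:
        stat, pval = stats.wilcoxon(bc, bs)
    return {
        "accuracy_control": float(correct_c.mean()),
        "accuracy_shuffled": float(correct_s.mean()),
        "difference": float(correct_c.mean() - correct_s.mean()),
        "wilcoxon_statistic": float(stat),
        "p_value": float(pval),
        "n_trials": n_trials,
        "n_blocks": n_blocks,
    }


def transitivity_bias(
    params: RnnParams,
    task: TaskConfig,
    n_trials: int,
    seed,
    window: float = 0.1,
    judge: Optional[Callable[[ObservationSequence, Query], float]] = None,
) -> dict:
    """Rate of judging X->Z true on chain DAGs X->Y->Z (the edge is absent).

    Trials are spread over all six chain relabelings; chance on balanced
    training is 0.5, and a rate above it quantifies the transitivity bias.
    """
    chains = [d for d in enumerate_dags(task.n_nodes) if task.n_nodes == 3
              and categorize_dag(d) == "chain"]
    if not chains:
        raise ValueError("transitivity bias is defined for the 3-node task")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    per = np.full(len(chains), n_trials // len(chains))
    per[: n_trials % len(chains)] += 1
    judged_true = []
    for dag, m, s in zip(chains, per, ss.spawn(len(chains))):
        if m == 0:
            continue
        (x, y), (y2, z) = sorted(dag.edges, key=lambda e: _chain_order(dag, e))
        query = Query(x, z)  # the transitive, absent edge
        batch = generate_batch(task, int(m), s, fixed_dag=dag, fixed_query=query)
        if judge is None:
            d = batch_decisions(params, batch.inputs, window)
        else:
            d = np.array([
                judge(ObservationSequence(o, source_dag=dag), query) > 0.5
                for o in batch.observations
            ])
        judged_true.append(d)
    rate = float(np.concatenate(judged_true).mean())
    return {"transitive_true_rate": rate, "chance": 0.5, "n_trials": n_trials}


def _chain_order(dag: CausalDag, edge) -> int:
    # order the two chain edges head-to-tail: X->Y before Y->Z
    heads = {e[0] for e in dag.edges}
    tails = {e[1] for e in dag.edges}
    return 0 if edge[0] not in tails else 1


def category_accuracies(
    params: RnnParams, task: TaskConfig, n_trials_per_category: int, seed,
    window: float = 0.1,
) -> pd.Series:
    """Judgment accuracy per 3-node DAG category on freshly generated trials."""
    from .model import evaluate_accuracy
    from .dag import DAG_CATEGORIES

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    out = {}
    for cat, s in zip(DAG_CATEGORIES, ss.spawn(len(DAG_CATEGORIES))):
        acc, _ = evaluate_accuracy(
            params, task, n_trials_per_category, s, dag_filter=cat, window=window
        )
        out[cat] = acc
    return pd.Series(out, name="accuracy")
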