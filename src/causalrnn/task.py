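"""Trial construction for the causal-judgment task.

A trial pairs a stochastic observation sequence with a single ordered
cause->effect query.  The network input at each timestep is a length
``M = 3 N`` vector: the N node-observation channels, then N one-hot cause
channels, then N one-hot effect channels.  Observations are pulsed
(``steps_per_obs`` steps each, optionally separated by ``gap_steps`` of
silence) while the query channels are tonic for the whole trial, including a
trailing query-only settle window where the judgment is read out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dag import (
    CausalDag,
    NoisyOrParams,
    ObservationSequence,
    activation_probability,
    enumerate_dags,
    sample_observations,
    _as_rng,
)


@dataclass(frozen=True)
class Query:
    """An ordered cause-effect pair; the trial asks whether edge (cause, effect) exists."""

    cause: int
    effect: int

    def __post_init__(self):
        if self.cause == self.effect:
            raise ValueError("query cause and effect must differ")


def all_queries(n_nodes: int) -> list[Query]:
    """All N(N-1) ordered queries, in row-major (cause, effect) order."""
    return [
        Query(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j
    ]


@dataclass(frozen=True)
class TaskConfig:
    n_nodes: int = 3
    n_obs: int = 50
    steps_per_obs: int = 5
    gap_steps: int = 0
    settle_steps: int = 20
    query_amplitude: float = 1.0
    params: NoisyOrParams = field(default_factory=NoisyOrParams)
    balance_labels: bool = True

    def __post_init__(self):
        if self.n_obs < 1 or self.steps_per_obs < 1 or self.gap_steps < 0:
            raise ValueError("invalid temporal configuration")
        if self.total_steps < 1:
            raise ValueError("trial length must be >= 1")

    @property
    def total_steps(self) -> int:
        return self.n_obs * (self.steps_per_obs + self.gap_steps) + self.settle_steps

    @property
    def n_inputs(self) -> int:
        return 3 * self.n_nodes


@dataclass
class Trial:
    observations: ObservationSequence
    query: Query
    label: bool
    inputs: np.ndarray  # T x M


def query_input_vector(query: Query, config: TaskConfig) -> np.ndarray:
    """The tonic M-vector carrying only the one-hot query channels."""
    n = config.n_nodes
    u = np.zeros(config.n_inputs)
    u[n + query.cause] = config.query_amplitude
    u[2 * n + query.effect] = config.query_amplitude
    return u


def observation_input_vector(pattern: Sequence[int], config: TaskConfig) -> np.ndarray:
    """The M-vector for one observation column (query channels zero)."""
    u = np.zeros(config.n_inputs)
    u[: config.n_nodes] = np.asarray(pattern, dtype=float)
    return u


def build_input_sequence(
    obs: ObservationSequence, query: Query, config: TaskConfig
) -> np.ndarray:
    """Deterministically lay out observations and query as a T x M input matrix."""
    n = config.n_nodes
    if obs.n_nodes != n:
        raise ValueError("observation node count does not match config")
    if not (0 <= query.cause < n and 0 <= query.effect < n):
        raise ValueError("query indices out of range")
    k = obs.n_obs
    t_total = k * (config.steps_per_obs + config.gap_steps) + config.settle_steps
    u = np.zeros((t_total, config.n_inputs))
    # (K, steps_per_obs + gap, N) block: pulse then silence, flattened in time
    block = np.zeros((k, config.steps_per_obs + config.gap_steps, n))
    block[:, : config.steps_per_obs, :] = obs.activity.T[:, None, :]
    u[: k * (config.steps_per_obs + config.gap_steps), :n] = block.reshape(-1, n)
    u += query_input_vector(query, config)
    return u


def recover_observations(inputs: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Invert build_input_sequence back to the N x K observation matrix."""
    n = config.n_nodes
    stride = config.steps_per_obs + config.gap_steps
    k = (inputs.shape[0] - config.settle_steps) // stride
    return inputs[: k * stride : stride, :n].T.astype(np.int8)


def recover_query(inputs: np.ndarray, config: TaskConfig) -> Query:
    n = config.n_nodes
    cause = int(np.argmax(inputs[0, n : 2 * n]))
    effect = int(np.argmax(inputs[0, 2 * n :]))
    return Query(cause, effect)


def generate_trial(
    config: TaskConfig,
    seed,
    fixed_dag: Optional[CausalDag] = None,
    fixed_query: Optional[Query] = None,
) -> Trial:
    """Draw one trial: a DAG, one observation sequence, and a single query.

    The DAG is uniform over all DAGs on ``n_nodes`` and the query uniform over
    ordered pairs, unless fixed.  With ``balance_labels`` a fair label coin is
    flipped first and (DAG, query) pairs are rejection-sampled until the edge
    membership matches, yielding a 50/50 true/false marginal.  The trial seed
    splits into independent substreams for the structure draw, the observation
    sampling, and nothing else.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    struct_rng, obs_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    dags = enumerate_dags(config.n_nodes)
    queries = all_queries(config.n_nodes)

    def draw():
        dag = fixed_dag if fixed_dag is not None else dags[struct_rng.integers(len(dags))]
        query = fixed_query if fixed_query is not None else queries[struct_rng.integers(len(queries))]
        return dag, query

    dag, query = draw()
    # balancing requires freedom in the DAG draw; a fixed DAG pins the label
    if config.balance_labels and fixed_dag is None:
        want = bool(struct_rng.random() < 0.5)
        while dag.has_edge(query.cause, query.effect) != want:
            dag, query = draw()
    obs = sample_observations(dag, config.n_obs, config.params, obs_rng)
    label = dag.has_edge(query.cause, query.effect)
    return Trial(obs, query, label, build_input_sequence(obs, query, config))


@dataclass
class TrialBatch:
    inputs: np.ndarray  # n x T x M
    labels: np.ndarray  # n bools
    queries: np.ndarray  # n x 2 (cause, effect)
    dag_indices: np.ndarray  # n indices into enumerate_dags(n_nodes)
    observations: np.ndarray  # n x N x K

    def __len__(self) -> int:
        return len(self.labels)


def _edge_consistent_dag_indices(n_nodes: int):
    """For each (query, label), the indices of DAGs with/without that edge."""
    dags = enumerate_dags(n_nodes)
    queries = all_queries(n_nodes)
    table = {}
    for qi, q in enumerate(queries):
        has = [i for i, d in enumerate(dags) if d.has_edge(q.cause, q.effect)]
        hasnt = [i for i, d in enumerate(dags) if not d.has_edge(q.cause, q.effect)]
        table[qi] = (np.array(hasnt), np.array(has))
    return dags, queries, table


def generate_batch(
    config: TaskConfig,
    n_trials: int,
    seed,
    fixed_dag: Optional[CausalDag] = None,
    fixed_query: Optional[Query] = None,
) -> TrialBatch:
    """Vectorized trial generation, distributionally matching generate_trial.

    Label balancing draws a fair coin per trial, then a DAG uniformly among
    those consistent with (query, label) — identical in law to per-trial
    rejection because every ordered edge appears in the same number of DAGs.
    """
    rng = _as_rng(seed)
    dags, queries, table = _edge_consistent_dag_indices(config.n_nodes)
    n_q = len(queries)

    if fixed_query is not None:
        q_idx = np.full(n_trials, queries.index(fixed_query))
    else:
        q_idx = rng.integers(n_q, size=n_trials)

    if fixed_dag is not None:
        dag_idx = np.full(n_trials, dags.index(fixed_dag))
    elif config.balance_labels:
        coins = rng.random(n_trials) < 0.5
        dag_idx = np.empty(n_trials, dtype=int)
        for qi in range(n_q):
            for lab in (0, 1):
                mask = (q_idx == qi) & (coins == bool(lab))
                pool = table[qi][lab]
                dag_idx[mask] = pool[rng.integers(len(pool), size=mask.sum())]
    else:
        dag_idx = rng.integers(len(dags), size=n_trials)

    n, k = config.n_nodes, config.n_obs
    obs = np.zeros((n_trials, n, k), dtype=np.int8)
    for di in np.unique(dag_idx):
        mask = dag_idx == di
        m = mask.sum()
        dag = dags[di]
        v = np.zeros((m, n, k), dtype=np.int8)
        for node in dag.topological_order():
            parents = dag.parents(node)
            a = v[:, list(parents), :].sum(axis=1) if parents else np.zeros((m, k))
            p = activation_probability(a, config.params)
            v[:, node, :] = rng.random((m, k)) < p
        obs[mask] = v

    labels = np.array(
        [dags[di].has_edge(queries[qi].cause, queries[qi].effect)
         for di, qi in zip(dag_idx, q_idx)]
    )

    # time layout: (K, steps_per_obs + gap) pulses, then the settle window
    stride = config.steps_per_obs + config.gap_steps
    t_total = config.total_steps
    inputs = np.zeros((n_trials, t_total, config.n_inputs))
    block = np.zeros((n_trials, k, stride, n))
    block[:, :, : config.steps_per_obs, :] = obs.transpose(0, 2, 1)[:, :, None, :]
    inputs[:, : k * stride, :n] = block.reshape(n_trials, -1, n)
    q_arr = np.array([(queries[qi].cause, queries[qi].effect) for qi in q_idx])
    rows = np.arange(n_trials)
    inputs[rows, :, n + q_arr[:, 0]] = config.query_amplitude
    inputs[rows, :, 2 * n + q_arr[:, 1]] = config.query_amplitude
    return TrialBatch(inputs, labels, q_arr, dag_idx, obs)


# --- shuffle controls ----------------------------------------------------

def circular_shuffle_node(obs: ObservationSequence, node: int, seed) -> ObservationSequence:
    """Cyclically rotate one node's row by a random nonzero offset.

    Preserves that row's activation count (and hence its marginal statistics)
    exactly while destroying its temporal alignment with the other rows.  With
    a single observation column there is no nonzero offset and the sequence is
    returned unchanged.
    """
    if not (0 <= node < obs.n_nodes):
        raise ValueError("node index out of range")
    k = obs.n_obs
    rng = _as_rng(seed)
    v = obs.activity.copy()
    if k > 1:
        offset = int(rng.integers(1, k))
        v[node] = np.roll(v[node], offset)
    return ObservationSequence(activity=v, source_dag=obs.source_dag)


def circular_shuffle_all(obs: ObservationSequence, seed) -> ObservationSequence:
    """Independent circular rotation of every node's row.

    Marginal activity statistics are preserved exactly; cross-node covariance
    is destroyed.
    """
    rng = _as_rng(seed)
    v = obs.activity.copy()
    k = obs.n_obs
    if k > 1:
        for node in range(obs.n_nodes):
            v[node] = np.roll(v[node], int(rng.integers(1, k)))
    return ObservationSequence(activity=v, source_dag=obs.source_dag)
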