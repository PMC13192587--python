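"""Exact Bayesian ideal observer over enumerated causal DAGs.

With the noisy-or parameters known, the likelihood of an observation sequence
under a candidate DAG factorizes over nodes and observation columns into
Bernoulli terms whose success probability depends only on the number of
active parents in the same column.  Posterior inference is exact by
enumeration (25 DAGs for three nodes); the edge marginal
P(edge (i,j) | observations) is the sum of posterior mass over DAGs
containing that edge.  The observer serves as a performance ceiling for the
trained network — it is a normative reference, not a mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import log_softmax, xlog1py, xlogy

from .dag import (
    CausalDag,
    NoisyOrParams,
    ObservationSequence,
    activation_probability,
    enumerate_dags,
)
from .task import Query


@dataclass
class DagPosterior:
    dags: list[CausalDag]
    log_likelihoods: np.ndarray
    posterior: np.ndarray
    edge_posterior: np.ndarray  # N x N, diagonal zero

    @property
    def map_dag(self) -> CausalDag:
        return self.dags[int(np.argmax(self.posterior))]


def dag_log_likelihood(
    obs: ObservationSequence, dag: CausalDag, params: NoisyOrParams
) -> float:
    """Log P(observations | dag, params) under the noisy-or model."""
    v = obs.activity
    if v.shape[0] != dag.n_nodes:
        raise ValueError("observation node count does not match dag")
    total = 0.0
    for node in range(dag.n_nodes):
        parents = dag.parents(node)
        a = v[list(parents)].sum(axis=0) if parents else np.zeros(v.shape[1])
        p = activation_probability(a, params)
        total += float(np.sum(xlogy(v[node], p) + xlog1py(1 - v[node], -p)))
    return total


def posterior_over_dags(
    obs: Optional[ObservationSequence],
    params: NoisyOrParams,
    n_nodes: int = 3,
    prior: Optional[Sequence[float]] = None,
) -> DagPosterior:
    """Posterior over all DAGs on ``n_nodes`` given observations (None = prior only).

    The prior defaults to uniform.  Normalization is stabilized through
    log-space softmax.
    """
    dags = enumerate_dags(n_nodes)
    if prior is None:
        log_prior = np.zeros(len(dags))
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (len(dags),) or np.any(prior < 0) or prior.sum() == 0:
            raise ValueError("prior must be nonnegative per-DAG weights, not all zero")
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
    if obs is None:
        logliks = np.zeros(len(dags))
    else:
        logliks = np.array([dag_log_likelihood(obs, d, params) for d in dags])
    post = np.exp(log_softmax(logliks + log_prior))
    edge_post = np.zeros((n_nodes, n_nodes))
    for w, d in zip(post, dags):
        for i, j in d.edges:
            edge_post[i, j] += w
    return DagPosterior(dags, logliks, post, edge_post)


def ideal_query_judgment(
    obs: Optional[ObservationSequence],
    query: Query,
    params: NoisyOrParams,
    n_nodes: int = 3,
    prior: Optional[Sequence[float]] = None,
) -> float:
    """Posterior probability that the queried edge exists (decision at > 0.5)."""
    post = posterior_over_dags(obs, params, n_nodes=n_nodes, prior=prior)
    return float(post.edge_posterior[query.cause, query.effect])


def balanced_prior(n_nodes: int, query: Query) -> np.ndarray:
    """Per-DAG prior matching the label-balanced trial generator.

    Balanced generation flips a fair label coin then draws a DAG uniformly
    among those consistent with the queried edge, so the DAG prior given the
    query is half the mass spread over with-edge DAGs and half over
    without-edge DAGs.
    """
    dags = enumerate_dags(n_nodes)
    has = np.array([d.has_edge(query.cause, query.effect) for d in dags])
    prior = np.where(has, 0.5 / has.sum(), 0.5 / (~has).sum())
    return prior
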