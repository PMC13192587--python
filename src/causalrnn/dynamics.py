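"""Reverse-engineering trained networks as dynamical systems.

Under tonic query-only input the network's slow dynamics are characterized by
fixed points of the discrete update, found by minimizing the speed function

    q(x) = 1/2 || -x + tanh(W x + B u_query) ||^2 .

For a trained network the fixed points of each query organize into an
approximate line attractor whose axis runs from the "false" to the "true" end
of the judgment.  Linearization at a fixed point x* gives

    z[t+1] ~= J_rec z[t] + J_inp w[t+1],
    J_rec = (1-alpha) I + alpha D W,   J_inp = alpha D B,
    D = diag(1 - tanh^2(W x* + B u_query)),

and with the leading eigenvalue lambda_1 ~= 1 (an integrating mode) the
terminal displacement after a single observation w_hat is approximately
r (l^T J_inp w_hat), where r and l are the leading right and left
eigenvectors of J_rec: r is the direction of slow movement and l the input
selectivity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import eig as dense_eig
from sklearn.decomposition import PCA

from .task import Query, TaskConfig, all_queries, generate_batch, query_input_vector, observation_input_vector
from .model import RnnParams, simulate_batch


# --- speed function and its gradient -------------------------------------

def speed(x: np.ndarray, u_query: np.ndarray, params: RnnParams) -> float:
    """q(x) = 1/2 ||-x + tanh(Wx + Bu)||^2; zero exactly at fixed points."""
    g = -x + np.tanh(params.W @ x + params.B @ u_query)
    return 0.5 * float(g @ g)


def _speed_and_grad(x, u_query, params):
    a = params.W @ x + params.B @ u_query
    th = np.tanh(a)
    g = -x + th
    d = 1.0 - th**2
    grad = -g + params.W.T @ (d * g)
    return 0.5 * float(g @ g), grad


@dataclass
class FixedPoint:
    x_star: np.ndarray
    query: Query
    speed: float
    jac_rec: np.ndarray
    jac_inp: np.ndarray
    eigenvalues: np.ndarray          # sorted by real part (desc), ties by |.|
    right_eigenvectors: np.ndarray   # columns, same order
    left_eigenvectors: np.ndarray    # rows, biorthogonal to the columns
    top_right: Optional[np.ndarray] = None  # real leading pair, l.r = 1
    top_left: Optional[np.ndarray] = None

    @property
    def top_eigenvalue(self) -> complex:
        return self.eigenvalues[0]


@dataclass
class LineAttractor:
    query: Query
    points: list  # FixedPoints sorted by axis projection (false -> true)
    centroid: np.ndarray
    axis: np.ndarray  # unit vector, true-end positive

    def projections(self) -> np.ndarray:
        return np.array([(p.x_star - self.centroid) @ self.axis for p in self.points])


def linearize(x_star: np.ndarray, u: np.ndarray, params: RnnParams):
    """Jacobians of the Euler update at (x_star, u) plus the eigensystem.

    Left eigenvectors are the rows of the inverse right-eigenvector matrix,
    which enforces biorthogonality L @ R = I for non-defective spectra; a
    defective (numerically singular) eigenbasis is flagged with a warning and
    the leading left/right pair omitted.
    """
    alpha = params.alpha
    a = params.W @ x_star + params.B @ u
    d = 1.0 - np.tanh(a) ** 2
    jac_rec = (1.0 - alpha) * np.eye(params.n_hidden) + alpha * (d[:, None] * params.W)
    jac_inp = alpha * (d[:, None] * params.B)

    evals, vr = dense_eig(jac_rec)
    order = np.lexsort((-np.abs(evals), -evals.real))
    evals, vr = evals[order], vr[:, order]
    try:
        vl = np.linalg.inv(vr)
        defective = not np.allclose(vl @ vr, np.eye(len(evals)), atol=1e-6)
    except np.linalg.LinAlgError:
        vl, defective = None, True
    top_r = top_l = None
    if defective:
        warnings.warn("near-defective eigenbasis; leading eigenvector pair omitted")
    elif abs(evals[0].imag) < 1e-10:
        # real simple leading mode: real biorthonormal pair with l . r = 1
        top_r = vr[:, 0].real.copy()
        top_l = vl[0].real.copy()
        s = top_l @ top_r
        top_l = top_l / s
    return jac_rec, jac_inp, evals, vr, vl, top_r, top_l


def _make_fixed_point(x, query, u, params) -> FixedPoint:
    jac_rec, jac_inp, evals, vr, vl, top_r, top_l = linearize(x, u, params)
    return FixedPoint(
        x_star=x,
        query=query,
        speed=speed(x, u, params),
        jac_rec=jac_rec,
        jac_inp=jac_inp,
        eigenvalues=evals,
        right_eigenvectors=vr,
        left_eigenvectors=vl,
        top_right=top_r,
        top_left=top_l,
    )


def find_fixed_points(
    params: RnnParams,
    query: Query,
    task: TaskConfig,
    seed,
    n_seeds: int = 512,
    tol: float = 1e-10,
    dedup_radius: float = 0.05,
    n_sample_trials: int = 100,
    jitter: float = 0.1,
) -> list[FixedPoint]:
    """Locate slow points of the query-conditioned dynamics.

    Candidate initial states are subsampled from trajectories simulated on
    freshly generated trials of the given query, jittered with isotropic
    Gaussian noise, then optimized in two stages: a joint L-BFGS descent of
    the summed speed (the objective decouples across candidates), followed by
    a Newton polish (root-finding on -x + tanh(Wx+Bu) with the analytic
    Jacobian) of every candidate below a loose cut.  Survivors with
    q < tol are deduplicated within ``dedup_radius`` (keeping the
    lowest-speed representative) and returned sorted by readout logit.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    trial_ss, pick_ss = ss.spawn(2)
    rng = np.random.default_rng(pick_ss)
    u = query_input_vector(query, task)

    batch = generate_batch(task, n_sample_trials, trial_ss, fixed_query=query)
    states = simulate_batch(params, batch.inputs).reshape(-1, params.n_hidden)
    idx = rng.integers(states.shape[0], size=n_seeds)
    x0 = states[idx] + jitter * rng.standard_normal((n_seeds, params.n_hidden))

    w_t = params.W.T

    def batch_obj(flat):
        x = flat.reshape(n_seeds, -1)
        a = x @ w_t + u @ params.B.T
        th = np.tanh(a)
        g = th - x
        grad = -g + (((1.0 - th**2) * g) @ params.W)
        return 0.5 * float((g * g).sum()), grad.ravel()

    res = optimize.minimize(
        batch_obj, x0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-18, "gtol": 1e-12},
    )
    cands = res.x.reshape(n_seeds, -1)

    def resid(x):
        return np.tanh(params.W @ x + params.B @ u) - x

    def resid_jac(x):
        th = np.tanh(params.W @ x + params.B @ u)
        return (1.0 - th**2)[:, None] * params.W - np.eye(params.n_hidden)

    polished = []
    loose = max(tol * 1e6, 1e-8)
    for x in cands:
        q = speed(x, u, params)
        if q < tol:
            polished.append(x)
            continue
        if q > loose:
            continue
        # Newton polish for near-misses only; along a line of fixed points the
        # residual Jacobian is singular and root-finding can slide arbitrarily
        # far down the line, so reject polish steps that travel
        sol = optimize.root(resid, x, jac=resid_jac, method="hybr")
        if (sol.success and np.linalg.norm(sol.x - x) <= dedup_radius
                and speed(sol.x, u, params) < tol):
            polished.append(sol.x)

    if not polished:
        warnings.warn(f"no fixed points below tol={tol} for query {query}")
        return []

    # dedup: greedy by increasing speed, merge within dedup_radius
    polished.sort(key=lambda x: speed(x, u, params))
    kept: list[np.ndarray] = []
    for x in polished:
        if all(np.linalg.norm(x - y) > dedup_radius for y in kept):
            kept.append(x)
    kept.sort(key=lambda x: float(params.C @ x))
    return [_make_fixed_point(x, query, u, params) for x in kept]


def slow_mode_prediction(
    fp: FixedPoint, w_hat: np.ndarray, horizon: Optional[int] = None
) -> tuple[np.ndarray, float]:
    """Predicted terminal displacement after one observation input w_hat.

    Returns (displacement J-vector, scalar magnitude l^T J_inp w_hat).  The
    displacement is r times the scalar; with a finite ``horizon`` the
    leading-eigenvalue decay lambda_1^horizon is applied (negligible when
    lambda_1 ~= 1, the integrating regime this approximation assumes).
    """
    if fp.top_right is None or fp.top_left is None:
        raise ValueError("leading eigenvalue is complex or defective; slow-mode "
                         "prediction requires a real simple leading mode")
    scalar = float(fp.top_left @ (fp.jac_inp @ w_hat))
    scale = 1.0 if horizon is None else float(fp.eigenvalues[0].real) ** horizon
    return fp.top_right * (scalar * scale), scalar


def build_line_attractor(points: Sequence[FixedPoint], params: RnnParams) -> LineAttractor:
    """Fit the judgment axis through one query's fixed points.

    The axis is the first principal component of the point locations, signed
    so that movement along it increases the readout logit C.x (true-end
    positive); points are returned sorted from the false end to the true end.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 fixed points to build a line attractor")
    locs = np.array([p.x_star for p in points])
    pca = PCA(n_components=1).fit(locs)
    axis = pca.components_[0]
    axis = axis / np.linalg.norm(axis)
    proj = locs @ axis
    logits = locs @ params.C
    slope = np.cov(proj, logits)[0, 1]
    sign = np.sign(slope) if slope != 0 else np.sign(axis @ params.C) or 1.0
    axis = axis * sign
    order = np.argsort(locs @ axis)
    return LineAttractor(
        query=points[0].query,
        points=[points[i] for i in order],
        centroid=locs.mean(axis=0),
        axis=axis,
    )


def interior_points(attr: LineAttractor, fraction: float = 0.6) -> list[FixedPoint]:
    """Fixed points in the middle ``fraction`` of the attractor by axis position.

    The consolidating extremes of the line are excluded when asserting the
    integrating-mode (eigenvalue ~= 1) property.
    """
    proj = attr.projections()
    lo, hi = np.quantile(proj, [(1 - fraction) / 2, 1 - (1 - fraction) / 2])
    return [p for p, z in zip(attr.points, proj) if lo <= z <= hi]


def observation_patterns(n_nodes: int) -> list[tuple[int, ...]]:
    """All 2^N binary observation patterns in lexicographic order."""
    return list(itertools.product((0, 1), repeat=n_nodes))


def input_effect_map(
    attr: LineAttractor,
    params: RnnParams,
    task: TaskConfig,
    relax_steps: int = 200,
) -> dict:
    """Displacement along the judgment axis for every (fixed point, pattern).

    From each fixed point, one observation pulse (``steps_per_obs`` steps of
    the pattern with the query on) is presented, then the state relaxes for
    ``relax_steps`` under query-only input.  Returned arrays have shape
    (n_fixed_points, 2^N): 'instant' holds the axis displacement after the
    first pulse step, 'relaxed' after the full relaxation.
    """
    patterns = observation_patterns(task.n_nodes)
    u_q = query_input_vector(attr.query, task)
    n_fp = len(attr.points)
    instant = np.zeros((n_fp, len(patterns)))
    relaxed = np.zeros((n_fp, len(patterns)))
    for i, fp in enumerate(attr.points):
        p0 = fp.x_star @ attr.axis
        for j, pat in enumerate(patterns):
            u_obs = observation_input_vector(pat, task) + u_q
            seq = np.vstack(
                [np.tile(u_obs, (task.steps_per_obs, 1)),
                 np.tile(u_q, (relax_steps, 1))]
            )
            states = simulate_batch(params, seq[None], x0=fp.x_star)[0]
            instant[i, j] = states[0] @ attr.axis - p0
            relaxed[i, j] = states[-1] @ attr.axis - p0
    return {"patterns": patterns, "instant": instant, "relaxed": relaxed}


def traverse_attractor(
    params: RnnParams,
    attr: LineAttractor,
    start_fp: FixedPoint,
    pattern: Sequence[int],
    n_repeats: int,
    task: TaskConfig,
    relax_steps: int = 20,
) -> np.ndarray:
    """Axis position after each of ``n_repeats`` presentations of one pattern.

    Each presentation is an observation pulse followed by ``relax_steps`` of
    query-only relaxation, mimicking the trial's pulse/settle rhythm.
    """
    u_q = query_input_vector(attr.query, task)
    u_obs = observation_input_vector(pattern, task) + u_q
    block = np.vstack(
        [np.tile(u_obs, (task.steps_per_obs, 1)), np.tile(u_q, (relax_steps, 1))]
    )
    x = start_fp.x_star.copy()
    positions = np.empty(n_repeats)
    for r in range(n_repeats):
        x = simulate_batch(params, block[None], x0=x)[0, -1]
        positions[r] = (x - attr.centroid) @ attr.axis
    return positions


def attractor_geometry(attractors: dict) -> dict:
    """Pairwise centroid distances between the per-query line attractors.

    Returns the 6x6 distance matrix (DataFrame labeled 'cause->effect') and
    mean distances within/between same-cause and same-effect query groups.
    """
    queries = list(attractors.keys())
    names = [f"{q.cause}->{q.effect}" for q in queries]
    cents = np.array([attractors[q].centroid for q in queries])
    dist = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
    df = pd.DataFrame(dist, index=names, columns=names)

    def group_means(attr_of):
        same, diff = [], []
        for i in range(len(queries)):
            for j in range(i + 1, len(queries)):
                (same if attr_of(queries[i]) == attr_of(queries[j]) else diff).append(
                    dist[i, j]
                )
        return float(np.mean(same)), float(np.mean(diff))

    same_cause, diff_cause = group_means(lambda q: q.cause)
    same_effect, diff_effect = group_means(lambda q: q.effect)
    return {
        "distances": df,
        "same_cause_mean": same_cause,
        "different_cause_mean": diff_cause,
        "same_effect_mean": same_effect,
        "different_effect_mean": diff_effect,
    }


def pca_projection(trajectories: Sequence[np.ndarray], n_components: int = 3):
    """Project state trajectories into a single common principal-component basis.

    The basis is fit on all states pooled across trajectories (a shared
    reference frame across queries); returns (projections, variance_fractions,
    components).
    """
    pooled = np.vstack(trajectories)
    if pooled.shape[0] < n_components:
        raise ValueError("not enough samples for the requested components")
    pca = PCA(n_components=n_components).fit(pooled)
    projs = [pca.transform(t) for t in trajectories]
    return projs, pca.explained_variance_ratio_, pca.components_


@dataclass
class DecisionAxis:
    axis: np.ndarray            # unit vector
    difference_norm: float      # ||mean difference|| before normalization


def decision_axis(
    params: RnnParams,
    task: TaskConfig,
    n_trials: int,
    seed,
    query: Optional[Query] = None,
    shuffle_labels: bool = False,
) -> DecisionAxis:
    """Normalized difference of mean terminal states, edge-present minus absent.

    With ``query`` fixed this is the per-query judgment direction; pooled over
    queries it is the global decision axis.  ``shuffle_labels`` permutes the
    labels as a null control (the difference norm should then be near zero).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    gen_ss, shuf_ss = ss.spawn(2)
    batch = generate_batch(task, n_trials, gen_ss, fixed_query=query)
    terminal = simulate_batch(params, batch.inputs)[:, -1]
    labels = batch.labels.copy()
    if shuffle_labels:
        np.random.default_rng(shuf_ss).shuffle(labels)
    if labels.all() or (~labels).all():
        raise ValueError("need both labels present to define a decision axis")
    diff = terminal[labels].mean(axis=0) - terminal[~labels].mean(axis=0)
    norm = float(np.linalg.norm(diff))
    axis = diff / norm if norm > 0 else diff
    return DecisionAxis(axis=axis, difference_norm=norm)
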