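# Methods

## The task

A trial presents `K` stochastic observations of `N` binary variables
generated from an unknown directed acyclic graph (DAG), together with a tonic
cue naming one ordered cause–effect pair.  The subject — here a recurrent
network — must report whether that directed edge exists in the generating
graph.  The generative model is the noisy-or parameterization: node `n` in
observation `k` activates with probability

    P(v_nk = 1 | a_nk) = 1 − (1 − p_spont) · (1 − p_cause)^{a_nk},

where `a_nk` counts the node's currently active parents in the same
observation column.  Columns are i.i.d. ancestral samples; there is no
temporal coupling between observations.  Noisy-or structure is partially
identifiable from observations alone because edges shape both marginal rates
(children are more active than parents) and cross-node covariance.

Defaults: `p_spont = 0.15`, `p_cause = 0.9`, `K = 50`, three nodes.  These
were calibrated once against the exact Bayesian observer: the study regime
should be solvable to high accuracy from `K = 50` observations yet remain
genuinely stochastic.  Measured balanced-trial accuracy of the ideal
observer across candidate settings (1,000–2,000 trials each):

| p_spont | p_cause | K  | Bayes ceiling |
|--------:|--------:|---:|--------------:|
| 0.05    | 0.8     | 50 | 0.87          |
| 0.10    | 0.8     | 50 | 0.94          |
| 0.10    | 0.9     | 50 | 0.96          |
| 0.15    | 0.8     | 50 | 0.97          |
| **0.15**| **0.9** | **50** | **0.98**  |
| 0.10    | 0.8     | 100| 0.98          |

A higher spontaneous rate is informative rather than noisy here: parents
must be active for their edges to leave a covariance signature, so very
sparse activity starves the observer of evidence.  The chosen setting keeps
`K = 50` (and hence the trial length) while leaving headroom for a trained
network to approach mid-0.9 accuracy.  All 25 three-node DAGs are
enumerated exhaustively and fall into six structural categories (empty 1,
single-edge 6, fork 3, collider 3, chain 6, mediator 6).

Trials are label-balanced to 50/50 true/false.  The reference implementation
of balancing is per-trial rejection sampling of (DAG, query) pairs against a
fair label coin; the vectorized batch generator draws the coin first and then
a DAG uniformly among those consistent with the (query, label) pair.  The two
schemes are identical in distribution because every ordered edge is contained
in exactly 8 of the 25 DAGs (and absent from 17), independently of the edge.

## Input encoding

The network input has `M = 3N` channels: `N` observation channels, `N`
one-hot cause-query channels, and `N` one-hot effect-query channels.  Each
observation column is held for `steps_per_obs = 5` integration steps
(`gap_steps = 0` between pulses), followed by a `settle_steps = 20`
query-only window; query channels are tonic at amplitude 1.0 for the whole
trial.  Total trial length is therefore `T = 50·5 + 20 = 270` steps.  The
pulse length and trailing settle window are presentation choices of this
package: the settle window gives the readout a defined, observation-free
decision epoch, matching how the judgment is interrogated in the analyses.

## The network

Hidden dynamics follow the standard leaky tanh rate equation
`τ dx/dt = −x + tanh(Wx + Bu)`, integrated by forward Euler:

    x[t+1] = (1 − α) x[t] + α tanh(W x[t] + B u[t+1]),   α = dt/τ = 0.2,

with `J = 128` hidden units, scalar readout `y = σ(C x)`, zero initial state
every trial, and no intrinsic noise.  A trial is judged "true" when the mean
output over the final 10% of timesteps exceeds 0.5 (ties resolve to false).

## Training

Gradients are computed by explicit backpropagation through time, written out
in numpy and verified against central finite differences; the BPTT pass runs
in float32 for throughput (the optimizer and all analysis code are float64),
so training reproducibility is documented at ~1e-6 tolerance rather than
bitwise.  Updates use Adam (lr 1e-3, β = 0.9/0.999), batch 64, global-norm
gradient clipping at 1.0, for up to 8,000 steps with early stopping once
held-out accuracy (fresh trials, trailing-window decisions) reaches 0.95.
The learning rate holds its base value for the first half of the run, then
cosine-decays to 10%.

Three choices matter for trainability and were settled by convergence
experiments during development:

- **Loss support.** Binary cross-entropy is applied to the output at *every*
  timestep of the trial, not only the terminal window.  With terminal-only
  loss the network sat at chance for thousands of steps (the gradient signal
  through 270 steps of leaky dynamics is too sparse); full-trajectory
  supervision encourages on-line integration and learns reliably.  Decisions
  are still *read out* from the trailing window only, so the behavioral
  contract is unchanged.
- **Initialization.** `W` is Gaussian with std `1.5/√J` (a Glorot scale
  inflated by gain 1.5), lengthening the intrinsic memory of the untrained
  network; `B` is Glorot inflated by gain 3.0 — the single most effective
  accelerator of the escape from the initial chance plateau (stronger input
  drive gives coincidence detection a usable gradient); `C` starts at zero
  so early outputs are 0.5.
- **Schedule.** Holding the full learning rate through the plateau phase is
  essential (decaying from step 0 stalled learning entirely); decaying in
  the second half tames the late oscillations in held-out accuracy.
- **Regularization.** L2 weight decay (1e-4 on W, B, C) plus a firing-rate
  penalty `5e-3 · mean(x²)`, as is standard for rate networks destined for
  fixed-point analysis.  Without it the trained attractors grow into long,
  strongly curved arcs at large state norms (deep tanh saturation); the
  penalties keep state norms moderate and the fixed-point geometry closer
  to straight lines, at no measurable cost in held-out accuracy.

Each training step's trials are generated fresh from the task distribution;
nothing is reused, so held-out evaluation is simply more fresh trials.
All seeds derive from a single master seed through `numpy` `SeedSequence`
spawning (order: init, data, eval), making runs reproducible to the bit on a
fixed BLAS.

## The ideal observer

The Bayesian ceiling enumerates all DAGs, scores each by the exact noisy-or
log likelihood (Bernoulli terms with the same-column active-parent count),
and normalizes in log space.  The judgment for a query is the posterior edge
marginal.  The observer knows the true `p_spont`/`p_cause` (it is a ceiling,
not an inference contribution) and, when compared on balanced trials, uses
the prior matched to the balanced generator (half the mass on with-edge
DAGs).  Its accuracy upper-bounds the trained network at matched `K`.

## Behavioral probes

- **Category accuracy**: fresh trials restricted to each of the six DAG
  categories; trained networks are consistently weakest on chains, and the
  chain deficit concentrates on the transitive query X→Z of X→Y→Z (the
  transitivity bias; rate of endorsing the absent transitive edge > 0.5).
- **Circular-shuffle probes**: rotating one node's observation row by a
  random offset preserves its activation count exactly while destroying its
  covariance with other rows.  Shuffling the non-queried common cause of a
  fork degrades accuracy on the A→B query (the network uses C to explain
  away the A–B covariance); per-node independent shuffles preserve all
  marginals yet abolish recovery of the full graph, showing judgments use
  covariance, not marginal rates alone.  Paired significance uses a Wilcoxon
  signed-rank test on block-aggregated correctness (blocks of 50 trials;
  aggregation avoids degenerate all-0/1 pairs).
- **Implicit graph readout**: with one observation sequence held fixed, all
  six ordered queries are presented in separate runs; thresholded judgments
  assemble an estimated adjacency matrix even though training never queries
  more than one edge per sequence.  Similarity between estimates is the
  fraction of the six ordered pairs on which they agree.  The correlation
  control notes that the observation correlation matrix is symmetric by
  construction, so any direction-discriminating readout (estimate[0,2] ≠
  estimate[2,0]) cannot be a thresholded correlation.

## Dynamical analysis

Fixed points of the query-conditioned dynamics (observations off, query on)
minimize the speed `q(x) = ½‖−x + tanh(Wx + Bu_query)‖²`.  Candidates are
512 states subsampled from 100 simulated trials of that query, jittered with
isotropic noise (scale 0.1), descended jointly by L-BFGS (the objective
decouples across candidates), then Newton-polished (Powell hybrid root
finding on the residual with analytic Jacobian) when within 1e-8 of zero
speed.  Because a line of fixed points makes the residual Jacobian singular
along the line, polish steps that move farther than the dedup radius are
rejected — otherwise root finding slides arbitrarily down the line and
collapses the attractor to one point.  Survivors below `q < 1e-10` are
deduplicated within Euclidean radius 0.05 keeping the lowest-speed
representative.  The finder is validated on a constructed network whose
fixed line is known analytically (a recurrent matrix with eigenvalue exactly
1 along a chosen direction, driven only in the contracting subspace at ~1e-3
amplitude so the cubic tanh error ~1e-9 is negligible); recovered points
must lie within 1e-3 of the true line.

Linearization at a fixed point gives `J_rec = (1−α)I + αDW` and
`J_inp = αDB` with `D = diag(1 − tanh²(Wx* + Bu))`, checked against central
finite differences (1e-6 relative).  Eigenvalues are sorted by real part
(ties by magnitude); left eigenvectors are rows of the inverse
right-eigenvector matrix, which enforces biorthogonality `L·R = I` (1e-8)
for non-defective spectra; complex leading pairs are reported but excluded
from slow-mode predictions.

The **line attractor** for a query is the first principal component of its
fixed-point cloud, signed so movement along the axis increases the readout
logit; "interior" points — used for the eigenvalue ≈ 1 assertion — are the
middle 60% by axis projection, excluding the consolidating extremes.  The
**slow-mode approximation** predicts the relaxed displacement after a single
observation `ŵ` as `z_T ≈ r (ℓᵀ J_inp ŵ)`; it is checked against full
nonlinear relaxation (300 steps) with relative error required below 20% for
small pulses and shrinking roughly quadratically with pulse amplitude.
Attractor geometry is summarized by centroid distances, grouped by shared
cause and shared effect.  Fixed points are analyzed for the discrete Euler
map; its fixed-point set coincides with that of the continuous-time flow.

## Problem sizes and seeds

Quantitative runs use: one trained network per run (8,000 optimization
steps, roughly ten minutes on one CPU), 2,000 fresh balanced trials for
accuracy estimates, 500 paired trials (10 blocks) for shuffle tests, 100
shuffles for the graph-recovery control, and 256–512 speed-minimization
seeds per query.  These sizes give binomial standard errors ≈ 0.01 on
accuracies while keeping a full reproduction under twenty minutes on a
single CPU.  All entry points accept a single seed from which every stream
derives.

A caveat on attractor geometry: the per-query fixed-point sets of networks
trained at this scale form slightly *curved* arcs in full state space — the
first principal component of a query's point cloud typically explains
0.75–0.95 of its variance rather than ≥ 0.9 uniformly.  Longer training
increases the number of recovered fixed points and task accuracy but also
elongates and bends the arcs; the L2 penalties temper, but do not remove,
this curvature.  The line-attractor description is therefore a good first
approximation whose residual curvature the test suite measures and reports
honestly rather than asserts away.

## Synthetic data and scope

All data are generated by the package itself; the generator *is* the task
definition, so passing tests demonstrate properties of networks trained on
this synthetic task, not claims about biological brains or human behavior.
Known limitations: observations are i.i.d. in k (no temporal kernels); only
2–4-node graphs are enumerable; the noisy-or parameters of the original
study conditions are fixed package defaults (`p_spont = 0.1`,
`p_cause = 0.8`) recorded in every archive; training quality varies with
seed — behavioral signatures are asserted directionally, not at exact
magnitudes.
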