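"""Dynamical-analysis machinery checked against analytic constructions."""

import numpy as np
import pytest

from causalrnn.model import RnnParams
from causalrnn.task import Query, TaskConfig, query_input_vector
from causalrnn.dynamics import (
    DecisionAxis,
    FixedPoint,
    build_line_attractor,
    decision_axis,
    find_fixed_points,
    input_effect_map,
    interior_points,
    linearize,
    observation_patterns,
    pca_projection,
    slow_mode_prediction,
    speed,
    _make_fixed_point,
)


def small_params(j=8, m=9, seed=2, scale=0.35, tau=5.0):
    r = np.random.default_rng(seed)
    return RnnParams(
        W=r.normal(0, scale / np.sqrt(j), (j, j)),
        B=r.normal(0, 0.25, (j, m)),
        C=r.normal(0, 0.5, j),
        tau=tau,
        dt=1.0,
    )


def line_attractor_params(j=12, m=9, amp=1e-3, seed=4):
    """A network with an analytically known line of fixed points.

    W = I on a chosen unit direction d plus a contraction elsewhere, so in the
    small-amplitude regime (tanh ~ identity to cubic order) every
    x = x_p + t d with (I - W) x_p = B u is a fixed point.  Amplitudes are
    kept ~1e-3 so the cubic tanh error (~1e-9) is far below the 1e-3
    recovery tolerance.
    """
    r = np.random.default_rng(seed)
    d = r.standard_normal(j)
    d /= np.linalg.norm(d)
    q, _ = np.linalg.qr(r.standard_normal((j, j)))
    # orthonormal basis with first column d
    q[:, 0] = d
    q, _ = np.linalg.qr(q)
    d = q[:, 0]
    evals = np.concatenate([[1.0], r.uniform(0.2, 0.6, j - 1)])
    w = q @ np.diag(evals) @ q.T
    b = np.zeros((j, m))
    # query channels drive only the contracting subspace (orthogonal to d)
    drive = q[:, 1:] @ r.normal(0, amp, (j - 1, 6))
    b[:, 3:] = drive
    c = d.copy()
    return RnnParams(W=w, B=b, C=c, tau=5.0, dt=1.0), d


class TestSpeed:
    def test_zero_at_origin_without_input(self):
        p = small_params()
        assert speed(np.zeros(8), np.zeros(9), p) == 0.0

    def test_closed_form_when_weights_zero(self):
        p = RnnParams(W=np.zeros((4, 4)), B=np.zeros((4, 9)), C=np.zeros(4),
                      tau=5.0, dt=1.0)
        v = np.array([1.0, -2.0, 0.5, 0.0])
        assert speed(v, np.zeros(9), p) == pytest.approx(0.5 * v @ v)

    def test_zero_at_self_consistent_state(self):
        p = small_params(scale=0.3)
        u = np.zeros(9)
        u[3] = 1.0
        x = np.zeros(8)
        for _ in range(2000):
            x = np.tanh(p.W @ x + p.B @ u)
        assert speed(x, u, p) < 1e-20


class TestLinearize:
    def test_origin_alpha_one_gives_w(self):
        p = small_params(tau=1.0)
        jac_rec, jac_inp, *_ = linearize(np.zeros(8), np.zeros(9), p)
        np.testing.assert_allclose(jac_rec, p.W, atol=1e-14)
        np.testing.assert_allclose(jac_inp, p.B, atol=1e-14)

    def test_finite_difference_jacobians(self):
        """Analytic Jacobians match central differences at random states."""
        from causalrnn.model import step

        p = small_params()
        r = np.random.default_rng(9)
        eps = 1e-6
        for _ in range(20):
            x = r.normal(0, 0.5, 8)
            u = r.normal(0, 0.5, 9)
            jac_rec, jac_inp, *_ = linearize(x, u, p)
            num_rec = np.empty((8, 8))
            for k in range(8):
                dx = np.zeros(8)
                dx[k] = eps
                num_rec[:, k] = (step(x + dx, u, p) - step(x - dx, u, p)) / (2 * eps)
            np.testing.assert_allclose(jac_rec, num_rec, rtol=1e-6, atol=1e-9)
            num_inp = np.empty((8, 9))
            for k in range(9):
                du = np.zeros(9)
                du[k] = eps
                num_inp[:, k] = (step(x, u + du, p) - step(x, u - du, p)) / (2 * eps)
            np.testing.assert_allclose(jac_inp, num_inp, rtol=1e-6, atol=1e-9)

    def test_symmetric_w_gives_real_spectrum_at_origin(self):
        r = np.random.default_rng(1)
        w = r.standard_normal((6, 6))
        w = (w + w.T) / 2
        p = RnnParams(W=w, B=np.zeros((6, 9)), C=np.zeros(6), tau=2.0, dt=1.0)
        *_, evals, vr, vl, tr, tl = linearize(np.zeros(6), np.zeros(9), p)
        assert np.abs(evals.imag).max() < 1e-10

    def test_biorthogonality(self):
        p = small_params(seed=11)
        *_, evals, vr, vl, tr, tl = linearize(
            np.random.default_rng(0).normal(0, 0.3, 8), np.zeros(9), p
        )
        np.testing.assert_allclose(vl @ vr, np.eye(8), atol=1e-8)

    def test_eigenvalues_sorted_by_real_part(self):
        p = small_params(seed=12)
        *_, evals, vr, vl, tr, tl = linearize(np.zeros(8), np.zeros(9), p)
        assert np.all(np.diff(evals.real) <= 1e-12)

    def test_one_step_error_scales_quadratically(self):
        """Linearized one-step prediction error ~ ||perturbation||^2."""
        from causalrnn.model import step

        p = small_params(seed=13)
        r = np.random.default_rng(5)
        x0 = r.normal(0, 0.3, 8)
        u = r.normal(0, 0.4, 9)
        jac_rec, *_ = linearize(x0, u, p)
        base = step(x0, u, p)
        direction = r.standard_normal(8)
        direction /= np.linalg.norm(direction)
        scales = np.logspace(-4, -1, 7)
        errs = []
        for s in scales:
            pred = base + jac_rec @ (s * direction)
            errs.append(np.linalg.norm(step(x0 + s * direction, u, p) - pred))
        slope = np.polyfit(np.log(scales), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)


class TestFixedPointFinder:
    def test_recovers_analytic_fixed_line(self):
        p, d = line_attractor_params()
        task = TaskConfig(n_obs=5, steps_per_obs=2, settle_steps=4)
        query = Query(0, 1)
        u = query_input_vector(query, task)
        fps = find_fixed_points(
            p, query, task, seed=0, n_seeds=64, tol=1e-12,
            dedup_radius=1e-4, n_sample_trials=8, jitter=2e-3,
        )
        assert len(fps) >= 3
        # particular solution on the contracting subspace
        x_p = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        for fp in fps:
            resid = fp.x_star - x_p
            off_line = resid - (resid @ d) * d
            assert np.linalg.norm(off_line) < 1e-3
            assert fp.speed < 1e-12

    def test_speeds_below_tolerance(self):
        p = small_params(scale=0.3)
        task = TaskConfig(n_obs=5, steps_per_obs=2, settle_steps=4)
        fps = find_fixed_points(
            p, Query(0, 1), task, seed=1, n_seeds=32, n_sample_trials=8
        )
        # contracting random network: a single stable fixed point
        assert len(fps) >= 1
        assert all(fp.speed < 1e-10 for fp in fps)


class TestSlowModePrediction:
    def test_zero_input_zero_displacement(self):
        p, d = line_attractor_params()
        task = TaskConfig()
        u = query_input_vector(Query(0, 1), task)
        x = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        fp = _make_fixed_point(x, Query(0, 1), u, p)
        disp, scalar = slow_mode_prediction(fp, np.zeros(9))
        assert scalar == 0.0
        np.testing.assert_allclose(disp, 0.0)

    def test_orthogonal_input_null(self):
        p, d = line_attractor_params()
        task = TaskConfig()
        u = query_input_vector(Query(0, 1), task)
        x = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        fp = _make_fixed_point(x, Query(0, 1), u, p)
        # build w_hat with J_inp w_hat orthogonal to l via least squares
        null = np.linalg.svd(fp.top_left @ fp.jac_inp[None].squeeze()[None])[2][1:]
        w_hat = null[0]
        _, scalar = slow_mode_prediction(fp, w_hat)
        assert abs(scalar) < 1e-10

    def test_matches_nonlinear_relaxation_for_small_pulses(self):
        """Relaxed displacement projected on r matches l^T J_inp w, with error
        shrinking quadratically in pulse amplitude."""
        from causalrnn.model import simulate

        p, d = line_attractor_params()
        task = TaskConfig()
        query = Query(0, 1)
        u_q = query_input_vector(query, task)
        x_star = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u_q, rcond=None)[0]
        # observation drive with a nonzero projection on the leading mode
        p.B[:, 0] = 0.5 * d + 0.5 * np.linalg.svd(p.W)[0][:, -1]
        fp = _make_fixed_point(x_star, query, u_q, p)
        amps = np.array([1.0, 0.3, 0.1])
        errs = []
        for amp in amps:
            w_hat = np.zeros(9)
            w_hat[0] = amp
            pred, scalar = slow_mode_prediction(fp, w_hat)
            pulse = np.vstack([(u_q + w_hat)[None], np.tile(u_q, (400, 1))])
            traj = simulate(p, pulse, x0=x_star)
            actual = (traj.states[-1] - x_star) @ fp.top_right / (
                fp.top_right @ fp.top_right
            )
            errs.append(abs(actual - scalar) / abs(scalar))
        assert errs[0] < 0.2          # within 20% already at unit amplitude
        assert errs[0] > errs[1] > errs[2]
        slope = np.polyfit(np.log(amps[:2]), np.log(errs[:2]), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.5)


class TestLineAttractor:
    def _fps_from_points(self, locs, params, query, u):
        return [_make_fixed_point(x, query, u, params) for x in locs]

    def test_collinear_points_axis(self):
        p, d = line_attractor_params()
        task = TaskConfig()
        query = Query(0, 1)
        u = query_input_vector(query, task)
        x_p = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        locs = [x_p + t * d * 1e-3 for t in (-1, -0.5, 0, 0.5, 1)]
        attr = build_line_attractor(self._fps_from_points(locs, p, query, u), p)
        cosine = abs(attr.axis @ d)
        assert cosine > 1 - 1e-8
        # sorted by projection, monotone readout along the axis (C = d here)
        proj = attr.projections()
        assert np.all(np.diff(proj) > 0)

    def test_axis_sign_flips_with_negated_readout(self):
        p, d = line_attractor_params()
        task = TaskConfig()
        query = Query(0, 1)
        u = query_input_vector(query, task)
        x_p = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        locs = [x_p + t * d * 1e-3 for t in (-1, 0, 1)]
        attr = build_line_attractor(self._fps_from_points(locs, p, query, u), p)
        p_neg = RnnParams(W=p.W, B=p.B, C=-p.C, tau=p.tau, dt=p.dt)
        attr2 = build_line_attractor(self._fps_from_points(locs, p_neg, query, u), p_neg)
        np.testing.assert_allclose(attr.axis, -attr2.axis, atol=1e-12)

    def test_refuses_fewer_than_three_points(self):
        p, d = line_attractor_params()
        u = query_input_vector(Query(0, 1), TaskConfig())
        x_p = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        pts = self._fps_from_points([x_p, x_p + 1e-3 * d], p, Query(0, 1), u)
        with pytest.raises(ValueError):
            build_line_attractor(pts, p)

    def test_interior_points_middle_fraction(self):
        p, d = line_attractor_params()
        u = query_input_vector(Query(0, 1), TaskConfig())
        x_p = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        locs = [x_p + t * d * 1e-3 for t in np.linspace(-1, 1, 10)]
        attr = build_line_attractor(self._fps_from_points(locs, p, Query(0, 1), u), p)
        inner = interior_points(attr, fraction=0.6)
        assert 4 <= len(inner) <= 7
        proj = attr.projections()
        lo, hi = np.quantile(proj, [0.2, 0.8])
        for fp in inner:
            z = (fp.x_star - attr.centroid) @ attr.axis
            assert lo <= z <= hi


class TestPcaProjection:
    def test_two_dimensional_data_fully_explained(self, rng):
        basis = rng.standard_normal((2, 10))
        trajs = [rng.standard_normal((30, 2)) @ basis for _ in range(4)]
        projs, var_frac, comps = pca_projection(trajs, n_components=2)
        assert var_frac.sum() == pytest.approx(1.0)
        assert all(p.shape == (30, 2) for p in projs)

    def test_variance_fractions_nonincreasing(self, rng):
        trajs = [rng.standard_normal((50, 6)) for _ in range(3)]
        _, var_frac, _ = pca_projection(trajs, n_components=4)
        assert np.all(np.diff(var_frac) <= 1e-12)
        assert var_frac.sum() <= 1.0 + 1e-12

    def test_reconstruction_pythagorean_identity(self, rng):
        trajs = [rng.standard_normal((40, 5)) for _ in range(2)]
        pooled = np.vstack(trajs)
        projs, var_frac, comps = pca_projection(trajs, n_components=2)
        centered = pooled - pooled.mean(axis=0)
        total = (centered**2).sum()
        recon = np.vstack(projs) @ comps
        residual = ((centered - recon) ** 2).sum()
        assert residual / total == pytest.approx(1 - var_frac.sum(), abs=1e-10)


class TestDecisionAxis:
    def test_label_shuffle_nulls_axis(self, random_params, small_task):
        real = decision_axis(random_params, small_task, 800, seed=2)
        null = decision_axis(random_params, small_task, 800, seed=2,
                             shuffle_labels=True)
        assert null.difference_norm < real.difference_norm + 0.5
        assert np.linalg.norm(null.axis) == pytest.approx(1.0)

    def test_input_effect_map_zero_pattern(self, small_task):
        p, d = line_attractor_params()
        query = Query(0, 1)
        u = query_input_vector(query, small_task)
        x_p = np.linalg.lstsq(np.eye(12) - p.W, p.B @ u, rcond=None)[0]
        fps = [_make_fixed_point(x_p + t * d * 1e-3, query, u, p) for t in (-1, 0, 1)]
        attr = build_line_attractor(fps, p)
        res = input_effect_map(attr, p, small_task, relax_steps=50)
        zero_idx = res["patterns"].index((0, 0, 0))
        np.testing.assert_allclose(res["relaxed"][:, zero_idx], 0.0, atol=1e-6)
        assert res["instant"].shape == (3, 8)

    def test_observation_patterns_complete(self):
        pats = observation_patterns(3)
        assert len(pats) == 8 and len(set(pats)) == 8
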