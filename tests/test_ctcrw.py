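"""CTCRW state-space model: transition, likelihood, fit, smoother.

Oracles: an Euler-Maruyama SDE simulation for the transition covariance, a
directly assembled joint-Gaussian density for the Kalman likelihood, and
parameter recovery from the synthetic generator.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from coopgis.ctcrw import (
    CTCRWParams,
    fit_ctcrw,
    impute_track,
    kalman_loglik,
    transition,
)
from coopgis.io import SensorFix
from coopgis.room import RoomGeometry
from coopgis.synthetic import SimulationSpec, simulate_sensor_log, simulate_track


def em_step_covariance(beta, sigma, delta, n_rep=100_000, dt=1e-3, seed=0):
    """Euler-Maruyama oracle: empirical cov of (x, v) after time delta.

    dv = -beta v dt + sigma dW, x' = v, starting from (0, 0).
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(delta / dt))
    x = np.zeros(n_rep)
    v = np.zeros(n_rep)
    sq = sigma * math.sqrt(dt)
    for _ in range(n_steps):
        x += v * dt
        v += -beta * v * dt + sq * rng.standard_normal(n_rep)
    return np.cov(np.vstack([x, v]))


def joint_gaussian_loglik(fixes, params):
    """Assemble the exact joint Gaussian of the observed positions directly.

    Per axis: z_0 ~ N(mu0, P0), z_k = Phi_k z_{k-1} + w_k, y_k = H z_k + e_k.
    The log density of the stacked observations is evaluated with scipy.
    """
    n = len(fixes)
    ts = [f.t for f in fixes]
    p0 = np.diag([params.tau**2 + 0.25, params.stationary_velocity_var])
    h = np.array([1.0, 0.0])
    ll = 0.0
    for axis in (0, 1):
        mu0 = np.array([fixes[0].x if axis == 0 else fixes[0].y, 0.0])
        # propagate means/covs of states and cross-covariances
        means = [mu0]
        covs = {(0, 0): p0}
        phis = [np.eye(2)]
        for k in range(1, n):
            phi, q = transition(params, ts[k] - ts[k - 1])
            phis.append(phi)
            means.append(phi @ means[-1])
            covs[(k, k)] = phi @ covs[(k - 1, k - 1)] @ phi.T + q
        for i in range(n):
            for j in range(i + 1, n):
                prod = np.eye(2)
                for k in range(i + 1, j + 1):
                    prod = phis[k] @ prod
                covs[(i, j)] = covs[(i, i)] @ prod.T
        big = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                c = covs[(i, j)] if i <= j else covs[(j, i)].T
                big[i, j] = h @ c @ h
        big += params.tau**2 * np.eye(n)
        mean_vec = np.array([h @ m for m in means])
        y = np.array([f.x if axis == 0 else f.y for f in fixes])
        ll += multivariate_normal.logpdf(y, mean=mean_vec, cov=big)
    return ll


class TestTransition:
    def test_zero_dt_is_identity(self):
        phi, q = transition(CTCRWParams(0.3, 0.2, 0.1), 0.0)
        assert np.allclose(phi, np.eye(2))
        assert np.allclose(q, 0.0)

    def test_large_beta_dt_asymptotics(self):
        p = CTCRWParams(2.0, 0.2, 0.1)
        phi, _ = transition(p, 1e4)
        assert phi[0, 1] == pytest.approx(1.0 / p.beta, rel=1e-12)
        assert phi[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            transition(CTCRWParams(1.0, 1.0, 0.0), -1.0)

    def test_q_matches_euler_maruyama_oracle(self):
        beta, sigma, delta = 0.2, 0.1, 8.0
        _, q = transition(CTCRWParams(beta, sigma, 0.0), delta)
        emp = em_step_covariance(beta, sigma, delta, n_rep=100_000, seed=7)
        n = 100_000
        # Monte-Carlo error: ~sqrt(2/n) relative for variances,
        # sqrt((Qxx Qvv + Qxv^2)/n) absolute for the covariance
        assert abs(emp[0, 0] - q[0, 0]) < 5 * q[0, 0] * math.sqrt(2.0 / n)
        assert abs(emp[1, 1] - q[1, 1]) < 5 * q[1, 1] * math.sqrt(2.0 / n)
        se_xv = math.sqrt((q[0, 0] * q[1, 1] + q[0, 1] ** 2) / n)
        assert abs(emp[0, 1] - q[0, 1]) < 5 * se_xv

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        beta=st.floats(1e-3, 10.0),
        sigma=st.floats(0.0, 5.0),
        dt=st.floats(0.0, 1000.0),
    )
    def test_q_positive_semidefinite(self, beta, sigma, dt):
        _, q = transition(CTCRWParams(beta, sigma, 0.0), dt)
        evals = np.linalg.eigvalsh(q)
        assert evals.min() >= -1e-9 * max(1.0, evals.max())


class TestLoglik:
    def test_three_fix_loglik_matches_joint_gaussian(self):
        params = CTCRWParams(0.3, 0.15, 0.2)
        fixes = [
            SensorFix("A", 0.0, 1.0, 2.0),
            SensorFix("A", 8.0, 1.4, 2.1),
            SensorFix("A", 24.0, 1.1, 2.6),
        ]
        ll, _ = kalman_loglik(fixes, params)
        assert ll == pytest.approx(joint_gaussian_loglik(fixes, params), abs=1e-8)

    def test_filter_matches_joint_gaussian_to_n10(self, rng):
        params = CTCRWParams(0.4, 0.25, 0.15)
        ts = np.cumsum(rng.uniform(2, 20, size=10))
        fixes = [
            SensorFix("A", float(t), float(rng.normal(3, 1)), float(rng.normal(2, 1)))
            for t in ts
        ]
        ll, _ = kalman_loglik(fixes, params)
        assert ll == pytest.approx(joint_gaussian_loglik(fixes, params), abs=1e-8)

    def test_duplicate_times_rejected(self):
        fixes = [SensorFix("A", 0, 1, 1), SensorFix("A", 0, 2, 2)]
        with pytest.raises(ValueError, match="increasing"):
            kalman_loglik(fixes, CTCRWParams(1.0, 1.0, 0.1))

    def test_translation_invariance(self):
        params = CTCRWParams(0.3, 0.15, 0.2)
        fixes = [
            SensorFix("A", 0.0, 1.0, 2.0),
            SensorFix("A", 8.0, 1.4, 2.1),
            SensorFix("A", 16.0, 1.1, 2.6),
        ]
        shifted = [SensorFix(f.animal_id, f.t, f.x + 1, f.y + 1) for f in fixes]
        ll1, _ = kalman_loglik(fixes, params)
        ll2, _ = kalman_loglik(shifted, params)
        assert ll1 == pytest.approx(ll2, abs=1e-10)


@pytest.fixture(scope="module")
def recovery_fit():
    """Fit on an interior-dominated synthetic track with known parameters."""
    true = CTCRWParams(beta=0.2, sigma=0.05, tau=0.25)
    arena = RoomGeometry(1000.0, 1000.0)  # no wall reflections
    spec = SimulationSpec(ctcrw_params=true, duration=6250 * 8.0, seed=11,
                          dropout_prob=0.2)
    track = simulate_track(spec, arena)
    fixes = simulate_sensor_log(track, dropout_prob=0.2, tau=true.tau, seed=12)
    return true, fixes, fit_ctcrw(fixes)


class TestFit:
    def test_parameter_recovery_within_15_percent(self, recovery_fit):
        true, fixes, fit = recovery_fit
        assert len(fixes) >= 4500
        assert abs(fit.params.beta - true.beta) / true.beta < 0.15
        assert abs(fit.params.sigma - true.sigma) / true.sigma < 0.15
        assert abs(fit.params.tau - true.tau) / true.tau < 0.15

    def test_refit_is_fixed_point(self, recovery_fit):
        _, fixes, fit = recovery_fit
        refit = fit_ctcrw(fixes[:500], init=fit.params)
        base = fit_ctcrw(fixes[:500], init=refit.params)
        assert abs(base.report.loglik - refit.report.loglik) < 1e-6 * max(
            1.0, abs(refit.report.loglik)
        )

    def test_tau_zero_init_converges_with_floor(self, recovery_fit):
        true, fixes, _ = recovery_fit
        fit = fit_ctcrw(fixes[:800], init=CTCRWParams(0.1, 0.1, 0.0))
        assert fit.params.tau >= 1e-4
        assert np.isfinite(fit.report.loglik)

    def test_few_fixes_warns(self):
        fixes = [SensorFix("A", 8.0 * i, 0.1 * i, 0.0) for i in range(5)]
        with pytest.warns(UserWarning, match="20 fixes"):
            fit_ctcrw(fixes, init=CTCRWParams(0.2, 0.2, 0.1))


class TestImpute:
    def _fixes(self, rng, n=40, gap_at=None, gap_len=0.0, tau=0.25):
        params = CTCRWParams(0.2, 0.2, tau)
        ts = []
        t = 0.0
        for i in range(n):
            ts.append(t)
            t += 8.0
            if gap_at is not None and i == gap_at:
                t += gap_len
        xs = np.cumsum(rng.normal(0, 0.3, n)) + 3.0
        ys = np.cumsum(rng.normal(0, 0.3, n)) + 2.0
        return [SensorFix("A", ts[i], xs[i], ys[i]) for i in range(n)], params

    def test_grid_count_formula(self, rng):
        fixes, params = self._fixes(rng, n=10)
        states = impute_track(fixes, params, grid_interval=8.0)
        assert len(states) == 10  # (72 s span) / 8 + 1
        span = 48 * 3600.0
        assert int(span / 8.0) + 1 == 21601  # the 48-h bookkeeping

    def test_noiseless_smoother_interpolates_fixes(self, rng):
        fixes, _ = self._fixes(rng, n=20, tau=0.0)
        params = CTCRWParams(0.2, 0.2, 0.0)
        states = impute_track(fixes, params, grid_interval=8.0)
        by_t = {s.t: s for s in states}
        for f in fixes:
            s = by_t[f.t]
            assert s.mean[0] == pytest.approx(f.x, abs=1e-8)
            assert s.mean[2] == pytest.approx(f.y, abs=1e-8)

    def test_gap_variance_peaks_at_gap_center(self, rng):
        fixes, params = self._fixes(rng, n=40, gap_at=19, gap_len=1800.0)
        states = impute_track(fixes, params, grid_interval=8.0)
        gap_start = fixes[19].t
        gap_end = fixes[20].t
        center = (gap_start + gap_end) / 2
        in_gap = [s for s in states if gap_start < s.t < gap_end]
        v_center = min(in_gap, key=lambda s: abs(s.t - center)).cov[0, 0]
        v_edge = min(in_gap, key=lambda s: abs(s.t - gap_start - 16)).cov[0, 0]
        assert v_center > v_edge

    def test_smoothed_variance_not_above_filtered(self, rng):
        fixes, params = self._fixes(rng, n=30)
        _, filtered = kalman_loglik(fixes, params)
        states = impute_track(fixes, params, grid_interval=8.0)
        sm_by_t = {s.t: s for s in states}
        for f_state in filtered:
            if f_state.t in sm_by_t:
                assert (
                    sm_by_t[f_state.t].cov[0, 0] <= f_state.cov[0, 0] + 1e-10
                )

    def test_means_clipped_to_room(self, rng, bare_room):
        fixes, params = self._fixes(rng, n=30)
        states = impute_track(fixes, params, grid_interval=8.0, room=bare_room)
        for s in states:
            assert 0 <= s.mean[0] <= bare_room.width
            assert 0 <= s.mean[2] <= bare_room.depth

    def test_invalid_grid_interval(self, rng):
        fixes, params = self._fixes(rng, n=5)
        with pytest.raises(ValueError):
            impute_track(fixes, params, grid_interval=0.0)
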