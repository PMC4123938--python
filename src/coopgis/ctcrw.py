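"""Continuous-time correlated random walk (CTCRW) fitting and imputation.

Movement model
--------------
Velocity follows an Ornstein-Uhlenbeck process with mean-reversion rate
``beta`` (1/s) and white-noise intensity ``sigma`` (m s^-3/2); position is
the time integral of velocity.  Per axis the state is (position, velocity)
and the exact discretization over a step of length dt is Gaussian with

    Phi = [[1, (1 - e^{-b dt}) / b],
           [0, e^{-b dt}]]

    Q_vv = s^2 (1 - e^{-2 b dt}) / (2 b)
    Q_xv = (s^2 / b^2) [(1 - e^{-b dt}) - (1 - e^{-2 b dt}) / 2]
    Q_xx = (s^2 / b^2) [dt - 2 (1 - e^{-b dt}) / b + (1 - e^{-2 b dt}) / (2 b)]

Observed fixes are the true position plus independent N(0, tau^2) noise per
axis.  The x and y axes are independent and share (beta, sigma, tau), so the
exact likelihood of an irregularly sampled, gappy track is the product of
two univariate-state Kalman filters; gaps enter only through dt.  Fitting
maximizes this likelihood over (log beta, log sigma, log tau) with a
derivative-free simplex and a small multi-start.  Imputation evaluates the
fixed-interval (RTS) smoother on a regular time grid; the room is finite
but the movement model is fit unbounded, and smoothed means are clipped to
the room rectangle afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .io import SensorFix
from .room import RoomGeometry

TAU_FLOOR = 1e-4  # m; keeps the observation variance positive during fitting
#: Physical box for the fitted parameters (log scale).  beta above ~2/s is
#: indistinguishable from white-noise velocity at 8-s sampling and lies on a
#: degenerate likelihood ridge (beta, sigma -> inf); the penalty keeps the
#: simplex off it.
FIT_BOUNDS = {
    "beta": (1e-4, 2.0),
    "sigma": (1e-5, 10.0),
    "tau": (TAU_FLOOR, 5.0),
}


@dataclass(frozen=True)
class CTCRWParams:
    """CTCRW movement/observation model parameters.

    beta   : velocity autocorrelation decay rate, 1/s  (> 0)
    sigma  : velocity white-noise intensity, m s^-3/2  (>= 0)
    tau    : measurement SD per axis, m                (>= 0)
    mu0    : optional initial state mean per axis ((x, vx), (y, vy));
             defaults to the first fix with zero velocity
    p0     : initial state covariance per axis (2x2), shared by both axes;
             defaults to diag(tau^2 + 0.25, sigma^2 / (2 beta))
    """

    beta: float
    sigma: float
    tau: float
    mu0: tuple[tuple[float, float], tuple[float, float]] | None = None
    p0: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("sigma and tau must be >= 0")
        if self.p0 is not None:
            p = np.asarray(self.p0, float)
            if p.shape != (2, 2) or abs(p[0, 1] - p[1, 0]) > 1e-12:
                raise ValueError("p0 must be a symmetric 2x2 matrix")
            if np.linalg.eigvalsh(p).min() < -1e-12:
                raise ValueError("p0 must be positive semi-definite")

    @property
    def stationary_velocity_var(self) -> float:
        """sigma^2 / (2 beta): variance of the OU velocity at stationarity."""
        return self.sigma**2 / (2.0 * self.beta)


@dataclass(frozen=True)
class StateEstimate:
    """Gaussian state estimate at one time: mean (x, vx, y, vy), 4x4 cov."""

    t: float
    mean: np.ndarray
    cov: np.ndarray


@dataclass
class FitReport:
    converged: bool
    loglik: float
    n_iter: int
    n_starts: int
    message: str = ""


@dataclass
class CTCRWFit:
    params: CTCRWParams
    report: FitReport


def transition(params: CTCRWParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-axis discretization: state matrix Phi and process cov Q."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    b, s = params.beta, params.sigma
    e1 = math.exp(-b * dt)
    e2 = math.exp(-2.0 * b * dt)
    phi = np.array([[1.0, (1.0 - e1) / b], [0.0, e1]])
    s2 = s * s
    q_vv = s2 * (1.0 - e2) / (2.0 * b)
    q_xv = (s2 / (b * b)) * ((1.0 - e1) - (1.0 - e2) / 2.0)
    q_xx = (s2 / (b * b)) * (dt - 2.0 * (1.0 - e1) / b + (1.0 - e2) / (2.0 * b))
    q = np.array([[q_xx, q_xv], [q_xv, q_vv]])
    return phi, q


def _initial_conditions(
    fixes: Sequence[SensorFix], params: CTCRWParams
) -> tuple[tuple[float, float], tuple[float, float], np.ndarray]:
    if params.mu0 is not None:
        mx, my = params.mu0
    else:
        mx, my = (fixes[0].x, 0.0), (fixes[0].y, 0.0)
    if params.p0 is not None:
        p0 = np.asarray(params.p0, float)
    else:
        p0 = np.diag([params.tau**2 + 0.25, params.stationary_velocity_var])
    return mx, my, p0


def _scalar_filter_pass(
    ts: np.ndarray,
    obs: np.ndarray,  # shape (n, 2): x and y observations
    params: CTCRWParams,
    mu_x: tuple[float, float],
    mu_y: tuple[float, float],
    p0: np.ndarray,
) -> float:
    """Fast shared-axis Kalman filter returning only the total log-likelihood.

    Scalar arithmetic on the 2x2 per-axis system; both axes share Phi/Q/R so
    the covariance recursion is run once.
    """
    b, s, tau = params.beta, params.sigma, params.tau
    r = tau * tau
    s2 = s * s
    bb = b * b
    # covariance (shared) and means per axis
    p00, p01, p11 = float(p0[0, 0]), float(p0[0, 1]), float(p0[1, 1])
    x0, v0 = mu_x
    y0, w0 = mu_y
    ll = 0.0
    log2pi = math.log(2.0 * math.pi)
    cache: dict[float, tuple[float, float, float, float, float]] = {}
    prev_t = None
    for i in range(len(ts)):
        t = ts[i]
        if prev_t is not None:
            dt = t - prev_t
            ent = cache.get(dt)
            if ent is None:
                e1 = math.exp(-b * dt)
                f01 = (1.0 - e1) / b  # Phi[0,1]
                e2 = e1 * e1
                q_vv = s2 * (1.0 - e2) / (2.0 * b)
                q_xv = (s2 / bb) * ((1.0 - e1) - (1.0 - e2) / 2.0)
                q_xx = (s2 / bb) * (dt - 2.0 * (1.0 - e1) / b + (1.0 - e2) / (2.0 * b))
                ent = (e1, f01, q_xx, q_xv, q_vv)
                cache[dt] = ent
            e1, f01, q_xx, q_xv, q_vv = ent
            # mean predict
            x0, v0 = x0 + f01 * v0, e1 * v0
            y0, w0 = y0 + f01 * w0, e1 * w0
            # cov predict: P = Phi P Phi' + Q
            a00 = p00 + f01 * p01
            a01 = p01 + f01 * p11
            p00 = a00 + f01 * a01 + q_xx
            p01 = e1 * a01 + q_xv
            p11 = e1 * e1 * p11 + q_vv
        prev_t = t
        # update with position observation, H = [1, 0]
        svar = p00 + r
        if not svar > 0 or not math.isfinite(svar):
            raise FilterError(f"singular innovation covariance at fix index {i}")
        inn_x = obs[i, 0] - x0
        inn_y = obs[i, 1] - y0
        ll += -0.5 * (
            2.0 * (log2pi + math.log(svar)) + (inn_x * inn_x + inn_y * inn_y) / svar
        )
        k0 = p00 / svar
        k1 = p01 / svar
        x0 += k0 * inn_x
        v0 += k1 * inn_x
        y0 += k0 * inn_y
        w0 += k1 * inn_y
        p11 = p11 - k1 * p01
        p01 = p01 - k0 * p01
        p00 = p00 - k0 * p00
    return ll


class FilterError(RuntimeError):
    """Numerical failure inside the Kalman recursion."""


def _validate_fixes(fixes: Sequence[SensorFix]) -> tuple[np.ndarray, np.ndarray]:
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes")
    ts = np.array([f.t for f in fixes], float)
    if np.any(np.diff(ts) <= 0):
        i = int(np.argmax(np.diff(ts) <= 0))
        raise ValueError(f"fix times must be strictly increasing (index {i + 1})")
    obs = np.array([[f.x, f.y] for f in fixes], float)
    return ts, obs


def kalman_loglik(
    fixes: Sequence[SensorFix], params: CTCRWParams
) -> tuple[float, list[StateEstimate]]:
    """Exact log-likelihood of the fixes plus filtered state estimates.

    The log-likelihood is the sum of the log predictive densities of each
    observed (x, y) under the Gaussian state-space model, axes independent.
    """
    ts, obs = _validate_fixes(fixes)
    mu_x, mu_y, p0 = _initial_conditions(fixes, params)
    ll = _scalar_filter_pass(ts, obs, params, mu_x, mu_y, p0)
    states = _filter_states(ts, obs, params, mu_x, mu_y, p0)[0]
    return ll, states


def _filter_states(
    ts: np.ndarray,
    obs: np.ndarray,
    params: CTCRWParams,
    mu_x: tuple[float, float],
    mu_y: tuple[float, float],
    p0: np.ndarray,
    observed: np.ndarray | None = None,
):
    """Full filter pass keeping per-step quantities for smoothing.

    ``observed`` marks which times carry an observation (all, by default).
    Returns (filtered StateEstimates, predicted means, predicted covs,
    filtered means, filtered covs, phis) with per-axis 2-vectors stacked as
    (x, vx, y, vy) and the shared 2x2 covariance per axis.
    """
    n = len(ts)
    if observed is None:
        observed = np.ones(n, bool)
    r = params.tau**2
    m = np.array([mu_x[0], mu_x[1], mu_y[0], mu_y[1]], float)
    p = p0.copy()
    pred_m = np.empty((n, 4))
    pred_p = np.empty((n, 2, 2))
    filt_m = np.empty((n, 4))
    filt_p = np.empty((n, 2, 2))
    phis = np.empty((n, 2, 2))
    states: list[StateEstimate] = []
    h = np.array([1.0, 0.0])
    prev_t = None
    for i in range(n):
        if prev_t is not None:
            phi, q = transition(params, float(ts[i] - prev_t))
            m = np.concatenate([phi @ m[:2], phi @ m[2:]])
            p = phi @ p @ phi.T + q
            phis[i] = phi
        else:
            phis[i] = np.eye(2)
        prev_t = ts[i]
        pred_m[i] = m
        pred_p[i] = p
        if observed[i]:
            svar = p[0, 0] + r
            if not svar > 0 or not np.isfinite(svar):
                raise FilterError(f"singular innovation covariance at fix index {i}")
            k = p @ h / svar
            inn = np.array([obs[i, 0] - m[0], obs[i, 1] - m[2]])
            m = m + np.concatenate([k * inn[0], k * inn[1]])
            p = p - np.outer(k, h @ p)
            p = (p + p.T) / 2.0
        filt_m[i] = m
        filt_p[i] = p
        states.append(StateEstimate(float(ts[i]), _stack_mean(m), _stack_cov(p)))
    return states, pred_m, pred_p, filt_m, filt_p, phis


def _stack_mean(m: np.ndarray) -> np.ndarray:
    return m.copy()


def _stack_cov(p2: np.ndarray) -> np.ndarray:
    """Expand the shared per-axis 2x2 covariance to the 4x4 (x,vx,y,vy) cov."""
    c = np.zeros((4, 4))
    c[:2, :2] = p2
    c[2:, 2:] = p2
    return c


def fit_ctcrw(
    fixes: Sequence[SensorFix],
    init: CTCRWParams | None = None,
    max_iter: int = 400,
) -> CTCRWFit:
    """Maximum-likelihood fit of (beta, sigma, tau) by Nelder-Mead simplex.

    Optimizes in (log beta, log sigma, log tau) from three starts (the
    initial guess and the same with sigma scaled x10 and /10); the best
    final log-likelihood wins, ties broken by the lower beta.  A floor of
    ``TAU_FLOOR`` keeps the measurement variance positive.
    """
    ts, obs = _validate_fixes(fixes)
    if len(fixes) < 20:
        import warnings

        warnings.warn("fewer than 20 fixes; CTCRW fit may be unstable", stacklevel=2)
    if init is None:
        init = _heuristic_init(ts, obs)
    mu_x = (fixes[0].x, 0.0)
    mu_y = (fixes[0].y, 0.0)

    lo = np.log([FIT_BOUNDS[k][0] for k in ("beta", "sigma", "tau")])
    hi = np.log([FIT_BOUNDS[k][1] for k in ("beta", "sigma", "tau")])

    def nll(theta: np.ndarray) -> float:
        # smooth quadratic penalty outside the physical box
        penalty = 1e4 * float(
            np.sum(np.maximum(theta - hi, 0.0) ** 2)
            + np.sum(np.maximum(lo - theta, 0.0) ** 2)
        )
        clipped = np.clip(theta, lo, hi)
        b, s, tau = np.exp(clipped)
        pars = CTCRWParams(b, s, tau)
        p0 = np.diag([tau**2 + 0.25, pars.stationary_velocity_var])
        try:
            return penalty - _scalar_filter_pass(ts, obs, pars, mu_x, mu_y, p0)
        except (FilterError, OverflowError):
            return 1e12

    starts = [
        (init.beta, init.sigma, max(init.tau, TAU_FLOOR)),
        (init.beta, init.sigma * 10.0, max(init.tau, TAU_FLOOR)),
        (init.beta, init.sigma / 10.0, max(init.tau, TAU_FLOOR)),
    ]
    best = None
    total_iter = 0
    any_converged = False
    for b0, s0, t0 in starts:
        res = minimize(
            nll,
            np.log([b0, s0, t0]),
            method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-8},
        )
        total_iter += res.nit
        any_converged = any_converged or bool(res.success)
        cand = (res.fun, np.exp(res.x))
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1][0] < best[1][0]
        ):
            best = cand
    nll_best, theta_best = best
    b, s, tau = np.exp(np.clip(np.log(theta_best), lo, hi))
    params = CTCRWParams(float(b), float(s), float(max(tau, TAU_FLOOR)))
    report = FitReport(
        converged=any_converged,
        loglik=-float(nll_best),
        n_iter=total_iter,
        n_starts=len(starts),
        message="" if any_converged else "simplex did not converge; best point kept",
    )
    return CTCRWFit(params, report)


def _heuristic_init(ts: np.ndarray, obs: np.ndarray) -> CTCRWParams:
    """Moment-style starting point from raw displacement statistics."""
    dt = np.diff(ts)
    v = np.diff(obs, axis=0) / dt[:, None]
    speed_var = float(np.mean(v**2))
    med_dt = float(np.median(dt))
    beta0 = 1.0 / max(2.0 * med_dt, 1e-3)
    sigma0 = math.sqrt(max(2.0 * beta0 * speed_var, 1e-8))
    tau0 = 0.1
    return CTCRWParams(beta0, sigma0, tau0)


def impute_track(
    fixes: Sequence[SensorFix],
    params: CTCRWParams,
    grid_interval: float = 8.0,
    room: RoomGeometry | None = None,
) -> list[StateEstimate]:
    """Kalman-smoothed states on a regular grid spanning the fixes.

    Runs the forward filter over the union of fix times and grid times
    (grid nodes carry no observation), then the Rauch-Tung-Striebel
    backward pass, and returns the smoothed states at the grid times with
    means optionally clipped to the room rectangle.  The grid runs from the
    first to the last fix inclusive, so a 48-h span at 8 s gives 21 601
    states.
    """
    if grid_interval <= 0:
        raise ValueError("grid_interval must be > 0")
    ts, obs = _validate_fixes(fixes)
    t0, t1 = float(ts[0]), float(ts[-1])
    n_steps = int(math.floor((t1 - t0) / grid_interval + 1e-9))
    grid = t0 + grid_interval * np.arange(n_steps + 1)
    # merge fix and grid times; grid node within 1e-9 of a fix time reuses it
    all_t = np.unique(np.concatenate([ts, grid]))
    is_obs = np.isin(all_t, ts)
    obs_full = np.zeros((len(all_t), 2))
    obs_full[is_obs] = obs
    mu_x, mu_y, p0 = _initial_conditions(fixes, params)
    _, pred_m, pred_p, filt_m, filt_p, phis = _filter_states(
        all_t, obs_full, params, mu_x, mu_y, p0, observed=is_obs
    )
    n = len(all_t)
    sm_m = filt_m.copy()
    sm_p = filt_p.copy()
    for i in range(n - 2, -1, -1):
        phi = phis[i + 1]
        pp = pred_p[i + 1]
        # smoother gain J = P_f Phi' Pp^{-1}
        j = filt_p[i] @ phi.T @ np.linalg.pinv(pp)
        dx = sm_m[i + 1][:2] - pred_m[i + 1][:2]
        dy = sm_m[i + 1][2:] - pred_m[i + 1][2:]
        sm_m[i][:2] = filt_m[i][:2] + j @ dx
        sm_m[i][2:] = filt_m[i][2:] + j @ dy
        sp = filt_p[i] + j @ (sm_p[i + 1] - pp) @ j.T
        sm_p[i] = (sp + sp.T) / 2.0
    keep = np.isin(all_t, grid)
    out: list[StateEstimate] = []
    for i in np.nonzero(keep)[0]:
        m = sm_m[i].copy()
        if room is not None:
            m[0], m[2] = room.clip_point(m[0], m[2])
        out.append(StateEstimate(float(all_t[i]), m, _stack_cov(sm_p[i])))
    return out


def states_to_frame(states: Sequence[StateEstimate], animal_id: str):
    """Tabulate smoothed states as a DataFrame (animal_id,t,x,y,var_x,var_y)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "t": [s.t for s in states],
            "x": [s.mean[0] for s in states],
            "y": [s.mean[2] for s in states],
            "var_x": [s.cov[0, 0] for s in states],
            "var_y": [s.cov[2, 2] for s in states],
        }
    )
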