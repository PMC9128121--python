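"""Filtering of Argos fixes, CTCRW fitting, and multiple path imputation.

The raw data are irregular, noisy satellite fixes.  Three deterministic
filtering rules are applied per animal: a post-capture gap (movements shortly
after handling are discarded), a seasonal window, and one fix per duty cycle
(the one with the smallest error ellipse); animals left with too few fixes
are excluded.  A continuous-time correlated random walk (CTCRW) — an
integrated Ornstein-Uhlenbeck velocity process observed through the Argos
error ellipses — is then fit per animal by maximum likelihood with a Kalman
filter, and multiple realizations of the path at a regular 4-day grid are
drawn from the joint smoothing distribution (conditional simulation).  Each
downstream analysis runs once per imputed dataset and posteriors are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .covariates import CovariateStack
from .distributions import wrap_angle
from .synthetic import ArgosObservation, TruePath, ellipse_covariance

POS_PRIOR_VAR = 1.0e10  # m^2; weak prior on the initial position (SD 100 km)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Deterministic fix-retention rules applied before any model fitting."""

    post_capture_gap: float = 5.0  # days
    season_start: tuple[int, int] = (3, 1)  # (month, day), inclusive
    season_end: tuple[int, int] = (6, 30)  # (month, day), inclusive
    min_locations: int = 3

    def __post_init__(self):
        if self.post_capture_gap < 0:
            raise ValueError("post_capture_gap must be >= 0")
        if self.min_locations < 3:
            raise ValueError("min_locations must be >= 3")
        if self.season_start >= self.season_end:
            raise ValueError("season_start must precede season_end")


@dataclass
class FilterResult:
    observations: list[ArgosObservation]
    excluded: bool = False
    reason: str | None = None
    counts: dict = field(default_factory=dict)


def _in_season(ts: np.datetime64, cfg: FilterConfig) -> bool:
    t = ts.astype("datetime64[s]").item()
    md = (t.month, t.day)
    return cfg.season_start <= md <= cfg.season_end


def filter_observations(
    obs: list[ArgosObservation], capture_time, cfg: FilterConfig | None = None
) -> FilterResult:
    """Apply the retention rules; returns the kept fixes or an exclusion.

    Rules, in order: drop fixes earlier than ``post_capture_gap`` days after
    ``capture_time``; drop fixes outside the seasonal window; keep exactly one
    fix per duty cycle, the one minimizing the ellipse area pi*smaj*smin; if
    fewer than ``min_locations`` fixes remain, the animal is excluded with
    reason ``"min_locations"``.
    """
    cfg = cfg or FilterConfig()
    times = [np.datetime64(o.timestamp, "ns") for o in obs]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("observations must be sorted by time")
    counts = {"input": len(obs)}
    cap = np.datetime64(capture_time, "ns")
    gap = np.timedelta64(int(cfg.post_capture_gap * 86400 * 1e9), "ns")
    kept = [o for o, t in zip(obs, times) if t - cap >= gap]
    counts["post_capture"] = len(kept)
    kept = [o for o in kept if _in_season(np.datetime64(o.timestamp, "ns"), cfg)]
    counts["season"] = len(kept)

    have_cycles = all(o.duty_cycle_id is not None for o in kept)
    best: dict = {}
    for o in kept:
        if have_cycles:
            key = o.duty_cycle_id
        else:  # conservative fallback: group by calendar day
            key = np.datetime64(o.timestamp, "D")
        area = o.semi_major * o.semi_minor  # pi cancels in the comparison
        if key not in best or area < best[key][0]:
            best[key] = (area, o)
    kept = sorted((v[1] for v in best.values()), key=lambda o: o.timestamp)
    counts["dedup"] = len(kept)

    if len(kept) < cfg.min_locations:
        return FilterResult([], excluded=True, reason="min_locations", counts=counts)
    return FilterResult(kept, counts=counts)


# ---------------------------------------------------------------------------
# CTCRW state-space model
# ---------------------------------------------------------------------------


@dataclass
class CTCRWFit:
    """Maximum-likelihood CTCRW fit for one animal.

    ``beta`` is the velocity autocorrelation parameter (1/day), ``sigma2``
    the velocity diffusion variance (m^2/day^3 scale); both shared across the
    two coordinate axes.  State per axis is (position, velocity).
    """

    animal_id: str
    class_label: str
    beta: float
    sigma2: float
    loglik: float
    converged: bool
    obs_t: np.ndarray  # (n,) days since epoch
    obs_xy: np.ndarray  # (n, 2)
    obs_R: np.ndarray  # (n, 2, 2)
    epoch: np.datetime64
    smoothed_mean: np.ndarray | None = None  # (n, 4) at observation times
    smoothed_cov: np.ndarray | None = None


def _trans(beta: float, sigma2: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix and process covariance for the integrated OU model."""
    e = np.exp(-beta * dt)
    t1 = np.array([[1.0, (1.0 - e) / beta], [0.0, e]])
    qvv = sigma2 * (1.0 - e * e) / (2.0 * beta)
    qxv = sigma2 * (1.0 - e) ** 2 / (2.0 * beta**2)
    qxx = sigma2 / beta**2 * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e * e) / (2.0 * beta))
    q1 = np.array([[qxx, qxv], [qxv, qvv]])
    T = np.zeros((4, 4))
    T[:2, :2] = t1
    T[2:, 2:] = t1
    Q = np.zeros((4, 4))
    Q[:2, :2] = q1
    Q[2:, 2:] = q1
    return T, Q


H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])


def initial_state(beta: float, sigma2: float, first_xy) -> tuple[np.ndarray, np.ndarray]:
    """Weakly informative initial state centred at the first fix.

    Position variance is large but proper; velocity starts at its stationary
    distribution N(0, sigma2/(2 beta)).
    """
    m0 = np.array([first_xy[0], 0.0, first_xy[1], 0.0])
    vv = sigma2 / (2.0 * beta)
    P0 = np.diag([POS_PRIOR_VAR, vv, POS_PRIOR_VAR, vv])
    return m0, P0


def _kalman(
    t_all: np.ndarray,
    obs_at: np.ndarray,
    y: np.ndarray,
    R: np.ndarray,
    beta: float,
    sigma2: float,
    m0: np.ndarray,
    P0: np.ndarray,
    smooth: bool = False,
):
    """Kalman filter (and optional RTS smoother) over a merged timeline.

    ``obs_at[j]`` is the observation index at time j, or -1 for prediction
    times.  Returns (loglik, smoothed_means, smoothed_covs); the smoothing
    outputs are None unless requested.
    """
    M = t_all.size
    mp = np.empty((M, 4))
    Pp = np.empty((M, 4, 4))
    mf = np.empty((M, 4))
    Pf = np.empty((M, 4, 4))
    Ts = np.empty((M, 4, 4))

    loglik = 0.0
    m, P = m0, P0
    for j in range(M):
        if j > 0:
            dt = float(t_all[j] - t_all[j - 1])
            T, Q = _trans(beta, sigma2, dt)
            m = T @ m
            P = T @ P @ T.T + Q
            Ts[j] = T
        mp[j], Pp[j] = m, P
        i = obs_at[j]
        if i >= 0:
            v = y[i] - H @ m
            S = H @ P @ H.T + R[i]
            Sinv = np.linalg.inv(S)
            sign, logdet = np.linalg.slogdet(S)
            loglik += -0.5 * (2 * np.log(2 * np.pi) + logdet + v @ Sinv @ v)
            K = P @ H.T @ Sinv
            m = m + K @ v
            P = P - K @ H @ P
            P = 0.5 * (P + P.T)
        mf[j], Pf[j] = m, P

    if not smooth:
        return loglik, None, None

    ms = np.empty((M, 4))
    Ps = np.empty((M, 4, 4))
    ms[-1], Ps[-1] = mf[-1], Pf[-1]
    for j in range(M - 2, -1, -1):
        G = Pf[j] @ Ts[j + 1].T @ np.linalg.inv(Pp[j + 1])
        ms[j] = mf[j] + G @ (ms[j + 1] - mp[j + 1])
        Ps[j] = Pf[j] + G @ (Ps[j + 1] - Pp[j + 1]) @ G.T
        Ps[j] = 0.5 * (Ps[j] + Ps[j].T)
    return loglik, ms, Ps


def _obs_arrays(obs: list[ArgosObservation]):
    t0 = np.datetime64(obs[0].timestamp, "ns")
    t = np.array(
        [(np.datetime64(o.timestamp, "ns") - t0) / np.timedelta64(1, "D") for o in obs]
    )
    xy = np.array([[o.x, o.y] for o in obs])
    R = np.array(
        [ellipse_covariance(o.semi_major, o.semi_minor, o.orientation) for o in obs]
    )
    return t0, t, xy, R


def ctcrw_loglik(
    obs_t: np.ndarray, obs_xy: np.ndarray, obs_R: np.ndarray, beta: float, sigma2: float
) -> float:
    """Kalman-filter log-likelihood of the fixes under the CTCRW model."""
    m0, P0 = initial_state(beta, sigma2, obs_xy[0])
    obs_at = np.arange(obs_t.size)
    ll, _, _ = _kalman(obs_t, obs_at, obs_xy, obs_R, beta, sigma2, m0, P0)
    return float(ll)


def fit_ctcrw(obs: list[ArgosObservation]) -> CTCRWFit:
    """Maximum-likelihood CTCRW fit via L-BFGS on (log beta, log sigma)."""
    if len(obs) < 3:
        raise ValueError("need at least 3 observations to fit the CTCRW")
    t0, t, xy, R = _obs_arrays(obs)
    if np.any(np.diff(t) <= 0):
        raise ValueError("observation times must be strictly increasing")

    dt = np.diff(t)
    vel = np.diff(xy, axis=0) / dt[:, None]
    sv = max(float(vel.std()), 1.0)

    def nll(z):
        beta, sig = np.exp(z)
        ll = ctcrw_loglik(t, xy, R, beta, sig * sig)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for beta0 in (1.0, 0.2):
        sig0 = sv * np.sqrt(2.0 * beta0)
        res = minimize(
            nll,
            x0=np.log([beta0, sig0]),
            method="L-BFGS-B",
            bounds=[(-7.0, 5.0), (np.log(1e-3), np.log(1e7))],
        )
        if best is None or res.fun < best.fun:
            best = res
    beta, sig = np.exp(best.x)
    sigma2 = float(sig * sig)
    converged = bool(best.success and np.isfinite(best.fun))

    m0, P0 = initial_state(beta, sigma2, xy[0])
    obs_at = np.arange(t.size)
    ll, ms, Ps = _kalman(t, obs_at, xy, R, beta, sigma2, m0, P0, smooth=True)
    return CTCRWFit(
        animal_id=obs[0].animal_id,
        class_label=obs[0].class_label,
        beta=float(beta),
        sigma2=sigma2,
        loglik=float(ll),
        converged=converged,
        obs_t=t,
        obs_xy=xy,
        obs_R=R,
        epoch=t0,
        smoothed_mean=ms,
        smoothed_cov=Ps,
    )


# ---------------------------------------------------------------------------
# path imputation (conditional simulation at a regular grid)
# ---------------------------------------------------------------------------


@dataclass
class PathRealization:
    """One imputed path at regular spacing; unit of an imputation dataset."""

    animal_id: str
    class_label: str
    dataset_index: int  # 1-based; 0 before assignment into datasets
    times: np.ndarray  # (n,) datetime64[ns]
    xy: np.ndarray  # (n, 2)


def _merged_timeline(fit: CTCRWFit, interval_days: float):
    n_out = int(np.floor((fit.obs_t[-1] - fit.obs_t[0]) / interval_days)) + 1
    t_grid = fit.obs_t[0] + interval_days * np.arange(n_out)
    t_all = np.unique(np.concatenate([fit.obs_t, t_grid]))
    obs_at = np.full(t_all.size, -1, dtype=int)
    obs_at[np.searchsorted(t_all, fit.obs_t)] = np.arange(fit.obs_t.size)
    grid_at = np.searchsorted(t_all, t_grid)
    return t_all, obs_at, t_grid, grid_at


def _simulate_states(
    t_all, beta, sigma2, m0, P0, rng: np.random.Generator
) -> np.ndarray:
    M = t_all.size
    a = np.empty((M, 4))
    a[0] = rng.multivariate_normal(m0, P0)
    for j in range(1, M):
        T, Q = _trans(beta, sigma2, float(t_all[j] - t_all[j - 1]))
        # Q is PSD block-diagonal; tiny jitter guards the Cholesky
        a[j] = rng.multivariate_normal(T @ a[j - 1], Q + 1e-9 * np.eye(4))
    return a


def simulate_paths(
    fit: CTCRWFit,
    m: int = 25,
    interval_days: float = 4.0,
    rng: np.random.Generator | None = None,
) -> list[PathRealization]:
    """Draw m path realizations at a regular grid from the CTCRW posterior.

    Conditional simulation by mean correction: simulate an unconditional
    state path and pseudo-observations, smooth both the real and the
    simulated data, and set draw = smooth(y) + (sim - smooth(y_sim)).  Times
    far from any fix correctly receive larger spread.
    """
    rng = np.random.default_rng() if rng is None else rng
    t_all, obs_at, t_grid, grid_at = _merged_timeline(fit, interval_days)
    m0, P0 = initial_state(fit.beta, fit.sigma2, fit.obs_xy[0])
    _, ms, _ = _kalman(
        t_all, obs_at, fit.obs_xy, fit.obs_R, fit.beta, fit.sigma2, m0, P0, smooth=True
    )
    chol_R = np.linalg.cholesky(fit.obs_R + 1e-12 * np.eye(2))

    out = []
    t0 = fit.epoch
    times = t0 + ((t_grid - fit.obs_t[0]) * 86400 * 1e9).astype("timedelta64[ns]")
    for j in range(m):
        a_sim = _simulate_states(t_all, fit.beta, fit.sigma2, m0, P0, rng)
        y_sim = a_sim[obs_at >= 0][:, [0, 2]] + np.einsum(
            "nij,nj->ni", chol_R, rng.standard_normal((fit.obs_t.size, 2))
        )
        _, ms_sim, _ = _kalman(
            t_all, obs_at, y_sim, fit.obs_R, fit.beta, fit.sigma2, m0, P0, smooth=True
        )
        draw = ms + (a_sim - ms_sim)
        out.append(
            PathRealization(
                animal_id=fit.animal_id,
                class_label=fit.class_label,
                dataset_index=0,
                times=times.astype("datetime64[ns]"),
                xy=draw[grid_at][:, [0, 2]],
            )
        )
    return out


def assemble_datasets(
    realizations: dict[str, list[PathRealization]],
    rng: np.random.Generator | None = None,
) -> list[list[PathRealization]]:
    """Form m datasets, each with one realization per animal, no reuse."""
    rng = np.random.default_rng() if rng is None else rng
    ms = {len(v) for v in realizations.values()}
    if len(ms) != 1:
        raise ValueError("all animals must have the same number of realizations")
    m = ms.pop()
    datasets: list[list[PathRealization]] = [[] for _ in range(m)]
    for aid in sorted(realizations):
        perm = rng.permutation(m)
        for j in range(m):
            r = realizations[aid][perm[j]]
            datasets[j].append(
                PathRealization(
                    animal_id=r.animal_id,
                    class_label=r.class_label,
                    dataset_index=j + 1,
                    times=r.times,
                    xy=r.xy,
                )
            )
    return datasets


# ---------------------------------------------------------------------------
# step geometry
# ---------------------------------------------------------------------------


@dataclass
class StepSeries:
    """Step lengths and per-step bearings for one animal's regular path.

    ``bearings[t]`` is the atan2 direction of step t, wrapped to (-pi, pi];
    turning deviations are differences of consecutive bearings and are formed
    downstream.  ``step_valid`` masks steps excluded by the on-ice filter.
    """

    animal_id: str
    class_label: str
    lengths: np.ndarray
    bearings: np.ndarray
    step_valid: np.ndarray | None = None

    def __post_init__(self):
        self.lengths = np.atleast_1d(np.asarray(self.lengths, dtype=float))
        self.bearings = np.atleast_1d(np.asarray(self.bearings, dtype=float))
        if np.any(self.lengths < 0):
            raise ValueError("step lengths must be >= 0")
        if self.bearings.size and np.any(np.abs(self.bearings) > np.pi + 1e-12):
            raise ValueError("bearings must be wrapped to (-pi, pi]")
        if self.bearings.size > self.lengths.size:
            raise ValueError("cannot have more bearings than steps")
        if self.step_valid is None:
            self.step_valid = np.ones(self.lengths.size, dtype=bool)
        else:
            self.step_valid = np.asarray(self.step_valid, dtype=bool)

    def deviations(self) -> tuple[np.ndarray, np.ndarray]:
        """Turning deviations between consecutive steps and their validity."""
        dev = wrap_angle(np.diff(self.bearings))
        valid = self.step_valid[:-1] & self.step_valid[1:]
        return dev, valid[: dev.size] if dev.size else valid[:0]


def steps_and_angles(
    path: PathRealization | TruePath,
    stack: CovariateStack | None = None,
    on_ice: bool = True,
) -> StepSeries:
    """Step lengths and bearings from a regular path.

    With a covariate stack and ``on_ice=True``, steps with either endpoint on
    a land cell are flagged invalid (the analysis is restricted to sea ice).
    """
    xy = np.asarray(path.xy, dtype=float)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 locations to compute an angle")
    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    bearings = wrap_angle(np.arctan2(d[:, 1], d[:, 0]))
    step_valid = np.ones(lengths.size, dtype=bool)
    if stack is not None and on_ice:
        land = stack.is_land(xy) & stack.grid.in_bounds(xy)
        step_valid = ~(land[:-1] | land[1:])
    return StepSeries(
        animal_id=path.animal_id,
        class_label=path.class_label,
        lengths=lengths,
        bearings=bearings,
        step_valid=step_valid,
    )
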