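"""Correlated velocity models (CVM) for planar cell trajectories.

The velocity of a swimming cell is modelled as a mean-reverting
Ornstein--Uhlenbeck process, written compactly with the planar velocity
encoded as a complex number ``V = vx + i*vy``::

    dV = (i*omega - 1/tau) * (V - mu) dt + noise

Four nested variants are supported:

========  =====================  ==============  ====
model     advection ``mu``       rotation        k
========  =====================  ==============  ====
UCVM      fixed (0, 0)           omega = 0        2
RCVM      fixed (0, 0)           omega free       3
ACVM      free                   omega = 0        4
RACVM     free                   omega free       5
========  =====================  ==============  ====

``tau`` (s) is the velocity-autocorrelation timescale: tau -> 0 gives
Brownian-like motion, large tau gives nearly linear paths.  ``eta``
(um/s) is the RMS of the stochastic velocity component about the
advection; the stationary root-mean-square speed is
``sqrt(eta**2 + |mu|**2)``.

Over a sampling interval ``dt`` the process has an exact discretization

    V_{k+1} = mu + a * (V_k - mu) + eps_k,
    a = exp((i*omega - 1/tau) * dt),

with ``eps_k`` circularly-symmetric complex Gaussian of total variance
``eta**2 * (1 - exp(-2*dt/tau))``.  Both the simulator and the velocity
likelihood below use this discretization, so they are mutually
consistent by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "MODELS",
    "K_FREE",
    "Trajectory",
    "CVMParams",
    "CVMFit",
    "simulate_cvm",
    "simulate_cvm_batch",
    "estimate_velocities",
    "cvm_loglik",
    "fit_cvm",
    "select_model",
    "read_trajectories",
    "write_trajectories",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)

#: Model names in tie-breaking order (simpler first).
MODELS = ("UCVM", "RCVM", "ACVM", "RACVM")

#: Number of free parameters per model.
K_FREE = {"UCVM": 2, "RCVM": 3, "ACVM": 4, "RACVM": 5}

_HAS_OMEGA = frozenset({"RCVM", "RACVM"})
_HAS_MU = frozenset({"ACVM", "RACVM"})

#: Default minimum number of positions required for likelihood fitting.
MIN_FIT_POINTS = 10

_DT_RTOL = 1e-6


class InsufficientDataError(ValueError):
    """Raised when a trajectory is too short for the requested operation."""


@dataclass
class Trajectory:
    """One cell's track: positions (um) at uniformly spaced times (s)."""

    traj_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise ValueError(f"{self.traj_id}: times/x/y length mismatch")
        if self.times.size < 2:
            raise ValueError(f"{self.traj_id}: need >= 2 points")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError(f"{self.traj_id}: times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > _DT_RTOL * dt):
            raise ValueError(f"{self.traj_id}: non-uniform time steps are not supported")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"{self.traj_id}: non-finite coordinates")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def net_displacement(self) -> float:
        """Euclidean distance from first to last position (um)."""
        return float(math.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))


@dataclass
class CVMParams:
    """Parameters of one CVM variant.

    tau and eta are in seconds and um/s; omega in rad/s; mu is the
    advection velocity in um/s as an (x, y) pair.
    """

    model: str
    tau: float
    eta: float
    omega: float = 0.0
    mu: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.model not in _HAS_OMEGA and self.omega != 0.0:
            raise ValueError(f"{self.model} fixes omega = 0")
        if self.model not in _HAS_MU and tuple(self.mu) != (0.0, 0.0):
            raise ValueError(f"{self.model} fixes mu = (0, 0)")

    @property
    def mu_complex(self) -> complex:
        return complex(self.mu[0], self.mu[1])

    @property
    def rms_speed(self) -> float:
        """Stationary root-mean-square speed sqrt(eta^2 + |mu|^2)."""
        return math.sqrt(self.eta**2 + abs(self.mu_complex) ** 2)


@dataclass
class CVMFit:
    """Result of fitting one CVM variant to one trajectory."""

    params: CVMParams
    loglik: float
    converged: bool
    boundary: bool

    @property
    def k(self) -> int:
        return K_FREE[self.params.model]

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def rms_speed(self) -> float:
        return self.params.rms_speed


def simulate_cvm(
    params: CVMParams,
    n_steps: int,
    dt: float,
    x0: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator | None = None,
    traj_id: str = "sim",
    meta: dict | None = None,
) -> Trajectory:
    """Simulate a trajectory of ``n_steps`` positions by exact discretization.

    The initial velocity is drawn from the stationary law (complex normal
    with mean mu and total variance eta^2); positions follow
    ``X_{k+1} = X_k + V_k * dt``.  The same seed yields identical output.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mu = params.mu_complex
    a = np.exp((1j * params.omega - 1.0 / params.tau) * dt)
    innov_sd = params.eta * math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * dt / params.tau)))

    n_vel = n_steps - 1
    z = rng.standard_normal((n_vel + 1, 2)) @ np.array([1.0, 1.0j])
    v = np.empty(n_vel, dtype=complex)
    # stationary start: total variance eta^2 => each component eta^2/2
    cur = mu + params.eta / math.sqrt(2.0) * z[0]
    for k in range(n_vel):
        v[k] = cur
        cur = mu + a * (cur - mu) + innov_sd / math.sqrt(2.0) * z[k + 1]

    pos = np.empty(n_steps, dtype=complex)
    pos[0] = complex(x0[0], x0[1])
    pos[1:] = pos[0] + np.cumsum(v) * dt
    times = np.arange(n_steps) * dt
    return Trajectory(traj_id, times, pos.real, pos.imag, meta=dict(meta or {}))


def simulate_cvm_batch(
    tau: np.ndarray,
    eta: np.ndarray,
    omega: np.ndarray,
    mu: np.ndarray,
    n_steps: int,
    dt: float,
    x0: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate many trajectories at once (same discretization as simulate_cvm).

    Parameter arrays are per-trajectory (``mu`` complex, ``x0`` complex
    start positions); returns a complex position array of shape
    ``(n_traj, n_steps)``.  The step recursion is vectorized across
    trajectories, which is what makes whole-experiment rendering cheap.
    """
    tau = np.asarray(tau, float)
    eta = np.asarray(eta, float)
    omega = np.asarray(omega, float)
    mu = np.asarray(mu, complex)
    x0 = np.asarray(x0, complex)
    if np.any(tau <= 0) or dt <= 0:
        raise ValueError("tau and dt must be > 0")
    m = tau.size
    a = np.exp((1j * omega - 1.0 / tau) * dt)
    innov_sd = eta * np.sqrt(np.maximum(0.0, 1.0 - np.exp(-2.0 * dt / tau)))

    n_vel = n_steps - 1
    z = rng.standard_normal((n_vel + 1, m, 2)) @ np.array([1.0, 1.0j])
    v = np.empty((n_vel, m), dtype=complex)
    cur = mu + eta / math.sqrt(2.0) * z[0]
    for k in range(n_vel):
        v[k] = cur
        cur = mu + a * (cur - mu) + innov_sd / math.sqrt(2.0) * z[k + 1]
    pos = np.empty((m, n_steps), dtype=complex)
    pos[:, 0] = x0
    pos[:, 1:] = x0[:, None] + np.cumsum(v.T, axis=1) * dt
    return pos


def estimate_velocities(traj: Trajectory) -> np.ndarray:
    """Finite-difference velocities ``(X_{k+1}-X_k)/dt`` as a complex array."""
    if traj.n < 3:
        raise InsufficientDataError(f"{traj.traj_id}: need >= 3 points for velocities")
    return (np.diff(traj.x) + 1j * np.diff(traj.y)) / traj.dt


def cvm_loglik(params: CVMParams, velocities: np.ndarray, dt: float) -> float:
    """Log-likelihood of a velocity series under the exact discretization.

    The first velocity contributes its stationary log-density; every
    subsequent one its conditional complex-Gaussian log-density.  With
    eta = 0 and non-degenerate data the contract is ``-inf`` (no
    exception): the degenerate model cannot explain any variation.
    """
    v = np.asarray(velocities, dtype=complex)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 velocities")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if params.eta == 0.0:
        mu = params.mu_complex
        a = np.exp((1j * params.omega - 1.0 / params.tau) * dt)
        resid = v[1:] - (mu + a * (v[:-1] - mu))
        if abs(v[0] - mu) == 0.0 and np.all(np.abs(resid) == 0.0):
            return math.inf  # delta-limit: all mass on the observed path
        return -math.inf

    mu = params.mu_complex
    a = np.exp((1j * params.omega - 1.0 / params.tau) * dt)
    eta2 = params.eta**2
    s2 = eta2 * (1.0 - math.exp(-2.0 * dt / params.tau))
    resid = v[1:] - (mu + a * (v[:-1] - mu))
    ll = (
        -math.log(math.pi * eta2)
        - abs(v[0] - mu) ** 2 / eta2
        - (v.size - 1) * math.log(math.pi * s2)
        - float(np.sum(np.abs(resid) ** 2)) / s2
    )
    return ll


def _initial_values(v: np.ndarray, dt: float, model: str) -> dict:
    """Moment-based starting values: deterministic and data-driven."""
    vbar = complex(np.mean(v))
    if model in _HAS_MU:
        mu0 = vbar
        dev = v - vbar
    else:
        mu0 = 0.0 + 0.0j
        dev = v
    eta0 = float(np.sqrt(np.mean(np.abs(dev) ** 2)))
    eta0 = max(eta0, 1e-3)

    # lag-1 autocorrelation of the centred series -> tau0
    d = v - vbar
    denom = float(np.sum(np.abs(d) ** 2))
    if denom > 0:
        rho1 = complex(np.sum(d[1:] * np.conj(d[:-1]))) / denom
    else:
        rho1 = 0.0 + 0.0j
    r = abs(rho1)
    tau0 = -dt / math.log(r) if 0.0 < r < 1.0 else 2.0 * dt
    omega0 = float(np.angle(rho1)) / dt if model in _HAS_OMEGA else 0.0
    return {"tau0": tau0, "eta0": eta0, "omega0": omega0, "mu0": mu0}


def fit_cvm(
    traj: Trajectory,
    model: str,
    min_points: int = MIN_FIT_POINTS,
    maxiter: int = 200,
) -> CVMFit:
    """Maximize the velocity likelihood of one CVM variant.

    Optimization runs over (log tau, log eta [, omega][, mu_x, mu_y])
    with box bounds tau in [dt/10, 100*T] (T = trajectory duration),
    eta in [1e-3, 10*max empirical speed], omega in [-pi/dt, pi/dt] and
    mu components within twice the largest empirical speed.  A fit whose
    optimizer did not report success is flagged ``converged=False``;
    a parameter resting on a box limit sets ``boundary=True``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if traj.n < min_points:
        raise InsufficientDataError(
            f"{traj.traj_id}: {traj.n} points < minimum {min_points} for fitting"
        )
    v = estimate_velocities(traj)
    dt = traj.dt
    vmax = float(np.max(np.abs(v)))
    vmax = max(vmax, 1e-2)

    lo_tau, hi_tau = math.log(dt / 10.0), math.log(100.0 * traj.duration)
    lo_eta, hi_eta = math.log(1e-3), math.log(10.0 * vmax)
    w_lim = math.pi / dt
    mu_lim = 2.0 * vmax

    init = _initial_values(v, dt, model)
    theta0 = [
        float(np.clip(math.log(init["tau0"]), lo_tau, hi_tau)),
        float(np.clip(math.log(init["eta0"]), lo_eta, hi_eta)),
    ]
    bounds = [(lo_tau, hi_tau), (lo_eta, hi_eta)]
    if model in _HAS_OMEGA:
        theta0.append(float(np.clip(init["omega0"], -w_lim, w_lim)))
        bounds.append((-w_lim, w_lim))
    if model in _HAS_MU:
        theta0 += [
            float(np.clip(init["mu0"].real, -mu_lim, mu_lim)),
            float(np.clip(init["mu0"].imag, -mu_lim, mu_lim)),
        ]
        bounds += [(-mu_lim, mu_lim), (-mu_lim, mu_lim)]

    v0, vk, vk1 = v[0], v[:-1], v[1:]
    n_cond = v.size - 1
    has_w = model in _HAS_OMEGA
    has_mu = model in _HAS_MU
    log_pi = math.log(math.pi)

    def nll(theta: np.ndarray) -> float:
        tau = math.exp(theta[0])
        eta2 = math.exp(2.0 * theta[1])
        omega = theta[2] if has_w else 0.0
        mu = complex(theta[-2], theta[-1]) if has_mu else 0.0j
        a = np.exp((1j * omega - 1.0 / tau) * dt)
        s2 = eta2 * (1.0 - math.exp(-2.0 * dt / tau))
        resid = vk1 - (mu + a * (vk - mu))
        ll = (
            -log_pi
            - math.log(eta2)
            - abs(v0 - mu) ** 2 / eta2
            - n_cond * (log_pi + math.log(s2))
            - float(np.sum(resid.real**2 + resid.imag**2)) / s2
        )
        return -ll

    res = minimize(
        nll,
        np.asarray(theta0),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter},
    )
    theta = res.x
    tau = math.exp(theta[0])
    eta = math.exp(theta[1])
    omega = float(theta[2]) if has_w else 0.0
    mu = (float(theta[-2]), float(theta[-1])) if has_mu else (0.0, 0.0)
    params = CVMParams(model=model, tau=tau, eta=eta, omega=omega, mu=mu)

    atol = 1e-6
    boundary = any(
        (th - lo) < atol * max(1.0, abs(lo)) or (hi - th) < atol * max(1.0, abs(hi))
        for th, (lo, hi) in zip(theta, bounds)
    )
    return CVMFit(
        params=params,
        loglik=-float(res.fun),
        converged=bool(res.success),
        boundary=boundary,
    )


def select_model(
    traj: Trajectory,
    models: Sequence[str] = MODELS,
    min_points: int = MIN_FIT_POINTS,
) -> tuple[CVMFit, dict[str, CVMFit]]:
    """Fit all variants and pick the minimum-AIC one.

    Ties are broken by smaller k, then by the fixed order
    UCVM < RCVM < ACVM < RACVM.  A variant whose fit raises is excluded
    from selection (and logged); if all variants fail, a RuntimeError
    is raised.
    """
    fits: dict[str, CVMFit] = {}
    for m in models:
        try:
            fits[m] = fit_cvm(traj, m, min_points=min_points)
        except InsufficientDataError:
            raise
        except Exception as exc:  # noqa: BLE001 - sub-fit failure is data-dependent
            logger.warning("fit of %s failed on %s: %s", m, traj.traj_id, exc)
    if not fits:
        raise RuntimeError(f"{traj.traj_id}: all model fits failed")
    order = {m: i for i, m in enumerate(MODELS)}
    best = min(fits.values(), key=lambda f: (f.aic, f.k, order[f.params.model]))
    return best, fits


# ---------------------------------------------------------------------------
# CSV interfaces

_TRAJ_COLS = ["traj_id", "genotype", "replicate", "status", "frame", "time_s", "x_um", "y_um"]


def write_trajectories(trajs: Sequence[Trajectory], path) -> None:
    """Write trajectories as long-format CSV (one row per frame)."""
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "traj_id": t.traj_id,
                    "genotype": t.meta.get("genotype", ""),
                    "replicate": t.meta.get("replicate", ""),
                    "status": t.meta.get("status", ""),
                    "frame": np.arange(t.n),
                    "time_s": t.times,
                    "x_um": t.x,
                    "y_um": t.y,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path) -> list[Trajectory]:
    """Read long-format trajectory CSV back into Trajectory objects."""
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {missing}")
    trajs = []
    for tid, g in df.groupby("traj_id", sort=False):
        g = g.sort_values("frame")
        meta = {
            "genotype": str(g["genotype"].iloc[0]),
            "replicate": g["replicate"].iloc[0],
            "status": str(g["status"].iloc[0]),
        }
        trajs.append(Trajectory(str(tid), g["time_s"].values, g["x_um"].values, g["y_um"].values, meta))
    return trajs


def fits_to_frame(rows: Mapping[str, tuple[CVMFit, dict[str, CVMFit]]]) -> pd.DataFrame:
    """Flatten per-trajectory selection results into the fit-table layout.

    ``rows`` maps traj_id to the (best, all-fits) pair from select_model;
    one output row per (trajectory, model), with ``selected`` marking the
    minimum-AIC variant.
    """
    recs = []
    for tid, (best, fits) in rows.items():
        for m, f in fits.items():
            p = f.params
            recs.append(
                {
                    "traj_id": tid,
                    "model": m,
                    "tau_s": p.tau,
                    "eta_um_s": p.eta,
                    "omega_rad_s": p.omega,
                    "mu_x": p.mu[0],
                    "mu_y": p.mu[1],
                    "loglik": f.loglik,
                    "k": f.k,
                    "aic": f.aic,
                    "rms_speed_um_s": f.rms_speed,
                    "converged": f.converged,
                    "boundary": f.boundary,
                    "selected": m == best.params.model,
                }
            )
    return pd.DataFrame(recs)
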