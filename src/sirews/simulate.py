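"""Trajectory generation for the stochastic SIR model with vaccination.

Four routes from parameters to time series, in decreasing order of fidelity
to the finite-population process:

* :func:`gillespie` — exact event-driven continuous-time Markov chain over
  the six demographic events (susceptible birth, death of S, transmission,
  sparking, recovery, death of I);
* :func:`euler_maruyama` — the diffusion approximation, integrating the
  drift with state-dependent demographic noise of covariance rate B;
* :func:`ou_sample` — exact sampling of the linearized (OU) fluctuations
  about an equilibrium, useful for long stationary series;
* :func:`ode_trajectory` — the noise-free deterministic skeleton.

Vaccine uptake may vary in time through a :class:`VaccineSchedule` (constant,
linear ramp, or piecewise linear), entering only the birth-splitting rate.
All simulators record their method, seed and parameters in the series
metadata so every stochastic artifact can be regenerated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import cholesky, expm

from .fluctuations import diffusion_matrix, stationary_covariance
from .model import Equilibrium, ModelParams, disease_free_equilibrium, equilibria

__all__ = [
    "VaccineSchedule",
    "TimeSeries",
    "gillespie",
    "euler_maruyama",
    "ou_sample",
    "ode_trajectory",
    "default_init",
]

#: Maximum holding time between rate refreshes when uptake varies in time.
MAX_EVENT_STEP_YEARS = 1.0 / 365.0

#: Default sampling interval: weekly reporting.
DEFAULT_SAMPLE_DT = 1.0 / 52.0


# ---------------------------------------------------------------------------
# Schedules and series containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VaccineSchedule:
    """Vaccine uptake as a function of time, clipped to [0, 1].

    ``constant``: nu(t) = nu0.  ``linear_ramp``: nu0 until ``ramp_start``,
    then nu0 + ramp_rate * (t - ramp_start).  ``piecewise``: linear
    interpolation through ``breakpoints`` [(time, uptake), ...], held flat
    outside their range.
    """

    mode: str = "constant"
    nu0: float = 0.0
    ramp_rate: float = 0.0
    ramp_start: float = 0.0
    breakpoints: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"constant", "linear_ramp", "piecewise"}:
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "piecewise":
            if not self.breakpoints:
                raise ValueError("piecewise schedule needs breakpoints")
            times = [t for t, _ in self.breakpoints]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("breakpoint times must be strictly increasing")

    @classmethod
    def constant(cls, nu: float) -> "VaccineSchedule":
        return cls(mode="constant", nu0=nu)

    @classmethod
    def linear_ramp(cls, nu0: float, rate: float, start: float) -> "VaccineSchedule":
        return cls(mode="linear_ramp", nu0=nu0, ramp_rate=rate, ramp_start=start)

    @classmethod
    def piecewise(cls, breakpoints: Sequence[tuple[float, float]]) -> "VaccineSchedule":
        return cls(mode="piecewise", breakpoints=tuple(breakpoints))

    @property
    def is_constant(self) -> bool:
        return self.mode == "constant" or (
            self.mode == "linear_ramp" and self.ramp_rate == 0.0
        )

    def nu_at(self, t: float | np.ndarray) -> float | np.ndarray:
        if self.mode == "constant":
            nu = np.full_like(np.asarray(t, dtype=float), self.nu0) if np.ndim(t) else self.nu0
        elif self.mode == "linear_ramp":
            nu = self.nu0 + self.ramp_rate * np.maximum(
                np.asarray(t, dtype=float) - self.ramp_start, 0.0
            )
        else:
            times = np.array([b[0] for b in self.breakpoints])
            values = np.array([b[1] for b in self.breakpoints])
            nu = np.interp(np.asarray(t, dtype=float), times, values)
        nu = np.clip(nu, 0.0, 1.0)
        return float(nu) if np.ndim(t) == 0 else nu


@dataclass
class TimeSeries:
    """A sampled (t, S, I, nu) trajectory with provenance metadata."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    nu: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "S": self.S, "I": self.I, "nu": self.nu})


def default_init(params: ModelParams, schedule: VaccineSchedule) -> tuple[float, float]:
    """Equilibrium state for the schedule's initial uptake."""
    p0 = params.with_nu(schedule.nu_at(0.0))
    eqs = equilibria(p0)
    eq = eqs[-1]  # endemic/sparked when present, else disease-free
    return eq.S_star, eq.I_star


# ---------------------------------------------------------------------------
# Exact event-driven simulation
# ---------------------------------------------------------------------------

def gillespie(
    params: ModelParams,
    schedule: VaccineSchedule,
    T: float,
    seed: int,
    init: tuple[int, int] | None = None,
    sample_dt: float = DEFAULT_SAMPLE_DT,
) -> TimeSeries:
    """Exact stochastic simulation of the SIR jump process.

    Events and rates: susceptible birth b(1-nu(t)); death of a susceptible
    mu S; transmission beta S I; sparking eta S (moves S to I); recovery
    gamma I; death of an infected mu I.  Recovery and death of I are
    simulated separately; together they contribute the (gamma+mu) I variance
    of the diffusion matrix.

    Time-varying uptake is handled by capping each exponential holding time
    at one day and refreshing the rates, which is exact for constant nu and
    accurate for the slow ramps of interest.  The trajectory is sampled on a
    regular grid of spacing ``sample_dt``.
    """
    if T <= 0:
        raise ValueError("horizon T must be positive")
    if init is None:
        S0, I0 = default_init(params, schedule)
        S, I = int(round(S0)), int(round(I0))
    else:
        S, I = init
        if S < 0 or I < 0 or S != int(S) or I != int(I):
            raise ValueError("initial state must be nonnegative integers")
        S, I = int(S), int(I)

    rng = np.random.default_rng(seed)
    beta, mu, gamma, eta, b = params.beta, params.mu, params.gamma, params.eta, params.b

    n_samples = int(math.floor(T / sample_dt)) + 1
    grid = np.arange(n_samples) * sample_dt
    out_S = np.empty(n_samples, dtype=np.int64)
    out_I = np.empty(n_samples, dtype=np.int64)

    constant = schedule.is_constant
    max_step = math.inf if constant else MAX_EVENT_STEP_YEARS
    nu_now = schedule.nu_at(0.0)

    t = 0.0
    k = 0  # next grid index to fill
    # local aliases for speed in the event loop
    exponential = rng.exponential
    random = rng.random
    while True:
        if not constant:
            nu_now = schedule.nu_at(t)
        r_birth = b * (1.0 - nu_now)
        r_dS = mu * S
        r_inf = beta * S * I
        r_spark = eta * S
        r_rec = gamma * I
        r_dI = mu * I
        total = r_birth + r_dS + r_inf + r_spark + r_rec + r_dI
        if not math.isfinite(total) or total < 0:
            raise FloatingPointError("event rates overflowed or went negative")
        wait = exponential(1.0 / total) if total > 0 else math.inf
        t_next = t + min(wait, max_step)
        # emit samples passed over by this holding interval
        while k < n_samples and grid[k] <= t_next:
            out_S[k] = S
            out_I[k] = I
            k += 1
        if k >= n_samples:
            break
        t = t_next
        if wait > max_step:
            continue  # rate refresh only, no event fired
        u = random() * total
        if u < r_birth:
            S += 1
        elif u < r_birth + r_dS:
            S -= 1
        elif u < r_birth + r_dS + r_inf:
            S -= 1
            I += 1
        elif u < r_birth + r_dS + r_inf + r_spark:
            S -= 1
            I += 1
        elif u < r_birth + r_dS + r_inf + r_spark + r_rec:
            I -= 1
        else:
            I -= 1

    return TimeSeries(
        t=grid,
        S=out_S,
        I=out_I,
        nu=np.asarray(schedule.nu_at(grid), dtype=float),
        meta={
            "method": "gillespie",
            "seed": seed,
            "params": params,
            "schedule": schedule,
            "sample_dt": sample_dt,
        },
    )


# ---------------------------------------------------------------------------
# Diffusion approximation
# ---------------------------------------------------------------------------

def euler_maruyama(
    params: ModelParams,
    schedule: VaccineSchedule,
    T: float,
    dt: float,
    seed: int | None,
    init: tuple[float, float] | None = None,
    noise: bool = True,
) -> TimeSeries:
    """Euler-Maruyama integration of the SIR diffusion approximation.

    At each step the drift advances the state and, when ``noise`` is on, a
    Gaussian increment with covariance B(state) * dt is added, with B
    factorized by Cholesky (falling back to an eigenvalue square root at
    semidefinite states).  States are floored at zero after each step — the
    standard truncation fix for diffusion approximations of count processes.
    With noise off this is a fixed-step integration of the deterministic
    skeleton.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if init is None:
        init = default_init(params, schedule)
    rng = np.random.default_rng(seed)
    beta, mu, gamma, eta, b = params.beta, params.mu, params.gamma, params.eta, params.b

    n_steps = int(round(T / dt))
    t = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 2))
    out[0] = init
    S, I = float(init[0]), float(init[1])
    sqrt_dt = math.sqrt(dt)
    for k in range(n_steps):
        nu_now = schedule.nu_at(t[k])
        infection = beta * S * I + eta * S
        dS = -infection + b * (1.0 - nu_now) - mu * S
        dI = infection - (gamma + mu) * I
        S += dS * dt
        I += dI * dt
        if noise:
            B = np.array(
                [
                    [infection + b * (1.0 - nu_now) + mu * max(S, 0.0), -infection],
                    [-infection, infection + (gamma + mu) * max(I, 0.0)],
                ]
            )
            L = _sqrt_psd(B)
            eps = L @ rng.standard_normal(2)
            S += eps[0] * sqrt_dt
            I += eps[1] * sqrt_dt
        S = max(S, 0.0)
        I = max(I, 0.0)
        out[k + 1] = (S, I)

    return TimeSeries(
        t=t,
        S=out[:, 0],
        I=out[:, 1],
        nu=np.asarray(schedule.nu_at(t), dtype=float),
        meta={
            "method": "euler_maruyama",
            "seed": seed,
            "params": params,
            "schedule": schedule,
            "dt": dt,
            "noise": noise,
        },
    )


def _sqrt_psd(B: np.ndarray) -> np.ndarray:
    """Matrix square root of a (numerically) positive-semidefinite 2x2."""
    try:
        return cholesky(B, lower=True)
    except np.linalg.LinAlgError:
        pass
    except Exception:
        pass
    evals, evecs = np.linalg.eigh(B)
    if np.any(evals < -1e-8 * max(1.0, float(np.abs(B).max()))):
        raise ValueError("diffusion matrix is not positive semidefinite")
    return evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))


# ---------------------------------------------------------------------------
# Exact OU sampling of the linearized fluctuations
# ---------------------------------------------------------------------------

def ou_sample(
    J: np.ndarray,
    B: np.ndarray,
    T: float,
    dt: float,
    seed: int | None,
) -> TimeSeries:
    """Exactly discretized OU sample of the linearized deviations.

    Uses the recursion z_{k+1} = F z_k + e_k with propagator F = exp(J dt)
    and innovation covariance Q = Sigma - F Sigma F', where Sigma solves the
    stationary Lyapunov equation; the first sample is drawn from Sigma, so
    the series is stationary from the start.  The S and I fields hold the
    deviations z_S, z_I (not counts); nu is reported as NaN.
    """
    J = np.asarray(J, dtype=float)
    Sigma = stationary_covariance(J, B)
    F = expm(J * dt)
    Q = Sigma - F @ Sigma @ F.T
    Q = (Q + Q.T) / 2.0
    L_Q = _sqrt_psd(Q)
    L_S = _sqrt_psd(Sigma)

    rng = np.random.default_rng(seed)
    n = int(round(T / dt)) + 1
    innov = rng.standard_normal((n, 2)) @ L_Q.T
    z = np.empty((n, 2))
    z[0] = L_S @ rng.standard_normal(2)
    zk = z[0]
    for k in range(1, n):
        zk = F @ zk + innov[k]
        z[k] = zk

    t = np.arange(n) * dt
    return TimeSeries(
        t=t,
        S=z[:, 0],
        I=z[:, 1],
        nu=np.full(n, np.nan),
        meta={"method": "ou_sample", "seed": seed, "dt": dt, "J": J, "B": np.asarray(B)},
    )


# ---------------------------------------------------------------------------
# Deterministic skeleton
# ---------------------------------------------------------------------------

def ode_trajectory(
    params: ModelParams,
    schedule: VaccineSchedule,
    T: float,
    init: tuple[float, float] | None = None,
    sample_dt: float = DEFAULT_SAMPLE_DT,
    rtol: float = 1e-9,
    atol: float = 1e-8,
) -> TimeSeries:
    """Adaptive-step integration of the noise-free SIR drift."""
    if T <= 0:
        raise ValueError("horizon T must be positive")
    if init is None:
        init = default_init(params, schedule)
    beta, mu, gamma, eta, b = params.beta, params.mu, params.gamma, params.eta, params.b

    def drift(t: float, y: np.ndarray) -> list[float]:
        S, I = y
        nu_now = schedule.nu_at(t)
        infection = beta * S * I + eta * S
        return [-infection + b * (1.0 - nu_now) - mu * S, infection - (gamma + mu) * I]

    grid = np.arange(int(math.floor(T / sample_dt)) + 1) * sample_dt
    sol = solve_ivp(drift, (0.0, T), init, t_eval=grid, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return TimeSeries(
        t=sol.t,
        S=sol.y[0],
        I=sol.y[1],
        nu=np.asarray(schedule.nu_at(sol.t), dtype=float),
        meta={"method": "ode", "seed": None, "params": params, "schedule": schedule,
              "sample_dt": sample_dt},
    )
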