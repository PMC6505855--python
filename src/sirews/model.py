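"""Deterministic skeleton of the SIR model with vaccination and sparking.

The model tracks susceptible (S) and infected (I) counts in a population of
expected size N = b/mu, with transmission rate beta, recovery rate gamma,
per-capita sparking (external introduction) rate eta, birth rate b, death
rate mu, and a fraction nu of births vaccinated.  The epidemiologically
meaningful control parameter is R0*(1 - nu): above 1 the endemic equilibrium
is stable, below 1 only the disease-free state persists, and the exchange of
stability at R0*(1 - nu) = 1 is a transcritical bifurcation.

This module provides the equilibria, their local linear analysis (Jacobian,
eigenvalues, trace/determinant, damping ratio), the harmonic-oscillator
potential of the linearized infected deviation, the immunization threshold,
closed-form eigenvalue approximations, the inter-epidemic period, and the
uptake level at which the equilibrium becomes underdamped.

All rates are per year; times are in years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "Equilibrium",
    "StabilityReport",
    "PeriodPrediction",
    "threshold_uptake",
    "equilibria",
    "endemic_equilibrium",
    "disease_free_equilibrium",
    "sparked_equilibrium",
    "jacobian",
    "stability",
    "eigenvalue_approximations",
    "period_prediction",
    "potential",
    "underdamped_boundary",
    "linear_solution",
]


# ---------------------------------------------------------------------------
# Parameters and equilibria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Rate constants and vaccine uptake defining one SIR system.

    Parameters
    ----------
    b : float
        Birth rate (individuals / year).
    mu : float
        Per-capita death rate (1 / year).
    gamma : float
        Recovery rate (1 / year); the infectious period is 1/gamma years.
    eta : float
        Per-capita sparking rate (1 / year): the rate at which a susceptible
        is infected from outside the population.  eta = 0 gives the closed
        model with a true disease-free state.
    nu : float
        Vaccine uptake, the fraction of births immunized (dimensionless).
    R0 : float
        Basic reproduction number (dimensionless).  The transmission rate is
        derived as beta = R0 * (gamma + mu) / N with N = b / mu.
    """

    b: float
    mu: float
    gamma: float
    eta: float = 0.0
    nu: float = 0.0
    R0: float = 17.0

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.mu > 0 and self.gamma > 0):
            raise ValueError("b, mu and gamma must be strictly positive")
        if self.eta < 0:
            raise ValueError("sparking rate eta must be nonnegative")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("vaccine uptake nu must lie in [0, 1]")
        if self.R0 <= 0:
            raise ValueError("R0 must be strictly positive")

    @property
    def N(self) -> float:
        """Expected total population size b/mu."""
        return self.b / self.mu

    @property
    def beta(self) -> float:
        """Transmission rate R0*(gamma+mu)/N (1 / (individual * year))."""
        return self.R0 * (self.gamma + self.mu) / self.N

    @property
    def control(self) -> float:
        """The control parameter R0*(1 - nu)."""
        return self.R0 * (1.0 - self.nu)

    def with_nu(self, nu: float) -> "ModelParams":
        """Copy of the parameter set at a different uptake."""
        return replace(self, nu=nu)


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the deterministic drift.

    ``branch`` is ``disease_free`` or ``endemic`` for the closed model
    (eta = 0) and ``sparked`` for the unique positive-prevalence equilibrium
    of the open model (eta > 0).
    """

    S_star: float
    I_star: float
    branch: str

    def __post_init__(self) -> None:
        if self.S_star < 0 or self.I_star < 0:
            raise ValueError("equilibrium counts must be nonnegative")
        if self.branch not in {"disease_free", "endemic", "sparked"}:
            raise ValueError(f"unknown branch {self.branch!r}")

    @property
    def state(self) -> np.ndarray:
        return np.array([self.S_star, self.I_star])


def threshold_uptake(params: ModelParams) -> float:
    """Critical vaccine uptake nu_c = 1 - 1/R0.

    Above this uptake the control parameter R0*(1 - nu) drops below 1 and
    sustained transmission is impossible.  Negative values (R0 < 1) mean no
    vaccination is needed to prevent transmission.
    """
    return 1.0 - 1.0 / params.R0


def disease_free_equilibrium(params: ModelParams) -> Equilibrium:
    """(S*, I*) = (N(1 - nu), 0); exists only in the closed model."""
    if params.eta > 0:
        raise ValueError("disease-free equilibrium requires eta = 0")
    return Equilibrium(params.N * (1.0 - params.nu), 0.0, "disease_free")


def endemic_equilibrium(params: ModelParams) -> Equilibrium:
    """(S*, I*) = (N/R0, (mu/beta)[R0(1 - nu) - 1]) for R0(1-nu) >= 1, eta = 0."""
    if params.eta > 0:
        raise ValueError("closed-model endemic equilibrium requires eta = 0")
    if params.control < 1.0:
        raise ValueError("endemic equilibrium requires R0(1 - nu) >= 1")
    I_star = (params.mu / params.beta) * (params.control - 1.0)
    return Equilibrium(params.N / params.R0, I_star, "endemic")


def sparked_equilibrium(params: ModelParams) -> Equilibrium:
    """Unique nonnegative equilibrium of the open model (eta > 0).

    Setting the drift to zero and eliminating S gives a quadratic in I*:

        beta*(gamma+mu) I**2
        + [(mu + eta)*(gamma+mu) - beta*b*(1-nu)] I
        - eta*b*(1-nu) = 0

    whose constant term is negative for eta > 0, so exactly one root is
    positive.  S* follows from the infection balance.
    """
    if params.eta <= 0:
        raise ValueError("sparked equilibrium requires eta > 0")
    beta, gm = params.beta, params.gamma + params.mu
    inflow = params.b * (1.0 - params.nu)
    a2 = beta * gm
    a1 = (params.mu + params.eta) * gm - beta * inflow
    a0 = -params.eta * inflow
    disc = a1 * a1 - 4.0 * a2 * a0
    assert disc >= 0, "sparked-equilibrium quadratic has no real root"
    I_star = (-a1 + math.sqrt(disc)) / (2.0 * a2)
    assert I_star > 0, "sparked equilibrium must have positive prevalence"
    S_star = gm * I_star / (beta * I_star + params.eta)
    return Equilibrium(S_star, I_star, "sparked")


def equilibria(params: ModelParams) -> list[Equilibrium]:
    """All admissible equilibria for the parameter set.

    Closed model (eta = 0): the disease-free state always, plus the endemic
    state when R0(1 - nu) > 1.  Open model (eta > 0): the single sparked
    equilibrium, which has I* > 0 at every uptake.
    """
    if params.eta > 0:
        return [sparked_equilibrium(params)]
    eqs = [disease_free_equilibrium(params)]
    if params.control > 1.0:
        eqs.append(endemic_equilibrium(params))
    return eqs


# ---------------------------------------------------------------------------
# Linear stability
# ---------------------------------------------------------------------------

def jacobian(params: ModelParams, eq: Equilibrium) -> np.ndarray:
    """Jacobian of the drift at an equilibrium.

        J = [[-beta*I* - eta - mu,  -beta*S*          ],
             [ beta*I* + eta,        beta*S* - (gamma+mu)]]
    """
    beta = params.beta
    S, I = eq.S_star, eq.I_star
    return np.array(
        [
            [-beta * I - params.eta - params.mu, -beta * S],
            [beta * I + params.eta, beta * S - (params.gamma + params.mu)],
        ]
    )


@dataclass(frozen=True)
class StabilityReport:
    """Local linear analysis of an equilibrium.

    The deviation of the infected count from equilibrium obeys the damped
    harmonic oscillator z'' - tau z' + Delta z = 0, where tau and Delta are
    the trace and determinant of J.  The damping ratio zeta = -tau/sqrt(4 Delta)
    is < 1 exactly when the eigenvalues are a complex pair (underdamped), in
    which case their common modulus is sqrt(Delta) and the oscillation period
    is 2 pi / Im(lambda).
    """

    J: np.ndarray
    eigenvalues: tuple[complex, complex]
    tau: float
    Delta: float
    zeta: float
    modulus: float
    period: float
    regime: tuple[str, str]

    @property
    def dominant(self) -> complex:
        """Eigenvalue with the largest real part."""
        return self.eigenvalues[0]

    @property
    def stable(self) -> bool:
        return self.regime[0] == "stable"

    @property
    def underdamped(self) -> bool:
        return self.regime[1] == "underdamped"


def stability(params: ModelParams, eq: Equilibrium) -> StabilityReport:
    """Eigenvalues, damping and regime labels for an equilibrium."""
    J = jacobian(params, eq)
    lam = np.linalg.eigvals(J)
    order = np.argsort(-lam.real)
    lam = lam[order]
    tau = float(np.trace(J))
    Delta = float(np.linalg.det(J))
    underdamped = bool(abs(lam[0].imag) > 0)
    zeta = -tau / math.sqrt(4.0 * Delta) if Delta > 0 else math.nan
    modulus = abs(lam[0]) if underdamped else math.nan
    period = 2.0 * math.pi / abs(lam[0].imag) if underdamped else math.nan
    stab = "stable" if max(lam.real) <= 0 else "unstable"
    if underdamped:
        damping = "underdamped"
    elif Delta > 0 and abs(zeta - 1.0) < 1e-12:
        damping = "critical"
    else:
        damping = "overdamped"
    return StabilityReport(
        J=J,
        eigenvalues=(complex(lam[0]), complex(lam[1])),
        tau=tau,
        Delta=Delta,
        zeta=zeta,
        modulus=modulus,
        period=period,
        regime=(stab, damping),
    )


def endemic_eigenvalues_closed_form(params: ModelParams) -> tuple[complex, complex]:
    """Closed-form endemic eigenvalues of the closed model,

        -mu R0 (1-nu)/2 +/- sqrt[(mu R0 (1-nu))^2/4 - mu (R0(1-nu)-1)(mu+gamma)].

    Used as an independent check on the numerical eigenvalues.
    """
    x = params.control
    re = -params.mu * x / 2.0
    rad = complex((params.mu * x) ** 2 / 4.0 - params.mu * (x - 1.0) * (params.mu + params.gamma))
    root = np.sqrt(rad)
    return (re + root, re - root)


def eigenvalue_approximations(params: ModelParams) -> tuple[float, float]:
    """Approximate (Re, Im) of the endemic eigenvalues for mu << gamma.

    Re(lambda) ~ -mu R0 (1-nu) / 2 and Im(lambda) ~ sqrt(mu (R0(1-nu)-1) gamma).
    Valid only above threshold, R0(1 - nu) > 1.
    """
    x = params.control
    if x <= 1.0:
        raise ValueError("eigenvalue approximations require R0(1 - nu) > 1")
    re = -params.mu * x / 2.0
    im = math.sqrt(params.mu * (x - 1.0) * params.gamma)
    return re, im


@dataclass(frozen=True)
class PeriodPrediction:
    """Inter-epidemic period, exactly and via the mean age at infection.

    A = 1/[mu (R0(1-nu) - 1)] is the mean age at infection, D = 1/gamma the
    expected infectious duration, and 2 pi sqrt(A D) approximates the period
    2 pi / Im(lambda) of the damped endemic oscillation when mu << gamma.
    """

    A: float
    D: float
    period_approx: float
    period_exact: float


def period_prediction(params: ModelParams) -> PeriodPrediction:
    """Predict the inter-epidemic period above threshold (R0(1-nu) > 1)."""
    x = params.control
    if x <= 1.0:
        raise ValueError("period prediction requires R0(1 - nu) > 1")
    A = 1.0 / (params.mu * (x - 1.0))
    D = 1.0 / params.gamma
    approx = 2.0 * math.pi * math.sqrt(A * D)
    closed = replace(params, eta=0.0)
    rep = stability(closed, endemic_equilibrium(closed))
    return PeriodPrediction(A=A, D=D, period_approx=approx, period_exact=rep.period)


def potential(Delta: float, z_I: float | np.ndarray) -> float | np.ndarray:
    """Harmonic-oscillator potential V(z_I) = Delta * z_I**2 / 2.

    Integrating the restorative force of z'' - tau z' + Delta z = 0 gives a
    quadratic well whose depth scales with the Jacobian determinant: the well
    is shallowest near the immunization threshold, where Delta -> 0.  For a
    prevalence-scale display, pass deviations rescaled by sqrt(b/mu).
    """
    return Delta * np.square(z_I) / 2.0


def underdamped_boundary(
    params: ModelParams,
    bracket: tuple[float, float] | None = None,
    xtol: float = 1e-6,
) -> float:
    """Uptake at which the equilibrium switches over- to underdamped.

    Solves zeta(nu) = 1 at the system's equilibrium (sparked when eta > 0,
    endemic otherwise) by bracketed root finding on
    [0.9 * nu_c, nu_c - 1e-6] by default.  ``params.nu`` is ignored.
    """
    nu_c = threshold_uptake(params)
    if bracket is None:
        bracket = (0.9 * nu_c, nu_c - 1e-6)
    lo, hi = bracket

    def zeta_minus_one(nu: float) -> float:
        p = params.with_nu(nu)
        eq = sparked_equilibrium(p) if p.eta > 0 else endemic_equilibrium(p)
        return stability(p, eq).zeta - 1.0

    f_lo, f_hi = zeta_minus_one(lo), zeta_minus_one(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"zeta(nu) - 1 does not change sign on [{lo:.6g}, {hi:.6g}] "
            f"(endpoint values {f_lo:.3g}, {f_hi:.3g})"
        )
    return float(brentq(zeta_minus_one, lo, hi, xtol=xtol))


def linear_solution(
    J: np.ndarray, z0: Sequence[float], t: float | np.ndarray
) -> np.ndarray:
    """Propagate a deviation z0 under the linearized dynamics z' = J z.

    Returns exp(J t) @ z0; for an array of times, one row per time.  This is
    the two-mode solution z_I(t) = k1 exp(lambda1 t) + k2 exp(lambda2 t) with
    the coefficients implied by the initial deviation.
    """
    z0 = np.asarray(z0, dtype=float)
    if np.ndim(t) == 0:
        if t < 0:
            raise ValueError("propagation time must be nonnegative")
        return expm(np.asarray(J) * float(t)) @ z0
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("propagation times must be nonnegative")
    return np.stack([expm(np.asarray(J) * ti) @ z0 for ti in t])
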