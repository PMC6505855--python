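"""Linear-noise (Ornstein-Uhlenbeck) fluctuation theory about an equilibrium.

Demographic stochasticity perturbs the SIR system continually; near a stable
equilibrium the deviations z = (S - S*, I - I*) behave as a two-dimensional
OU process dz = J z dt + dW with drift given by the Jacobian J and white
noise of covariance rate B (the demographic diffusion matrix).  Its
stationary law is bivariate normal with covariance Sigma solving the
continuous Lyapunov equation J Sigma + Sigma J' + B = 0, and its lagged
autocovariance is C(l) = exp(J l) Sigma.

The module computes B, Sigma, the generalized variance det(Sigma), the 95%
concentration ellipse, lagged autocovariance/autocorrelation, and a scan of
these summaries over a vaccine-uptake grid (the quantities whose peaks near
the immunization threshold serve as early warning signals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import chi2

from .model import (
    Equilibrium,
    ModelParams,
    disease_free_equilibrium,
    endemic_equilibrium,
    jacobian,
    sparked_equilibrium,
    stability,
)

__all__ = [
    "diffusion_matrix",
    "stationary_covariance",
    "generalized_variance",
    "ellipse_95",
    "Ellipse",
    "autocovariance",
    "autocorrelation",
    "FluctuationSummary",
    "fluctuation_summary",
    "variance_scan",
]

#: 95% quantile of the chi-square law with 2 degrees of freedom; the Mahalanobis
#: radius-squared of the smallest region holding 95% of a bivariate normal.
CHI2_95_2DF: float = float(chi2.ppf(0.95, df=2))


def diffusion_matrix(params: ModelParams, state: Sequence[float]) -> np.ndarray:
    """Demographic-noise covariance rate B at a state (S, I).

        B = [[beta S I + eta S + b(1-nu) + mu S,  -(beta S I + eta S)       ],
             [-(beta S I + eta S),                 beta S I + eta S + (gamma+mu) I]]

    Each diagonal entry sums the rates of all events moving that variable;
    the off-diagonal carries (negatively) the infection events that move S
    and I together.  Units: individuals^2 / year.
    """
    S, I = float(state[0]), float(state[1])
    if S < 0 or I < 0:
        raise ValueError("state counts must be nonnegative")
    infection = params.beta * S * I + params.eta * S
    return np.array(
        [
            [infection + params.b * (1.0 - params.nu) + params.mu * S, -infection],
            [-infection, infection + (params.gamma + params.mu) * I],
        ]
    )


def stationary_covariance(J: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Stationary covariance Sigma of the OU process dz = J z dt + dW.

    Solves J Sigma + Sigma J' + B = 0 exactly, written as a 3-unknown linear
    system in (Sigma_SS, Sigma_SI, Sigma_II) for the symmetric 2x2 case.
    Requires J to be stable (all eigenvalues with negative real part).
    """
    J = np.asarray(J, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(np.linalg.eigvals(J).real >= 0):
        raise ValueError("J must be stable for a stationary distribution to exist")
    a, bb, c, d = J[0, 0], J[0, 1], J[1, 0], J[1, 1]
    # Unknowns x = (s11, s12, s22); rows are the (0,0), (0,1), (1,1) entries
    # of J Sigma + Sigma J' = -B.
    M = np.array(
        [
            [2.0 * a, 2.0 * bb, 0.0],
            [c, a + d, bb],
            [0.0, 2.0 * c, 2.0 * d],
        ]
    )
    rhs = -np.array([B[0, 0], B[0, 1], B[1, 1]])
    s11, s12, s22 = np.linalg.solve(M, rhs)
    return np.array([[s11, s12], [s12, s22]])


def generalized_variance(Sigma: np.ndarray) -> float:
    """Determinant of the stationary covariance (individuals^4)."""
    return float(np.linalg.det(np.asarray(Sigma, dtype=float)))


@dataclass(frozen=True)
class Ellipse:
    """Geometry of a bivariate-normal 95% concentration ellipse."""

    area: float
    semi_axes: tuple[float, float]
    orientation: float  # radians, angle of the major axis from the S axis


def ellipse_95(Sigma: np.ndarray) -> Ellipse:
    """Smallest ellipse containing 95% of the stationary deviations.

    For a bivariate normal the region is {z : z' Sigma^-1 z <= q} with q the
    0.95 quantile of chi-square(2), so area = pi q sqrt(det Sigma) and the
    semi-axes are sqrt(q * eigenvalue_i) along the eigenvectors of Sigma.
    Hence area^2 is proportional to the generalized variance.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    evals, evecs = np.linalg.eigh(Sigma)
    if np.any(evals <= 0):
        raise ValueError("Sigma must be positive definite")
    q = CHI2_95_2DF
    area = math.pi * q * math.sqrt(float(np.linalg.det(Sigma)))
    major = math.sqrt(q * evals[1])
    minor = math.sqrt(q * evals[0])
    orientation = math.atan2(evecs[1, 1], evecs[0, 1])
    return Ellipse(area=area, semi_axes=(major, minor), orientation=orientation)


def autocovariance(J: np.ndarray, Sigma: np.ndarray, lag: float) -> np.ndarray:
    """Lagged autocovariance C(lag) = exp(J lag) Sigma of the OU deviations.

    Defined for lag >= 0 (deviations propagated forward); C(-lag) = C(lag)'.
    """
    J = np.asarray(J, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if lag < 0:
        return autocovariance(J, Sigma, -lag).T
    return expm(J * lag) @ Sigma


def autocorrelation(J: np.ndarray, Sigma: np.ndarray, lag: float) -> np.ndarray:
    """Per-variable normalized ACF: entry (i, j) is C_ij(lag)/sqrt(S_ii S_jj)."""
    Sigma = np.asarray(Sigma, dtype=float)
    C = autocovariance(J, Sigma, lag)
    scale = np.sqrt(np.outer(np.diag(Sigma), np.diag(Sigma)))
    return C / scale


@dataclass(frozen=True)
class FluctuationSummary:
    """Stationary second-moment summary of the linearized fluctuations."""

    Sigma: np.ndarray
    gen_var: float
    ellipse_area_95: float
    acf: Callable[[float], np.ndarray]


def fluctuation_summary(params: ModelParams, eq: Equilibrium) -> FluctuationSummary:
    """Full linear-noise summary at an equilibrium of the SIR model."""
    J = jacobian(params, eq)
    B = diffusion_matrix(params, eq.state)
    Sigma = stationary_covariance(J, B)
    return FluctuationSummary(
        Sigma=Sigma,
        gen_var=generalized_variance(Sigma),
        ellipse_area_95=ellipse_95(Sigma).area,
        acf=lambda lag: autocovariance(J, Sigma, lag),
    )


SCAN_COLUMNS = [
    "nu",
    "var_S",
    "var_I",
    "cov_SI",
    "gen_var",
    "ellipse_area",
    "re_lambda",
    "im_lambda",
]


def variance_scan(params: ModelParams, nu_grid: Sequence[float]) -> pd.DataFrame:
    """Fluctuation summaries on a grid of vaccine-uptake values.

    Uses the sparked equilibrium when eta > 0 and the endemic (or, above
    threshold, disease-free) equilibrium otherwise.  Grid points whose
    equilibrium is not strictly stable are flagged (``stable`` False, NaN
    statistics) rather than computed.

    Returns a DataFrame with one row per nu: variances and covariance of the
    (S, I) deviations, the generalized variance, the 95%-ellipse area, and
    the dominant eigenvalue split into real and imaginary parts.
    """
    rows = []
    for nu in nu_grid:
        if not 0.0 <= nu < 1.0:
            raise ValueError("nu grid must lie within [0, 1)")
        p = params.with_nu(nu)
        if p.eta > 0:
            eq = sparked_equilibrium(p)
        elif p.control > 1.0:
            eq = endemic_equilibrium(p)
        else:
            eq = disease_free_equilibrium(p)
        rep = stability(p, eq)
        lam = rep.dominant
        row = {"nu": nu, "re_lambda": lam.real, "im_lambda": lam.imag, "stable": rep.stable}
        if rep.stable and max(e.real for e in rep.eigenvalues) < 0:
            Sigma = stationary_covariance(rep.J, diffusion_matrix(p, eq.state))
            row.update(
                var_S=Sigma[0, 0],
                var_I=Sigma[1, 1],
                cov_SI=Sigma[0, 1],
                gen_var=generalized_variance(Sigma),
                ellipse_area=ellipse_95(Sigma).area,
            )
        else:
            row["stable"] = False
            row.update({k: math.nan for k in ("var_S", "var_I", "cov_SI", "gen_var", "ellipse_area")})
        rows.append(row)
    return pd.DataFrame(rows, columns=SCAN_COLUMNS + ["stable"])
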