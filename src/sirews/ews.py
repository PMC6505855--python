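"""Early-warning indicators estimated from (S, I) time series.

Critical slowing down near the immunization threshold leaves statistical
fingerprints in incidence-like series: rising or peaking variances, rising
lag-autocorrelation, lengthening oscillation periods, and shrinking recovery
rates.  This module estimates those indicators from sampled trajectories:

* rolling-window variances, covariance and generalized variance;
* rolling-window lag-autocorrelation of S and I;
* a damped-cosine fit to an empirical or theoretical ACF, yielding the
  damping rate and angular frequency — estimates of -Re(lambda) and
  Im(lambda) of the dominant Jacobian eigenvalues;
* the recovery rate, the slope of log oscillation amplitude against time in
  a deterministic relaxation;
* inversion of the eigenvalue-modulus relation det(J) = mu (mu+gamma)
  (R0(1-nu) - 1) to turn (damping, frequency) into a distance-to-threshold
  estimate.

Deviations are taken about the window mean (no smoothing): the linearized
theory is near-stationary on windows short relative to the uptake trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .model import Equilibrium
from .simulate import TimeSeries

__all__ = [
    "EWS_COLUMNS",
    "windowed_moments",
    "windowed_acf",
    "ews_table",
    "empirical_acf",
    "fit_damped_oscillation",
    "RecoveryRateEstimate",
    "recovery_rate",
    "distance_to_threshold",
]

#: Column order of the indicator tables written to CSV.
EWS_COLUMNS = [
    "window_center",
    "var_S",
    "var_I",
    "gen_var",
    "acf_S",
    "acf_I",
    "damping",
    "frequency",
]

DEFAULT_WINDOW = 10.0  # years; exceeds the correlation time except very near threshold
DEFAULT_STRIDE = 1.0  # years
DEFAULT_LAG = 1.0  # years


def _sample_dt(series: TimeSeries) -> float:
    dt = np.diff(series.t)
    if dt.size == 0:
        raise ValueError("series has fewer than two samples")
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("windowed estimators require a regular sampling grid")
    return float(dt[0])


def _windows(series: TimeSeries, window: float, stride: float) -> list[tuple[int, int]]:
    dt = _sample_dt(series)
    w = int(round(window / dt))
    s = max(int(round(stride / dt)), 1)
    if w > len(series):
        raise ValueError("window longer than the series")
    if w < 10:
        raise ValueError("window must contain at least 10 samples")
    return [(i, i + w) for i in range(0, len(series) - w + 1, s)]


def windowed_moments(
    series: TimeSeries,
    window: float = DEFAULT_WINDOW,
    stride: float = DEFAULT_STRIDE,
) -> pd.DataFrame:
    """Rolling-window second moments of the (S, I) deviations.

    Per window: Var(S), Var(I), their covariance, and the generalized
    variance (determinant of the 2x2 sample covariance), with deviations
    taken about the window mean.  Returns one row per window, indexed by the
    window-center time.
    """
    rows = []
    for i, j in _windows(series, window, stride):
        x = np.stack([series.S[i:j], series.I[i:j]]).astype(float)
        cov = np.cov(x, ddof=1)
        rows.append(
            {
                "window_center": 0.5 * (series.t[i] + series.t[j - 1]),
                "var_S": cov[0, 0],
                "var_I": cov[1, 1],
                "cov_SI": cov[0, 1],
                "gen_var": float(np.linalg.det(cov)),
            }
        )
    return pd.DataFrame(rows)


def _lag_corr(x: np.ndarray, k: int) -> float:
    """Lag-k autocorrelation of a 1-d array about its mean (biased normalizer)."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return math.nan
    if k == 0:
        return 1.0
    return float(np.dot(x[:-k], x[k:]) / denom)


def windowed_acf(
    series: TimeSeries,
    window: float = DEFAULT_WINDOW,
    lag: float = DEFAULT_LAG,
    stride: float = DEFAULT_STRIDE,
) -> pd.DataFrame:
    """Rolling-window lag-autocorrelation of S and I.

    The requested lag is interpolated linearly between the two neighbouring
    multiples of the sampling interval.  Windows with too few samples at the
    lag are flagged with NaN.  Requires lag < window / 4.
    """
    dt = _sample_dt(series)
    if not lag < window / 4:
        raise ValueError("lag must be shorter than a quarter window")
    k_lo = int(math.floor(lag / dt))
    k_hi = int(math.ceil(lag / dt))
    frac = 0.0 if k_hi == k_lo else (lag / dt - k_lo) / (k_hi - k_lo)
    rows = []
    for i, j in _windows(series, window, stride):
        n = j - i
        row = {"window_center": 0.5 * (series.t[i] + series.t[j - 1])}
        for name, x in (("acf_S", series.S[i:j]), ("acf_I", series.I[i:j])):
            if k_hi >= n - 1:
                row[name] = math.nan
                continue
            lo = _lag_corr(np.asarray(x, dtype=float), k_lo)
            hi = _lag_corr(np.asarray(x, dtype=float), k_hi)
            row[name] = (1.0 - frac) * lo + frac * hi
        rows.append(row)
    return pd.DataFrame(rows)


def empirical_acf(x: np.ndarray, dt: float, max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Empirical autocorrelation of a series on lags 0, dt, ..., max_lag.

    Deviations are taken about the series mean; the biased normalizer (divide
    by the lag-0 sum of squares) keeps |acf| <= 1.
    """
    x = np.asarray(x, dtype=float)
    kmax = int(round(max_lag / dt))
    if kmax >= x.size:
        raise ValueError("max_lag must be shorter than the series")
    vals = np.array([_lag_corr(x, k) for k in range(kmax + 1)])
    return np.arange(kmax + 1) * dt, vals


def ews_table(
    series: TimeSeries,
    window: float = DEFAULT_WINDOW,
    stride: float = DEFAULT_STRIDE,
    lag: float = DEFAULT_LAG,
    fit_acf: bool = False,
    fit_max_lag: float | None = None,
) -> pd.DataFrame:
    """Combined indicator track: moments, lag-ACF and optional ACF fits.

    One row per window with the columns of :data:`EWS_COLUMNS`.  When
    ``fit_acf`` is on, each window's empirical ACF of I (out to
    ``fit_max_lag``, default a quarter window) is fitted with a damped
    cosine; windows where the fit fails get NaN damping/frequency.
    """
    moments = windowed_moments(series, window, stride)
    acf = windowed_acf(series, window, lag, stride)
    table = moments.merge(acf, on="window_center")
    damping = np.full(len(table), np.nan)
    frequency = np.full(len(table), np.nan)
    if fit_acf:
        dt = _sample_dt(series)
        max_lag = fit_max_lag if fit_max_lag is not None else window / 4.0
        for r, (i, j) in enumerate(_windows(series, window, stride)):
            try:
                lags, vals = empirical_acf(np.asarray(series.I[i:j], float), dt, max_lag)
                damping[r], frequency[r] = fit_damped_oscillation(lags, vals)
            except (ValueError, RuntimeError):
                pass
    table["damping"] = damping
    table["frequency"] = frequency
    return table[EWS_COLUMNS + ["cov_SI"]]


# ---------------------------------------------------------------------------
# Damped-oscillation fitting and threshold inversion
# ---------------------------------------------------------------------------

def fit_damped_oscillation(
    lags: np.ndarray,
    values: np.ndarray,
    n_starts: int = 8,
) -> tuple[float, float]:
    """Fit a damped cosine A exp(-a l) cos(w l + phi) to ACF values.

    Returns ``(damping, frequency)`` = (a, w), estimating (|Re lambda|,
    Im lambda) of the dominant eigenvalue pair.  The fit is nonlinear least
    squares with multiple starts: w is initialized from the first zero
    crossing of the ACF (w ~ pi / (2 l_zero)) and from harmonically related
    guesses, phi over a coarse grid; ties go to the lowest residual, then
    the lowest frequency.  A frequency estimate collapsing to ~0 signals an
    overdamped (pure-exponential) ACF.

    Requires at least 8 lag points spanning at least one putative period.
    """
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if lags.size < 8:
        raise ValueError("need at least 8 lag points")
    span = lags.max() - lags.min()

    # frequency scale from the first sign change, if any
    sign_change = np.nonzero(np.diff(np.signbit(values)))[0]
    if sign_change.size:
        l0 = lags[sign_change[0] + 1]
        w_base = math.pi / (2.0 * l0) if l0 > 0 else math.pi / span
    else:
        w_base = math.pi / span  # no crossing: at most half a cycle visible
    w_starts = [0.0, 0.5 * w_base, w_base, 2.0 * w_base, 3.0 * w_base]
    phi_starts = [0.0, math.pi / 2, -math.pi / 2]
    a0 = max(1.0 / span, 1e-3)

    def resid(theta: np.ndarray) -> np.ndarray:
        A, a, w, phi = theta
        return A * np.exp(-a * lags) * np.cos(w * lags + phi) - values

    best: tuple[float, float, float] | None = None  # (cost, a, w)
    for w0 in w_starts:
        for phi0 in phi_starts:
            try:
                sol = least_squares(
                    resid,
                    x0=[max(abs(values[0]), 0.1), a0, w0, phi0],
                    bounds=([0.0, 0.0, 0.0, -math.pi], [np.inf, np.inf, np.inf, math.pi]),
                    max_nfev=2000,
                )
            except Exception:
                continue
            if not sol.success and sol.status <= 0:
                continue
            cost, a, w = sol.cost, abs(sol.x[1]), abs(sol.x[2])
            if best is None or cost < best[0] - 1e-12 or (
                abs(cost - best[0]) <= 1e-12 and w < best[2]
            ):
                best = (cost, a, w)
    if best is None:
        raise RuntimeError("damped-oscillation fit did not converge from any start")
    return best[1], best[2]


@dataclass(frozen=True)
class RecoveryRateEstimate:
    """Slope of log oscillation amplitude vs time, with supporting peaks."""

    lambda_hat: float
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray


def recovery_rate(series: TimeSeries, equilibrium: Equilibrium) -> RecoveryRateEstimate:
    """Recovery rate lambda = d ln r / dt of a deterministic relaxation.

    r is the amplitude of the oscillation of (I - I*)/N: successive local
    maxima of |I - I*| are extracted (with quadratic interpolation around
    each discrete peak; plateaus take the leftmost point) and log amplitude
    is regressed on peak time.  The slope estimates Re(lambda) of the
    dominant eigenvalues and is negative for a decaying oscillation.

    Requires at least 3 peaks.
    """
    dev = np.abs(np.asarray(series.I, dtype=float) - equilibrium.I_star)
    idx, props = find_peaks(dev, plateau_size=(1, None))
    idx = props["left_edges"]  # plateaus take the leftmost point
    if idx.size < 3:
        raise ValueError(f"need at least 3 oscillation peaks, found {idx.size}")
    times = np.empty(idx.size)
    amps = np.empty(idx.size)
    dt = float(series.t[1] - series.t[0])
    for m, i in enumerate(idx):
        y0, y1, y2 = dev[i - 1], dev[i], dev[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper quadratic maximum
            shift = 0.5 * (y0 - y2) / denom
            times[m] = series.t[i] + shift * dt
            amps[m] = y1 - 0.25 * (y0 - y2) * shift
        else:
            times[m] = series.t[i]
            amps[m] = y1
    slope, _ = np.polyfit(times, np.log(amps), 1)
    return RecoveryRateEstimate(
        lambda_hat=float(slope), peak_times=times, peak_amplitudes=amps
    )


def distance_to_threshold(
    damping: float, frequency: float, mu: float, gamma: float
) -> float:
    """Distance of the control parameter R0(1 - nu) from its critical value 1.

    Inverts the eigenvalue-modulus relation |lambda|^2 = det(J) =
    mu (mu + gamma) (R0(1-nu) - 1), giving

        R0(1 - nu) - 1 = (damping^2 + frequency^2) / (mu (mu + gamma)).

    Valid for underdamped estimates (frequency > 0); a nonpositive result
    means the system is at or below the threshold.
    """
    if frequency <= 0:
        raise ValueError("distance inversion requires an underdamped (frequency > 0) estimate")
    return (damping**2 + frequency**2) / (mu * (mu + gamma))
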