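"""CSV round-tripping for time series and validated run configuration.

Time series travel as plain CSV with header ``t,S,I,nu`` (comma separated,
UTF-8, '.' decimal); run metadata goes in a YAML sidecar so every stochastic
artifact can be regenerated from its logged parameters and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams
from .simulate import DEFAULT_SAMPLE_DT, TimeSeries, VaccineSchedule

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "RunConfig",
    "load_config",
]

TIMESERIES_COLUMNS = ["t", "S", "I", "nu"]


class TimeSeriesParseError(ValueError):
    """A time-series CSV violated the format contract."""


def write_timeseries(series: TimeSeries, path: str | Path, meta_sidecar: bool = True) -> None:
    """Write a series as CSV (t,S,I,nu) plus an optional YAML meta sidecar.

    Floats are printed with 15 significant digits, so a round trip is
    lossless to 12 significant digits.
    """
    path = Path(path)
    series.to_frame().to_csv(path, index=False, float_format="%.15g")
    if meta_sidecar and series.meta:
        meta = {}
        for key, value in series.meta.items():
            if isinstance(value, ModelParams):
                meta[key] = asdict(value)
            elif isinstance(value, VaccineSchedule):
                meta[key] = {k: v for k, v in asdict(value).items() if v is not None}
            elif isinstance(value, np.ndarray):
                meta[key] = value.tolist()
            else:
                meta[key] = value
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(meta, sort_keys=False)
        )


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a t,S,I,nu CSV back into a :class:`TimeSeries`.

    Raises :class:`TimeSeriesParseError` for a missing column, an empty
    series, non-monotone times or negative counts.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in frame.columns]
    if missing:
        raise TimeSeriesParseError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(frame) == 0:
        raise TimeSeriesParseError(f"{path}: empty series (header only)")
    t = frame["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise TimeSeriesParseError(f"{path}: sample times not strictly increasing")
    S = frame["S"].to_numpy(dtype=float)
    I = frame["I"].to_numpy(dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise TimeSeriesParseError(f"{path}: negative counts")
    meta: dict[str, Any] = {"source": str(path)}
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if sidecar.exists():
        meta.update(yaml.safe_load(sidecar.read_text()) or {})
    return TimeSeries(t=t, S=S, I=I, nu=frame["nu"].to_numpy(dtype=float), meta=meta)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

PARAM_KEYS = {"b", "mu", "gamma", "eta", "nu", "R0", "infectious_period_days"}
SCHEDULE_KEYS = {"mode", "nu0", "ramp_rate", "ramp_start", "breakpoints"}
SIMULATION_KEYS = {"method", "T", "dt", "sample_dt", "seed", "replicates"}
EWS_KEYS = {"window", "stride", "lag"}
TOP_KEYS = {"params", "schedule", "simulation", "ews", "output"}

STOCHASTIC_METHODS = {"gillespie", "euler_maruyama"}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of model, schedule, simulation and EWS settings."""

    params: ModelParams
    schedule: VaccineSchedule
    method: str = "gillespie"
    T: float = 50.0
    dt: float = 1.0 / 365.0
    sample_dt: float = DEFAULT_SAMPLE_DT
    seed: int | None = None
    replicates: int = 1
    window: float = 10.0
    stride: float = 1.0
    lag: float = 1.0
    output: str | None = None


def _reject_unknown(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {name}: {', '.join(sorted(unknown))}")


def load_config(source: str | Path | dict) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or an equivalent dict.

    Unknown keys are rejected.  ``gamma`` may be given directly as a rate or
    via ``infectious_period_days`` (stored as the rate 365/days).  A seed is
    mandatory for the stochastic methods.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _reject_unknown(raw, TOP_KEYS, "config")

    psec = dict(raw.get("params", {}))
    _reject_unknown(psec, PARAM_KEYS, "params")
    if "infectious_period_days" in psec:
        if "gamma" in psec:
            raise ValueError("give gamma or infectious_period_days, not both")
        psec["gamma"] = 365.0 / float(psec.pop("infectious_period_days"))
    params = ModelParams(**{k: float(v) for k, v in psec.items()})

    ssec = dict(raw.get("schedule", {"mode": "constant", "nu0": params.nu}))
    _reject_unknown(ssec, SCHEDULE_KEYS, "schedule")
    if "breakpoints" in ssec and ssec["breakpoints"] is not None:
        ssec["breakpoints"] = tuple(tuple(bp) for bp in ssec["breakpoints"])
    schedule = VaccineSchedule(**ssec)

    sim = dict(raw.get("simulation", {}))
    _reject_unknown(sim, SIMULATION_KEYS, "simulation")
    ews = dict(raw.get("ews", {}))
    _reject_unknown(ews, EWS_KEYS, "ews")

    method = sim.get("method", "gillespie")
    seed = sim.get("seed")
    if method in STOCHASTIC_METHODS and seed is None:
        raise ValueError(f"method {method!r} is stochastic: a seed is mandatory")

    return RunConfig(
        params=params,
        schedule=schedule,
        method=method,
        T=float(sim.get("T", 50.0)),
        dt=float(sim.get("dt", 1.0 / 365.0)),
        sample_dt=float(sim.get("sample_dt", DEFAULT_SAMPLE_DT)),
        seed=None if seed is None else int(seed),
        replicates=int(sim.get("replicates", 1)),
        window=float(ews.get("window", 10.0)),
        stride=float(ews.get("stride", 1.0)),
        lag=float(ews.get("lag", 1.0)),
        output=raw.get("output"),
    )
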