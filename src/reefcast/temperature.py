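"""Seasonal + linear-trend sea-surface temperature model.

The SST driving the coral dynamics is modelled as a single annual harmonic
(irradiance-driven seasonality) superimposed on a linear warming trend:

    T(t) = I_ave * (a1*cos(2*pi*(t - t0)) + a2*sin(2*pi*(t - t0)))
           + lam*(t - t0) + a3

with t in fractional calendar years.  ``lam`` (degC per year) is the
climate-change coefficient: the rate of background ocean warming under a
given emissions scenario.  ``a3`` is the annual-mean SST where the trend is
zero, and ``I_ave`` (annual-average photosynthetically available radiation,
treated as a dimensionless scalar multiplier, default 45) couples the
seasonal harmonic amplitudes ``a1``/``a2`` to temperature.

The seasonal argument uses 2*pi*(t - t0) so the period is exactly one year.

Scenario coefficient sets for the Representative Concentration Pathways
(modern / RCP 4.5 / RCP 6.0 / RCP 8.5) ship with the package; their trend
term is anchored at calendar year zero (t0 = 0), which is the only origin
under which their a3 intercepts yield tropical SSTs (~25-26 degC) over the
2005-2100 simulation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError, InvalidInputError, MalformedSeriesError, UnderdeterminedFitError

__all__ = [
    "TemperatureModel",
    "SstSeries",
    "sst_at",
    "fit_sst_model",
    "scenario_model",
    "SCENARIOS",
    "I_AVE_DEFAULT",
]

#: Annual-average irradiance multiplier used in all scenario runs.
I_AVE_DEFAULT = 45.0


@dataclass(frozen=True)
class TemperatureModel:
    """Coefficients of the seasonal-plus-trend SST curve.

    Parameters
    ----------
    i_ave : float
        Annual-average irradiance (PAR), a dimensionless scalar multiplier
        on the seasonal harmonic.
    a1, a2 : float
        Irradiance-to-temperature rates (degC/PAR) for the cosine and sine
        components of the annual cycle.
    a3 : float
        Annual-mean SST offset (degC) at the trend origin.
    lam : float
        Climate-change coefficient (degC / year); linear warming rate.
    t0 : float
        Calendar year at which the linear trend is zero.
    """

    i_ave: float = I_AVE_DEFAULT
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 25.0
    lam: float = 0.0
    t0: float = 2005.0

    def __post_init__(self) -> None:
        for name in ("i_ave", "a1", "a2", "a3", "lam", "t0"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidInputError(f"TemperatureModel.{name} must be finite")

    def __call__(self, t):
        return sst_at(self, t)

    def annual_mean(self, year: float) -> float:
        """Mean SST over the calendar year starting at ``year``.

        The harmonic integrates to zero over a whole period, leaving the
        trend evaluated at mid-year plus the offset.
        """
        return self.lam * (year + 0.5 - self.t0) + self.a3

    def with_lambda(self, lam: float) -> "TemperatureModel":
        return replace(self, lam=lam)


# Scenario coefficient table: (a1, a2, a3, lam), trend origin at year 0.
# "modern" has no trend, so its a3 is the observed annual mean directly.
SCENARIOS: dict[str, tuple[float, float, float, float]] = {
    "modern": (-0.003, 0.001, 25.49, 0.0),
    "rcp45": (-0.0001, 0.00013, -4.81, 0.015),
    "rcp60": (0.00002, -0.00005, -16.06, 0.021),
    "rcp85": (-0.00006, 0.00002, -52.08, 0.039),
}


def scenario_model(rcp: str, i_ave: float = I_AVE_DEFAULT) -> TemperatureModel:
    """Return the packaged SST model for an RCP scenario label.

    ``rcp`` is one of ``modern``, ``rcp45``, ``rcp60``, ``rcp85``.  The
    returned model uses a calendar-year-zero trend origin (see module notes).
    """
    key = rcp.lower().replace(" ", "").replace(".", "").replace("_", "")
    if key not in SCENARIOS:
        from .errors import ConfigurationError

        raise ConfigurationError(
            f"unknown scenario {rcp!r}; expected one of {sorted(SCENARIOS)}"
        )
    a1, a2, a3, lam = SCENARIOS[key]
    return TemperatureModel(i_ave=i_ave, a1=a1, a2=a2, a3=a3, lam=lam, t0=0.0)


def sst_at(model: TemperatureModel, t):
    """Evaluate SST (degC) at fractional calendar year(s) ``t``.

    Accepts scalars or arrays; raises :class:`InvalidInputError` on
    non-finite input.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise InvalidInputError("time must be finite")
    phase = 2.0 * np.pi * (t_arr - model.t0)
    out = (
        model.i_ave * (model.a1 * np.cos(phase) + model.a2 * np.sin(phase))
        + model.lam * (t_arr - model.t0)
        + model.a3
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class SstSeries:
    """Monthly SST observations as (fractional year, degC) pairs."""

    times: np.ndarray
    sst: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sst, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise MalformedSeriesError("times and sst must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise MalformedSeriesError("times must be strictly increasing")
        if s.size and (np.any(s <= -5.0) or np.any(s >= 45.0)):
            raise MalformedSeriesError("SST values outside (-5, 45) degC")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sst", s)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_csv(cls, path) -> "SstSeries":
        """Read a monthly SST table with columns ``date`` (yyyy-mm) and ``sst_c``.

        Times are placed at month centres in fractional years.
        """
        df = pd.read_csv(path)
        missing = {"date", "sst_c"} - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing column(s) {sorted(missing)}")
        try:
            period = pd.PeriodIndex(df["date"].astype(str), freq="M")
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise DataError(f"{path}: unparseable date column ({exc})") from exc
        times = period.year.to_numpy() + (period.month.to_numpy() - 0.5) / 12.0
        return cls(times=times, sst=df["sst_c"].to_numpy(dtype=float))


def fit_sst_model(
    series: SstSeries,
    fix_lambda: float | None = None,
    t0: float = 2005.0,
    i_ave: float = I_AVE_DEFAULT,
) -> tuple[TemperatureModel, float]:
    """Least-squares fit of the SST curve to a monthly series.

    The model is linear in (i_ave*a1, i_ave*a2, lam, a3) once ``t0`` is
    fixed, so the fit is an exact ordinary-least-squares solve.  Returns the
    fitted :class:`TemperatureModel` and the residual RMSE (degC).

    Parameters
    ----------
    fix_lambda : float, optional
        Hold the warming trend fixed at this value instead of estimating it.
    """
    n = len(series)
    n_free = 3 if fix_lambda is not None else 4
    if n < n_free:
        raise UnderdeterminedFitError(f"{n} points cannot constrain {n_free} parameters")
    if n < 24:
        raise UnderdeterminedFitError(
            f"need at least 24 monthly points to separate seasonality from trend (got {n})"
        )
    tt = series.times - t0
    phase = 2.0 * np.pi * tt
    cols = [i_ave * np.cos(phase), i_ave * np.sin(phase), np.ones(n)]
    y = series.sst.astype(float).copy()
    if fix_lambda is None:
        cols.insert(2, tt)
    else:
        y = y - fix_lambda * tt
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    if fix_lambda is None:
        a1, a2, lam, a3 = coef
    else:
        a1, a2, a3 = coef
        lam = fix_lambda
    model = TemperatureModel(i_ave=i_ave, a1=a1, a2=a2, a3=a3, lam=lam, t0=t0)
    rmse = float(np.sqrt(np.mean((sst_at(model, series.times) - series.sst) ** 2)))
    return model, rmse
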