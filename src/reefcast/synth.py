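"""Synthetic-data generators.

Real coral-cover recovery series and ONI anomaly tables are small and often
not redistributable, so the package ships generators that emulate their
statistical structure:

* :func:`generate_synthetic_cover` - a logistic recovery toward K with
  lag-1 autoregressive observation noise and (optionally) one abrupt
  bleaching-style multiplicative drop, the shape of observed post-1998
  recovery records.
* :func:`generate_synthetic_oni` - a sub-threshold noise baseline with
  triangular warm-anomaly pulses at specified (start, length, peak)
  positions, so the event classifier has an exact constructed ground truth.

Both are pure functions of their random generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .events import MIN_EVENT_SEASONS, OniSeries

__all__ = ["generate_synthetic_cover", "generate_synthetic_oni", "OniEventSpec"]


def generate_synthetic_cover(
    r: float,
    K: float,
    p0: float,
    rho: float,
    sigma: float,
    n_years: int,
    rng: np.random.Generator,
    bleach_year: int | None = None,
    bleach_survival_fraction: float = 1.0,
    year0: int = 1997,
) -> pd.DataFrame:
    """Simulate an annual percent-cover series.

    The noiseless path is the logistic solution from ``p0``; at
    ``bleach_year`` (an offset in years from the series start) the
    underlying cover is multiplied by ``bleach_survival_fraction`` and the
    logistic recovery restarts from the survivor level.  AR(1) Gaussian
    noise (coefficient ``rho``, innovation SD ``sigma``) is added on top and
    the result clamped to (0.1, 100) so covers stay usable as percentages.

    Returns a DataFrame with columns ``year`` and ``cover_pct``.
    """
    if not (0 < K <= 100 and 0 < p0 <= K and r >= 0):
        raise ConfigurationError("require 0 < K <= 100, 0 < p0 <= K, r >= 0")
    if not (0.0 < bleach_survival_fraction <= 1.0):
        raise ConfigurationError("bleach_survival_fraction must be in (0, 1]")
    if not (-1.0 < rho < 1.0) or sigma < 0:
        raise ConfigurationError("require |rho| < 1 and sigma >= 0")
    if bleach_year is not None and not (0 < bleach_year < n_years):
        raise ConfigurationError("bleach_year must fall inside the series")

    def logistic(p_start: float, t: np.ndarray) -> np.ndarray:
        ert = np.exp(r * t)
        return K * p_start * ert / (K + p_start * (ert - 1.0))

    t = np.arange(n_years, dtype=float)
    if bleach_year is None:
        mu = logistic(p0, t)
    else:
        mu = np.empty(n_years)
        pre = t[: bleach_year + 1]
        mu[: bleach_year + 1] = logistic(p0, pre)
        survivor = mu[bleach_year] * bleach_survival_fraction
        post = t[bleach_year:] - t[bleach_year]
        mu[bleach_year:] = logistic(survivor, post)

    e = np.zeros(n_years)
    if sigma > 0:
        e[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - rho**2))
        for i in range(1, n_years):
            e[i] = rho * e[i - 1] + rng.normal(0.0, sigma)
    cover = np.clip(mu + e, 0.1, 100.0)
    return pd.DataFrame({"year": year0 + np.arange(n_years), "cover_pct": cover})


@dataclass(frozen=True)
class OniEventSpec:
    """Ground truth for one synthetic warm event.

    ``start`` is a flat season index from the series start, ``length`` the
    number of consecutive seasons (>= 5), ``peak`` the peak anomaly (degC).
    """

    start: int
    length: int
    peak: float

    def __post_init__(self) -> None:
        if self.length < MIN_EVENT_SEASONS:
            raise ConfigurationError(f"event length must be >= {MIN_EVENT_SEASONS} seasons")
        if self.peak < 0.5:
            raise ConfigurationError("peak must be >= 0.5 degC to qualify as an event")
        if self.start < 0:
            raise ConfigurationError("start must be non-negative")


def generate_synthetic_oni(
    event_specs: Sequence[OniEventSpec | tuple],
    n_years: int,
    noise_sd: float,
    rng: np.random.Generator,
    year0: int = 1950,
) -> OniSeries:
    """Build an ONI series whose events are known by construction.

    Outside events the anomaly is Normal(0, noise_sd) truncated below
    0.4 degC (so noise can never create or extend an event).  Inside an
    event the anomaly follows a triangular pulse from 0.5 degC at the edges
    to the specified peak, guaranteeing every in-event season is at or above
    threshold.  With ``noise_sd <= 0.1`` the classifier recovers exactly the
    specified events.
    """
    specs = [s if isinstance(s, OniEventSpec) else OniEventSpec(*s) for s in event_specs]
    n_seasons = n_years * 12
    specs.sort(key=lambda s: s.start)
    prev_end = -1
    for s in specs:
        if s.start <= prev_end + 1:  # adjacent events would merge into one run
            raise ConfigurationError("event specs overlap or touch")
        if s.start + s.length > n_seasons:
            raise ConfigurationError("event spec extends past the series end")
        prev_end = s.start + s.length - 1

    anoms = rng.normal(0.0, noise_sd, size=n_seasons) if noise_sd > 0 else np.zeros(n_seasons)
    np.clip(anoms, -4.99, 0.39, out=anoms)
    for s in specs:
        i = np.arange(s.length)
        half = (s.length - 1) / 2.0
        shape = 1.0 - np.abs(i - half) / (half + 1.0)
        shape /= shape.max()  # the pulse attains the specified peak exactly
        anoms[s.start : s.start + s.length] = 0.5 + (s.peak - 0.5) * shape

    flat = np.arange(n_seasons)
    return OniSeries(years=year0 + flat // 12, seasons=flat % 12, anomalies=anoms)
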