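"""El Nino classification and stochastic thermal-stress schedules.

Two concerns live here.  First, the historical side: the Oceanic Nino Index
(ONI, the running 3-month SST anomaly for the Nino 3.4 region) is scanned
for El Nino events - five or more consecutive overlapping seasons at or
above the +0.5 degC anomaly - which are then binned by peak anomaly into
weak (0.5-0.9), moderate (1.0-1.4), strong (1.5-1.9) and very strong
(>= 2.0 degC) categories, and summarized by their return periods.

Second, the forward side: simulated futures draw event schedules whose
inter-event gaps come from a Poisson distribution rejected outside
configured bounds (default 3-9 years, mean 6 - the historical return range
of weak-to-strong events; very strong events are too rare over a
century-scale horizon to schedule) and whose anomaly durations come from a
gamma distribution rejected outside 2-8 weeks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    InsufficientEventsError,
    InvalidInputError,
    MalformedSeriesError,
)

__all__ = [
    "SEASONS",
    "EventCategory",
    "OniSeries",
    "ElNinoEvent",
    "ThermalEvent",
    "ScheduleConfig",
    "EventSchedule",
    "PeriodicityStats",
    "read_oni",
    "classify_enso_events",
    "periodicity_stats",
    "draw_schedule",
    "draw_interval",
    "draw_duration",
]

#: NOAA's twelve overlapping 3-month seasons, in calendar order.  DJF is
#: centred on January of the labelled year.
SEASONS = ("DJF", "JFM", "FMA", "MAM", "AMJ", "MJJ", "JJA", "JAS", "ASO", "SON", "OND", "NDJ")

ONSET_THRESHOLD_C = 0.5
MIN_EVENT_SEASONS = 5


class EventCategory(enum.IntEnum):
    """El Nino strength class; ordering supports >= comparisons."""

    weak = 1
    moderate = 2
    strong = 3
    very_strong = 4

    @classmethod
    def from_peak(cls, peak: float) -> "EventCategory":
        # category boundaries are closed on the left
        if peak >= 2.0:
            return cls.very_strong
        if peak >= 1.5:
            return cls.strong
        if peak >= 1.0:
            return cls.moderate
        if peak >= ONSET_THRESHOLD_C:
            return cls.weak
        raise InvalidInputError(f"peak anomaly {peak} below event threshold")


@dataclass(frozen=True)
class OniSeries:
    """Contiguous ONI records: parallel arrays of year, season index, anomaly."""

    years: np.ndarray
    seasons: np.ndarray  # 0..11 indices into SEASONS
    anomalies: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.years, dtype=int)
        s = np.asarray(self.seasons, dtype=int)
        a = np.asarray(self.anomalies, dtype=float)
        if not (y.shape == s.shape == a.shape) or y.ndim != 1 or y.size == 0:
            raise MalformedSeriesError("years/seasons/anomalies must be equal-length 1-D")
        idx = y * 12 + s
        if np.any(np.diff(idx) != 1):
            pos = int(np.argmax(np.diff(idx) != 1))
            raise MalformedSeriesError(
                f"season sequence not contiguous at record {pos + 1} "
                f"({y[pos]} {SEASONS[s[pos]]} -> {y[pos + 1]} {SEASONS[s[pos + 1]]})"
            )
        if np.any(np.abs(a) >= 5.0):
            raise MalformedSeriesError("anomalies outside (-5, 5) degC")
        object.__setattr__(self, "years", y)
        object.__setattr__(self, "seasons", s)
        object.__setattr__(self, "anomalies", a)

    def __len__(self) -> int:
        return self.years.size


def read_oni(path) -> OniSeries:
    """Read an ONI table, auto-detecting the dialect from the header.

    Accepts the NOAA-style wide layout (``YEAR`` plus twelve season columns
    ``DJF``..``NDJ``) or a tidy layout with columns ``year``, ``season``
    (season label or 1-12 index) and ``anomaly``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().upper(): c for c in df.columns}
    if "YEAR" in cols and all(s in cols for s in SEASONS):
        years, seasons, anoms = [], [], []
        for _, row in df.iterrows():
            for i, s in enumerate(SEASONS):
                val = row[cols[s]]
                if pd.isna(val):
                    continue
                years.append(int(row[cols["YEAR"]]))
                seasons.append(i)
                anoms.append(float(val))
        return OniSeries(np.array(years), np.array(seasons), np.array(anoms))
    if {"YEAR", "SEASON", "ANOMALY"} <= set(cols):
        season_col = df[cols["SEASON"]]
        if season_col.dtype.kind in "iuf":
            sidx = season_col.astype(int).to_numpy() - 1
        else:
            lookup = {s: i for i, s in enumerate(SEASONS)}
            try:
                sidx = np.array([lookup[str(v).strip().upper()] for v in season_col])
            except KeyError as exc:
                raise DataError(f"{path}: unknown season label {exc}") from exc
        return OniSeries(
            df[cols["YEAR"]].astype(int).to_numpy(),
            sidx,
            df[cols["ANOMALY"]].astype(float).to_numpy(),
        )
    raise DataError(
        f"{path}: header matches neither the NOAA wide layout (YEAR, DJF..NDJ) "
        f"nor the tidy layout (year, season, anomaly); got {list(df.columns)}"
    )


@dataclass(frozen=True)
class ElNinoEvent:
    """One classified warm event: a maximal run of >= 5 seasons at >= 0.5 degC."""

    start_year: int
    start_season: int
    end_year: int
    end_season: int
    peak_anomaly: float
    category: EventCategory

    @property
    def n_seasons(self) -> int:
        return (self.end_year * 12 + self.end_season) - (
            self.start_year * 12 + self.start_season
        ) + 1

    @property
    def start_time(self) -> float:
        """Fractional-year centre of the starting season."""
        return self.start_year + (self.start_season + 0.5) / 12.0


def classify_enso_events(oni: OniSeries) -> list[ElNinoEvent]:
    """Extract El Nino events from an ONI series.

    Maximal runs of at least five consecutive seasons with anomaly at or
    above 0.5 degC become events; the category comes from the run's peak
    anomaly.  Runs shorter than five seasons are discarded.
    """
    hot = oni.anomalies >= ONSET_THRESHOLD_C
    events: list[ElNinoEvent] = []
    i = 0
    n = len(oni)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        if j - i + 1 >= MIN_EVENT_SEASONS:
            peak = float(np.max(oni.anomalies[i : j + 1]))
            events.append(
                ElNinoEvent(
                    start_year=int(oni.years[i]),
                    start_season=int(oni.seasons[i]),
                    end_year=int(oni.years[j]),
                    end_season=int(oni.seasons[j]),
                    peak_anomaly=peak,
                    category=EventCategory.from_peak(peak),
                )
            )
        i = j + 1
    return events


@dataclass(frozen=True)
class PeriodicityStats:
    """Return-period summary of qualifying events (gaps in whole years)."""

    mean: float
    median: float
    sd: float
    n_events: int
    gaps: tuple[int, ...]


def periodicity_stats(
    events: Sequence[ElNinoEvent],
    min_category: EventCategory | str = EventCategory.weak,
) -> PeriodicityStats:
    """Mean/median/SD of start-to-start gaps between qualifying events.

    Gaps are differences of the events' starting calendar years, matching
    the convention of counting "years between the start of each event".
    ``min_category`` keeps only events at or above that strength.
    """
    if isinstance(min_category, str):
        min_category = EventCategory[min_category]
    starts = sorted(e.start_year for e in events if e.category >= min_category)
    if len(starts) < 2:
        raise InsufficientEventsError(
            f"need >= 2 events at or above {min_category.name}, got {len(starts)}"
        )
    gaps = np.diff(starts)
    sd = float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0
    return PeriodicityStats(
        mean=float(np.mean(gaps)),
        median=float(np.median(gaps)),
        sd=sd,
        n_events=len(starts),
        gaps=tuple(int(g) for g in gaps),
    )


@dataclass(frozen=True)
class ThermalEvent:
    """One acute thermal-stress anomaly in a simulated schedule.

    ``t_start`` is the onset in fractional calendar years, ``duration_weeks``
    the anomaly length, and ``eps`` the extreme-event coefficient: the
    intensity knob that drives mortality through f(eps) = -eps**3.
    """

    t_start: float
    duration_weeks: float
    eps: float

    def __post_init__(self) -> None:
        if self.duration_weeks <= 0 or self.eps < 0:
            raise InvalidInputError("duration must be positive and eps non-negative")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_weeks / 52.0


@dataclass(frozen=True)
class ScheduleConfig:
    """Sampling configuration for stochastic event schedules.

    Inter-event gaps (start-to-start, whole years) are Poisson(``mean_interval``)
    draws rejected outside [``interval_min``, ``interval_max``]; durations are
    gamma(``gamma_shape``, ``gamma_scale``) draws (weeks) rejected outside
    [``duration_min``, ``duration_max``].  ``eps`` is the intensity assigned
    to every event, and ``start_phase`` the within-year onset (0.5 =
    mid-summer).
    """

    interval_min: int = 3
    interval_max: int = 9
    mean_interval: float = 6.0
    duration_min: float = 2.0
    duration_max: float = 8.0
    gamma_shape: float = 2.0
    gamma_scale: float = 2.0
    eps: float = 3.0
    start_phase: float = 0.5

    def __post_init__(self) -> None:
        if self.interval_min < 1:
            raise ConfigurationError("interval_min must be >= 1 year")
        if not (0 < self.duration_min <= self.duration_max <= 52):
            raise ConfigurationError("duration bounds must satisfy 0 < min <= max <= 52 weeks")
        if not (self.interval_min <= self.mean_interval <= self.interval_max):
            raise ConfigurationError(
                "mean_interval must lie inside [interval_min, interval_max]; "
                "rejection sampling would loop otherwise"
            )
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ConfigurationError("gamma shape/scale must be positive")
        if not (0.0 <= self.start_phase < 1.0):
            raise ConfigurationError("start_phase must be in [0, 1)")

    def high_frequency(self) -> "ScheduleConfig":
        """The shortened-return-period variant (3-6 year intervals)."""
        return replace(self, interval_min=3, interval_max=6, mean_interval=4.5)


@dataclass(frozen=True)
class EventSchedule:
    """An ordered set of thermal events over a simulation horizon.

    ``config`` records the sampling configuration when the schedule came
    from :func:`draw_schedule`, in which case start-to-start gaps are
    validated against its interval bounds; hand-built schedules may pass
    ``config=None`` and are only checked for ordering and horizon.
    """

    events: tuple[ThermalEvent, ...]
    horizon: tuple[float, float]
    config: ScheduleConfig | None = None

    def __post_init__(self) -> None:
        start, end = self.horizon
        if end < start:
            raise ConfigurationError("horizon end before start")
        prev = None
        for ev in self.events:
            if not (start <= ev.t_start <= end):
                raise ConfigurationError(f"event at {ev.t_start} outside horizon {self.horizon}")
            if prev is not None:
                if ev.t_start <= prev.t_start:
                    raise ConfigurationError("events must be strictly ordered")
                gap = ev.t_start - prev.t_start
                if self.config is not None and not (
                    self.config.interval_min - 1e-9 <= gap <= self.config.interval_max + 1e-9
                ):
                    raise ConfigurationError(
                        f"start-to-start gap {gap} outside "
                        f"[{self.config.interval_min}, {self.config.interval_max}]"
                    )
            prev = ev

    def __len__(self) -> int:
        return len(self.events)

    def gaps(self) -> np.ndarray:
        starts = np.array([e.t_start for e in self.events])
        return np.diff(starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start": [e.t_start for e in self.events],
                "duration_weeks": [e.duration_weeks for e in self.events],
                "eps": [e.eps for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rejection_draw(draw, lo: float, hi: float, max_tries: int = 10_000) -> float:
    for _ in range(max_tries):
        x = draw()
        if lo <= x <= hi:
            return x
    raise ConfigurationError(
        f"rejection sampling failed to land in [{lo}, {hi}] after {max_tries} tries"
    )


def draw_interval(cfg: ScheduleConfig, rng: np.random.Generator) -> int:
    """One inter-event gap (years): Poisson(mean_interval) rejected outside bounds."""
    return int(
        _rejection_draw(
            lambda: int(rng.poisson(cfg.mean_interval)), cfg.interval_min, cfg.interval_max
        )
    )


def draw_duration(cfg: ScheduleConfig, rng: np.random.Generator) -> float:
    """One anomaly duration (weeks): gamma(shape, scale) rejected outside bounds."""
    return float(
        _rejection_draw(
            lambda: float(rng.gamma(cfg.gamma_shape, cfg.gamma_scale)),
            cfg.duration_min,
            cfg.duration_max,
        )
    )


def draw_schedule(
    cfg: ScheduleConfig,
    horizon: tuple[float, float],
    rng: np.random.Generator,
) -> EventSchedule:
    """Draw one stochastic event schedule over ``horizon``.

    The first event follows one sampled gap after the horizon start (the
    start itself is not an event year); events land at the configured
    within-year phase.  Fully reproducible from the supplied generator.
    """
    start, end = float(horizon[0]), float(horizon[1])
    if end < start:
        raise ConfigurationError("horizon end before start")
    events: list[ThermalEvent] = []
    t = start
    while True:
        t += draw_interval(cfg, rng)
        t_start = np.floor(t) + cfg.start_phase if cfg.start_phase else t
        if t_start > end:
            break
        dur = draw_duration(cfg, rng)
        events.append(ThermalEvent(t_start=float(t_start), duration_weeks=dur, eps=cfg.eps))
    return EventSchedule(events=tuple(events), horizon=(start, end), config=cfg)
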