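"""Raw GPS trace reduction to daily mobility summaries.

Converts per-day latitude/longitude traces into the two baseline mobility
variables used throughout the package:

* **DMA** — daily minutes spent away from home, i.e. total minutes per day a
  subject is beyond a fixed radius (default 500 m) around their home geocode.
* **MDR** — maximum daily radius, the largest distance in km from the home
  geocode reached during a day (samples inside the home radius included).

Distances use a planar (equirectangular) approximation: latitude and longitude
degree differences are converted to km separately, longitude scaled by the
cosine of the mean latitude of the pair, and combined by the Pythagorean
theorem. This is accurate to well under 1% for the within-city distances the
method targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: km per degree of latitude (and of longitude at the equator).
KM_PER_DEGREE = 111.32

#: Day indices treated as weekend when a calendar is not supplied
#: (day 1 = Monday, days 6 and 7 = Saturday/Sunday).
WEEKEND_DAYS = frozenset({6, 7})


@dataclass(frozen=True)
class GeoSample:
    """One GPS fix: minutes-of-day timestamp plus coordinates in degrees."""

    timestamp: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class HomeAnchor:
    """Home geocode with the radius (metres) defining 'at home'."""

    lat: float
    lon: float
    radius_m: float = 500.0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("radius_m must be positive")


@dataclass
class GeoTrace:
    """Ordered GPS samples for one subject-day."""

    subject_id: str
    day_index: int
    samples: list[GeoSample] = field(default_factory=list)


@dataclass(frozen=True)
class DailyMobility:
    """One subject-day's mobility summary (one row of the stacked table)."""

    subject_id: str
    day_index: int
    is_weekend: bool
    dma_minutes: float
    mdr_km: float


def is_weekend_day(day_index: int) -> bool:
    """Default weekend flag: cycle day_index over a Monday-start week."""
    return ((day_index - 1) % 7 + 1) in WEEKEND_DAYS


def planar_distance_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Planar distance in km between two (lat, lon) points in degrees.

    Degree differences are converted to km independently (longitude corrected
    by cos of the mean latitude) and combined with the Pythagorean theorem.
    Symmetric and nonnegative; intended for separations up to ~100 km.
    """
    lat_a, lon_a = a
    lat_b, lon_b = b
    for lat, lon in ((lat_a, lon_a), (lat_b, lon_b)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinate ({lat}, {lon}) out of bounds")
    dlat_km = (lat_b - lat_a) * KM_PER_DEGREE
    mean_lat = math.radians((lat_a + lat_b) / 2.0)
    dlon_km = (lon_b - lon_a) * KM_PER_DEGREE * math.cos(mean_lat)
    return math.hypot(dlat_km, dlon_km)


def is_away(sample: GeoSample, home: HomeAnchor) -> bool:
    """True iff the sample lies strictly beyond the home radius.

    A point at exactly the radius counts as at home.
    """
    d_km = planar_distance_km((sample.lat, sample.lon), (home.lat, home.lon))
    return d_km > home.radius_m / 1000.0


def summarize_day(
    trace: GeoTrace, home: HomeAnchor, *, default_interval_min: float = 1.0
) -> DailyMobility:
    """Reduce one day's trace to (DMA, MDR).

    Each sample represents the interval until the next sample; the last
    sample carries the trace's median inter-sample interval (so irregular
    sampling is weighted by time, not by fix count). DMA sums the minutes of
    samples classified away; MDR is the maximum distance from home over all
    samples, including those inside the home radius. A single-sample trace
    has no intervals and falls back to ``default_interval_min``.
    """
    if not trace.samples:
        raise ValueError(f"empty trace for subject {trace.subject_id}")
    samples = sorted(trace.samples, key=lambda s: s.timestamp)
    times = np.array([s.timestamp for s in samples], dtype=float)
    if len(samples) >= 2:
        intervals = np.diff(times)
        if np.any(intervals < 0):  # unreachable after sort; guards NaN input
            raise ValueError("timestamps must be non-decreasing")
        weights = np.append(intervals, np.median(intervals))
    else:
        weights = np.array([default_interval_min])

    dists = np.array(
        [planar_distance_km((s.lat, s.lon), (home.lat, home.lon)) for s in samples]
    )
    away = dists > home.radius_m / 1000.0
    dma = float(np.clip(weights[away].sum(), 0.0, 1440.0))
    mdr = float(dists.max())
    return DailyMobility(
        subject_id=trace.subject_id,
        day_index=trace.day_index,
        is_weekend=is_weekend_day(trace.day_index),
        dma_minutes=dma,
        mdr_km=mdr,
    )


def summarize_traces(
    traces: list[GeoTrace], home: HomeAnchor, **kwargs
) -> pd.DataFrame:
    """Summarize many traces into a stacked GPS table (one row per day)."""
    rows = [summarize_day(t, home, **kwargs) for t in traces]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "day_index": [r.day_index for r in rows],
            "is_weekend": [r.is_weekend for r in rows],
            "dma_minutes": [r.dma_minutes for r in rows],
            "mdr_km": [r.mdr_km for r in rows],
        }
    )


def read_traces_csv(path) -> list[GeoTrace]:
    """Read traces from CSV with columns subject_id, day_index, timestamp, lat, lon."""
    df = pd.read_csv(path)
    traces = []
    for (sid, day), grp in df.groupby(["subject_id", "day_index"], sort=True):
        grp = grp.sort_values("timestamp")
        samples = [
            GeoSample(float(t), float(la), float(lo))
            for t, la, lo in zip(grp["timestamp"], grp["lat"], grp["lon"])
        ]
        traces.append(GeoTrace(subject_id=str(sid), day_index=int(day), samples=samples))
    return traces
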