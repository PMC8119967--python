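"""Synthetic GPS mobility cohorts with the structure the pipeline assumes.

The original clinical study data (185 German women with a history of child
abuse, 3–7 monitored days each, ~80% with a PTSD diagnosis) is not public, so
this module generates stand-in cohorts carrying the statistical features the
downstream analysis is designed to detect:

* 3–7 observation days per subject, ~80/20 class imbalance,
* a group shift in daily minutes away from home (controls spend *less* time
  away than the PTSD group, matching the source cohort's direction),
* a group shift and a weekend contraction in the maximum daily radius,
* subject-level random intercepts plus day-level residual noise.

Daily minutes away (DMA) are Gaussian with a random subject intercept,
clamped to [0, 1440]; the maximum daily radius (MDR) is log-normal (radii are
nonnegative and right-skewed), with group and weekend shifts acting on the
log scale. Both choices are the simplest forms exposing the group / weekend /
subject structure while staying checkable in closed form.

``generate_gps_trace`` additionally builds raw coordinate traces with known
ground-truth DMA/MDR, to exercise the trace-reduction math end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geo import KM_PER_DEGREE, GeoSample, GeoTrace, HomeAnchor, is_weekend_day

STACKED_COLUMNS = ["subject_id", "day_index", "is_weekend", "dma_minutes", "mdr_km"]
LABEL_COLUMNS = ["subject_id", "group"]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Group 1 is the PTSD group (majority), group 2 the trauma-exposed control
    group. ``dma_effect`` and ``mdr_effect`` are the group-2 shifts (negative
    = controls spend less time away / travel less far); ``weekend_mdr_shift``
    applies to both groups on weekend days. DMA parameters are in minutes;
    MDR parameters are on the log-km scale.
    """

    n_group1: int = 150
    n_group2: int = 35
    days_min: int = 3
    days_max: int = 7
    dma_mean_g1: float = 240.0
    dma_effect: float = -85.0
    mdr_log_mean: float = 1.0
    mdr_effect: float = -0.5
    weekend_mdr_shift: float = -0.3
    subject_sd: float = 60.0
    noise_sd: float = 60.0
    mdr_subject_sd: float = 0.35
    mdr_noise_sd: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_group1 < 1:
            raise ConfigurationError(f"n_group1 must be >= 1, got {self.n_group1}")
        if self.n_group2 < 1:
            raise ConfigurationError(f"n_group2 must be >= 1, got {self.n_group2}")
        if not (1 <= self.days_min <= self.days_max <= 7):
            raise ConfigurationError(
                f"need 1 <= days_min <= days_max <= 7, got "
                f"days_min={self.days_min}, days_max={self.days_max}"
            )
        for name in ("subject_sd", "noise_sd", "mdr_subject_sd", "mdr_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")


def study_config(seed: int = 0) -> CohortConfig:
    """Preset emulating the source cohort's published structure.

    N = 185 (150 PTSD / 35 control), 3–7 days, controls away less and with a
    smaller radius (~1 SD standardized group effects), weekend radius
    contraction of −0.3 log-km for everyone.
    """
    return CohortConfig(seed=seed)


def null_config(seed: int = 0) -> CohortConfig:
    """Same generative process with both group effects zeroed (labels carry no signal)."""
    return replace(study_config(seed), dma_effect=0.0, mdr_effect=0.0)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (stacked GPS table, label table).

    The stacked table has columns subject_id, day_index, is_weekend,
    dma_minutes, mdr_km — one row per observed subject-day, day_index
    strictly increasing within subject. Deterministic given ``config``
    (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_group1 + config.n_group2
    groups = np.array([1] * config.n_group1 + [2] * config.n_group2)
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]

    rows: list[tuple] = []
    for sid, group in zip(subject_ids, groups):
        n_days = int(rng.integers(config.days_min, config.days_max + 1))
        days = np.sort(rng.choice(np.arange(1, 8), size=n_days, replace=False))
        b_dma = rng.normal(0.0, config.subject_sd)
        b_mdr = rng.normal(0.0, config.mdr_subject_sd)
        g2 = group == 2
        for day in days:
            weekend = is_weekend_day(int(day))
            dma = (
                config.dma_mean_g1
                + (config.dma_effect if g2 else 0.0)
                + b_dma
                + rng.normal(0.0, config.noise_sd)
            )
            log_mdr = (
                config.mdr_log_mean
                + (config.mdr_effect if g2 else 0.0)
                + (config.weekend_mdr_shift if weekend else 0.0)
                + b_mdr
                + rng.normal(0.0, config.mdr_noise_sd)
            )
            rows.append(
                (sid, int(day), weekend, float(np.clip(dma, 0.0, 1440.0)), math.exp(log_mdr))
            )

    stacked = pd.DataFrame(rows, columns=STACKED_COLUMNS)
    labels = pd.DataFrame({"subject_id": subject_ids, "group": groups})
    return stacked, labels


def generate_null_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """As :func:`generate_cohort` with group effects forced to zero."""
    return generate_cohort(replace(config, dma_effect=0.0, mdr_effect=0.0))


def generate_gps_trace(
    home: HomeAnchor,
    away_minutes: float,
    max_km: float,
    sampling_interval: float = 1.0,
    seed: int = 0,
    subject_id: str = "S0001",
    day_index: int = 1,
) -> GeoTrace:
    """Build a coordinate trace with known DMA/MDR ground truth.

    Samples cover one day at ``sampling_interval`` minutes. A contiguous block
    of round(away_minutes / interval) samples is displaced due north to
    ``max_km`` from home; all other samples sit at the home coordinate. The
    true minutes-beyond-radius and max distance therefore equal the targets
    within one sampling interval. The block's start time is drawn from
    ``seed`` so repeated calls with one seed are identical.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    if not (0.0 <= away_minutes <= 1440.0):
        raise ValueError(f"away_minutes {away_minutes} not in [0, 1440]")
    if max_km < 0:
        raise ValueError("max_km must be >= 0")
    n_samples = int(1440 // sampling_interval)
    n_away = int(round(away_minutes / sampling_interval))
    if n_away > n_samples:
        raise ValueError("away target exceeds the day at this sampling interval")
    if n_away > 0 and max_km * 1000.0 <= home.radius_m:
        raise ValueError("away target needs max_km beyond the home radius")
    if n_away == 0 and max_km * 1000.0 > home.radius_m:
        raise ValueError("max_km beyond the home radius needs away_minutes > 0")

    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n_samples - n_away + 1)) if n_away else 0
    dlat = max_km / KM_PER_DEGREE  # displacement due north: no longitude correction
    samples = []
    for i in range(n_samples):
        t = i * sampling_interval
        if n_away and start <= i < start + n_away:
            samples.append(GeoSample(t, home.lat + dlat, home.lon))
        elif max_km > 0 and n_away == 0 and i == 0:
            samples.append(GeoSample(t, home.lat + dlat, home.lon))
        else:
            samples.append(GeoSample(t, home.lat, home.lon))
    return GeoTrace(subject_id=subject_id, day_index=day_index, samples=samples)


def write_cohort_csv(stacked: pd.DataFrame, labels: pd.DataFrame, stacked_path, labels_path) -> None:
    stacked[STACKED_COLUMNS].to_csv(stacked_path, index=False)
    labels[LABEL_COLUMNS].to_csv(labels_path, index=False)


def read_cohort_csv(stacked_path, labels_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    stacked = pd.read_csv(stacked_path)
    labels = pd.read_csv(labels_path)
    missing = set(STACKED_COLUMNS) - set(stacked.columns)
    if missing:
        raise ValueError(f"stacked table missing columns: {sorted(missing)}")
    missing = set(LABEL_COLUMNS) - set(labels.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return stacked, labels
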