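"""Feature engineering for the three arms of the ensemble pipeline.

Three feature spaces are built from the stacked subject-day mobility table:

* **Arm 1** — 15 distributional statistics of a per-subject series (applied
  to the out-of-fold day-level prediction probabilities): mean, median,
  sample variance, OLS slope on day index, RMSSD, and the 5%..95% quantiles
  in 10% steps.
* **Arm 2** — the wide-format day matrix: dma_day1..7, mdr_day1..7
  (14 columns, missing cells where a day was not observed).
* **Arm 3** — 39 per-subject features of the raw DMA/MDR series: for MDR the
  15 distributional statistics plus the random-intercept BLUP from an
  intercept-only mixed model, weekday mean, weekend mean, weekday/weekend
  mean ratio and the weekend-max minus weekday-max difference (20 features);
  for DMA the first 18 of those are repeated; plus the percent of total time
  away spent on weekends.

Standardization (z-scoring) and cross-subject column-mean imputation learn
their statistics on a training partition only and are applied unchanged to
held-out data, so no information leaks across resampling splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd

QUANTILE_GRID = np.arange(0.05, 0.96, 0.10)  # 5%..95% in 10% steps
QUANTILE_NAMES = [f"q{int(round(q * 100)):02d}" for q in QUANTILE_GRID]

WIDE_COLUMNS = [f"dma_day{d}" for d in range(1, 8)] + [f"mdr_day{d}" for d in range(1, 8)]


@dataclass(frozen=True)
class SeriesSummary:
    """The 15 distributional statistics of one per-subject series."""

    mean: float
    median: float
    variance: float
    slope: float
    rmssd: float
    q05: float
    q15: float
    q25: float
    q35: float
    q45: float
    q55: float
    q65: float
    q75: float
    q85: float
    q95: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


SUMMARY_NAMES = [f.name for f in dataclass_fields(SeriesSummary)]
assert len(SUMMARY_NAMES) == 15


def slope(values, day_indices) -> float:
    """Ordinary-least-squares slope of values on day index.

    Fewer than two distinct day indices is degenerate: the trend is
    unidentifiable and 0.0 is returned.
    """
    x = np.asarray(day_indices, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        return 0.0
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def rmssd(values) -> float:
    """Root mean square of successive differences; 0.0 for a single point."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        return 0.0
    d = np.diff(y)
    return float(np.sqrt(np.mean(d * d)))


def summarize_series(values, day_indices=None) -> SeriesSummary:
    """Compute the 15 distributional statistics of one series.

    ``values`` must be ordered by day; ``day_indices`` (defaults to 1..n)
    feed the slope. Variance uses the n−1 denominator; quantiles use linear
    interpolation between order statistics. Single-point series get
    variance/slope/rmssd of 0.
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("cannot summarize an empty series")
    x = np.arange(1, y.size + 1) if day_indices is None else np.asarray(day_indices, float)
    qs = np.quantile(y, QUANTILE_GRID)
    return SeriesSummary(
        mean=float(y.mean()),
        median=float(np.median(y)),
        variance=float(y.var(ddof=1)) if y.size > 1 else 0.0,
        slope=slope(y, x),
        rmssd=rmssd(y),
        **dict(zip(QUANTILE_NAMES, map(float, qs))),
    )


def random_intercepts(stacked: pd.DataFrame, variable: str) -> pd.Series:
    """Per-subject random-intercept BLUPs from an intercept-only mixed model.

    Fits y_ij = mu + b_i + e_ij by REML and returns the shrunken subject
    intercepts b_i (shrinkage n_i*tau^2 / (n_i*tau^2 + sigma^2) toward 0).
    When the between-subject variance is estimated at ~0 every BLUP is ~0.
    On a fit failure the centered subject means are returned with a warning.
    """
    col = {"DMA": "dma_minutes", "MDR": "mdr_km"}.get(variable.upper())
    if col is None:
        raise ValueError(f"variable must be 'DMA' or 'MDR', got {variable!r}")
    if stacked["subject_id"].nunique() < 2:
        raise ValueError("random intercepts need at least 2 subjects")
    y = stacked[col].to_numpy(dtype=float)
    groups = stacked["subject_id"].to_numpy()
    subjects = pd.unique(groups)
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups)
            fit = model.fit(reml=True)
        re = {k: float(v.iloc[0]) for k, v in fit.random_effects.items()}
        return pd.Series([re[s] for s in subjects], index=subjects, name=f"ri_{variable.lower()}")
    except Exception:  # singular fits on degenerate toy inputs
        warnings.warn(
            f"mixed-model fit failed for {variable}; falling back to centered subject means",
            RuntimeWarning,
            stacklevel=2,
        )
        means = pd.Series(y).groupby(pd.Series(groups)).mean()
        centered = means - means.mean()
        return pd.Series(
            [float(centered[s]) for s in subjects], index=subjects, name=f"ri_{variable.lower()}"
        )


def to_wide(stacked: pd.DataFrame) -> pd.DataFrame:
    """Pivot the stacked table to the 14-column wide day matrix.

    Rows are subjects, columns dma_day1..7 then mdr_day1..7; unobserved
    subject-days are NaN. Duplicate (subject, day) pairs are an error.
    """
    if len(stacked) == 0:
        return pd.DataFrame(columns=WIDE_COLUMNS)
    if not stacked["day_index"].between(1, 7).all():
        raise ValueError("day_index must be in 1..7")
    if stacked.duplicated(["subject_id", "day_index"]).any():
        dups = stacked[stacked.duplicated(["subject_id", "day_index"], keep=False)]
        raise ValueError(f"duplicate subject-day rows: {dups['subject_id'].unique()[:5]}")
    wide = stacked.pivot(index="subject_id", columns="day_index", values=["dma_minutes", "mdr_km"])
    out = pd.DataFrame(index=wide.index)
    for var, prefix in (("dma_minutes", "dma"), ("mdr_km", "mdr")):
        for d in range(1, 8):
            key = (var, d)
            out[f"{prefix}_day{d}"] = wide[key] if key in wide.columns else np.nan
    return out[WIDE_COLUMNS]


def _series_summary_frame(stacked: pd.DataFrame, col: str, prefix: str) -> pd.DataFrame:
    rows = {}
    for sid, grp in stacked.sort_values("day_index").groupby("subject_id", sort=False):
        s = summarize_series(grp[col].to_numpy(), grp["day_index"].to_numpy())
        rows[sid] = {f"{prefix}_{k}": v for k, v in s.to_dict().items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def engineer_arm3(stacked: pd.DataFrame) -> pd.DataFrame:
    """Build the 39-feature per-subject matrix from the stacked table.

    Cells that are undefined for a subject (weekend features with no weekend
    days, the weekday/weekend ratio with a zero weekend mean, the weekend
    away percent with zero total DMA) are left NaN for downstream
    training-fold imputation.
    """
    stacked = stacked.sort_values(["subject_id", "day_index"])
    mdr = _series_summary_frame(stacked, "mdr_km", "arm3_mdr")
    dma = _series_summary_frame(stacked, "dma_minutes", "arm3_dma")

    ri_mdr = random_intercepts(stacked, "MDR")
    ri_dma = random_intercepts(stacked, "DMA")

    extra = {}
    for sid, grp in stacked.groupby("subject_id", sort=False):
        we = grp[grp["is_weekend"]]
        wd = grp[~grp["is_weekend"]]
        we_mdr_mean = we["mdr_km"].mean() if len(we) else np.nan
        wd_mdr_mean = wd["mdr_km"].mean() if len(wd) else np.nan
        we_dma_mean = we["dma_minutes"].mean() if len(we) else np.nan
        wd_dma_mean = wd["dma_minutes"].mean() if len(wd) else np.nan
        ratio = (
            wd_mdr_mean / we_mdr_mean
            if len(we) and len(wd) and we_mdr_mean not in (0.0,) and not np.isnan(we_mdr_mean)
            else np.nan
        )
        max_diff = (
            we["mdr_km"].max() - wd["mdr_km"].max() if len(we) and len(wd) else np.nan
        )
        total_dma = grp["dma_minutes"].sum()
        pct = 100.0 * we["dma_minutes"].sum() / total_dma if total_dma > 0 else np.nan
        extra[sid] = {
            "arm3_mdr_weekday_mean": wd_mdr_mean,
            "arm3_mdr_weekend_mean": we_mdr_mean,
            "arm3_mdr_weekday_weekend_ratio": ratio,
            "arm3_mdr_max_weekend_minus_max_weekday": max_diff,
            "arm3_dma_weekday_mean": wd_dma_mean,
            "arm3_dma_weekend_mean": we_dma_mean,
            "arm3_weekend_away_pct": pct,
        }
    extra = pd.DataFrame.from_dict(extra, orient="index")

    out = pd.concat(
        [
            mdr,
            ri_mdr.rename("arm3_mdr_random_intercept"),
            extra[
                [
                    "arm3_mdr_weekday_mean",
                    "arm3_mdr_weekend_mean",
                    "arm3_mdr_weekday_weekend_ratio",
                    "arm3_mdr_max_weekend_minus_max_weekday",
                ]
            ],
            dma,
            ri_dma.rename("arm3_dma_random_intercept"),
            extra[["arm3_dma_weekday_mean", "arm3_dma_weekend_mean", "arm3_weekend_away_pct"]],
        ],
        axis=1,
    )
    assert out.shape[1] == 39
    return out


def engineer_prediction_features(day_probs: pd.DataFrame) -> pd.DataFrame:
    """Summarize day-level prediction probabilities into 15 features per subject.

    ``day_probs`` has columns subject_id, day_index, prob_group1 (each
    probability in [0, 1], 3–7 per subject in the study design).
    """
    p = day_probs["prob_group1"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prediction probabilities must lie in [0, 1]")
    rows = {}
    for sid, grp in day_probs.sort_values("day_index").groupby("subject_id", sort=False):
        s = summarize_series(grp["prob_group1"].to_numpy(), grp["day_index"].to_numpy())
        rows[sid] = {f"pred_{k}": v for k, v in s.to_dict().items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    assert out.shape[1] == 15
    return out


@dataclass(frozen=True)
class ScalingStats:
    """Per-feature centers/scales (and imputation means) from a training partition."""

    center: pd.Series
    scale: pd.Series  # 0 flags a constant training feature

    @classmethod
    def fit(cls, matrix: pd.DataFrame) -> "ScalingStats":
        center = matrix.mean(axis=0, skipna=True)
        if center.isna().any():
            bad = center.index[center.isna()].tolist()
            raise ValueError(f"training columns entirely missing: {bad}")
        scale = matrix.std(axis=0, ddof=1, skipna=True).fillna(0.0)
        return cls(center=center, scale=scale)


def impute_column_means(matrix: pd.DataFrame, stats: ScalingStats) -> pd.DataFrame:
    """Replace missing cells by the training-partition column means."""
    return matrix.fillna(stats.center)


def standardize(matrix: pd.DataFrame, stats: ScalingStats) -> pd.DataFrame:
    """Z-score columns with training stats; constant training columns map to 0."""
    scale = stats.scale.replace(0.0, np.nan)
    out = (matrix - stats.center) / scale
    return out.fillna(0.0)
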