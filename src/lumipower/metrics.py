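"""Daily light-exposure metrics computed from one participant-day of mel EDI.

The twelve default metrics:

================  ======================  =========================================
column            unit                    definition
================  ======================  =========================================
gm                lx                      geometric mean, log base 10
gsd               (multiplicative)        geometric standard deviation, log base 10
le                lx*h                    luminous exposure (time-integrated)
tat250, tat1000   h                       time above 250 / 1000 lx
mtl_above250      decimal hours-of-day    mean timing of light above 250 lx
mtl_below10       decimal hours-of-day    mean timing of light below 10 lx
iv                dimensionless           intradaily variability (hourly bins)
m10_mean/m10_mid  lx / hours-of-day       brightest 10-h window mean and midpoint
l5_mean/l5_mid    lx / hours-of-day       darkest 5-h window mean and midpoint
================  ======================  =========================================

All metrics use only the *valid* epochs of a day (non-wear and gaps are
excluded, not zero-filled).  A metric that is undefined for a day (e.g. no
epoch above 250 lx) yields a missing cell, which downstream model fitting
tolerates.  Timing is decimal hours since local midnight, evaluated at the
epoch midpoint; hh:mm rendering happens only at the reporting layer.

Threshold comparisons are strict (> above, < below); with continuous
irradiance values the boundary has measure zero.  Intradaily variability
follows the Van Someren first-order-difference ratio on hourly means:

    IV = mean of (x_i - x_{i-1})^2 over clock-adjacent hourly bins
         / population variance of the hourly means

which for a complete day of N bins equals
N * sum_i (x_i - x_{i-1})^2 / ((N-1) * sum_i (x_i - xbar)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricConfig",
    "DaySeries",
    "METRIC_COLUMNS",
    "geometric_mean",
    "geometric_sd",
    "luminous_exposure",
    "time_above_threshold",
    "mean_timing_relative_to_threshold",
    "intradaily_variability",
    "conditional_window",
    "compute_day_metrics",
]

#: the default metric columns, in reporting order
METRIC_COLUMNS = (
    "gm", "gsd", "le", "tat250", "tat1000",
    "mtl_above250", "mtl_below10", "iv",
    "m10_mean", "m10_mid", "l5_mean", "l5_mid",
)


@dataclass(frozen=True)
class MetricConfig:
    """Parametrization of the daily metrics.

    Defaults follow standard melanopic-EDI practice: TAT thresholds of 250
    and 1000 lx, mean-timing thresholds of 250 lx (above) and 10 lx
    (below), brightest-10-h / darkest-5-h windows, and a 0.01 lx floor
    before taking log10 (mel EDI reaches 0 at night; the floor sits below
    typically observed darkest-5-h means of ~0.05 lx).
    """

    tat_thresholds: tuple[float, ...] = (250.0, 1000.0)
    mtl_above: float = 250.0
    mtl_below: float = 10.0
    log_floor: float = 0.01
    m10_width_h: float = 10.0
    l5_width_h: float = 5.0
    window_min_coverage: float = 0.5
    circular_mtl: bool = False
    metrics: tuple[str, ...] = METRIC_COLUMNS


@dataclass
class DaySeries:
    """One participant-day on its epoch grid.

    ``times_h``: clock hours of each epoch *start* since local midnight,
    contiguous at spacing ``delta_h``; ``values``: mel EDI (NaN for gaps);
    ``valid``: wear/validity mask.
    """

    times_h: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    delta_h: float

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    @property
    def valid_mid_times(self) -> np.ndarray:
        return self.times_h[self.valid] + self.delta_h / 2.0


def geometric_mean(values: np.ndarray, floor: float = 0.01) -> float:
    """10^(mean log10) of the day's valid values, floored at ``floor`` lx."""
    if len(values) == 0:
        return math.nan
    logs = np.log10(np.maximum(values, floor))
    return float(10.0 ** logs.mean())


def geometric_sd(values: np.ndarray, floor: float = 0.01) -> float:
    """10^(sample SD of log10), a multiplicative dispersion factor (>= 1)."""
    if len(values) < 2:
        return math.nan
    logs = np.log10(np.maximum(values, floor))
    return float(10.0 ** logs.std(ddof=1))


def luminous_exposure(values: np.ndarray, delta_h: float) -> float:
    """Time-integrated illuminance over the day's valid epochs, lx*h."""
    return float(values.sum() * delta_h)


def time_above_threshold(values: np.ndarray, delta_h: float, threshold: float) -> float:
    """Total valid time with value strictly above ``threshold``, in hours."""
    return float((values > threshold).sum() * delta_h)


def mean_timing_relative_to_threshold(
    values: np.ndarray,
    mid_times_h: np.ndarray,
    threshold: float,
    direction: str,
    circular: bool = False,
) -> float:
    """Mean clock time (decimal h) of valid epochs above/below a threshold.

    ``direction`` is ``"above"`` (strictly >) or ``"below"`` (strictly <).
    Missing when no epoch qualifies.  The default is the linear mean on a
    midnight-anchored day; ``circular=True`` uses the circular mean on the
    24-h clock instead.
    """
    if direction == "above":
        mask = values > threshold
    elif direction == "below":
        mask = values < threshold
    else:
        raise ValueError("direction must be 'above' or 'below'")
    if not mask.any():
        return math.nan
    t = mid_times_h[mask]
    if not circular:
        return float(t.mean())
    ang = t * (2 * np.pi / 24.0)
    mean_ang = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean_ang * 24.0 / (2 * np.pi)) % 24.0)


def _hourly_means(day: DaySeries) -> tuple[np.ndarray, np.ndarray]:
    """(clock hours, mean values) for hourly bins with >=1 valid epoch."""
    hours = np.floor(day.times_h[day.valid]).astype(int)
    vals = day.valid_values
    uniq = np.unique(hours)
    means = np.array([vals[hours == h].mean() for h in uniq], dtype=float)
    return uniq, means


def intradaily_variability(day: DaySeries) -> float:
    """Van Someren fragmentation index on hourly means.

    Hourly bins with no valid epoch are dropped; squared successive
    differences are taken only between bins adjacent in clock time.
    Missing when fewer than 2 bins survive, no adjacent pair exists, or
    the day is constant (zero variance).
    """
    hours, x = _hourly_means(day)
    n = len(x)
    if n < 2:
        return math.nan
    adjacent = np.diff(hours) == 1
    if not adjacent.any():
        return math.nan
    diffs = np.diff(x)[adjacent]
    msd = float((diffs**2).mean())
    var = float(((x - x.mean()) ** 2).mean())  # population variance over N bins
    if var == 0.0:
        return math.nan
    return msd / var


def conditional_window(
    day: DaySeries,
    width_h: float,
    mode: str,
    min_coverage: float = 0.5,
) -> tuple[float, float]:
    """Mean and midpoint of the brightest/darkest window of ``width_h`` hours.

    A window of exactly ``width_h`` slides in epoch steps, fully inside
    the day's grid (no midnight wrap).  Its score is the mean of valid
    epochs inside; windows with less than ``min_coverage`` of their cells
    valid are not scoreable.  Brightest (``mode="brightest"``) takes the
    maximum score, darkest the minimum; the earliest window wins ties.
    Returns ``(mean lx, window start + width/2 in decimal hours)`` or
    ``(nan, nan)`` when no window is scoreable.
    """
    if mode not in ("brightest", "darkest"):
        raise ValueError("mode must be 'brightest' or 'darkest'")
    k = int(round(width_h / day.delta_h))
    n = len(day.values)
    if k <= 0 or k > n:
        return math.nan, math.nan
    vals = np.where(day.valid, day.values, 0.0)
    valid = day.valid.astype(float)
    csum_v = np.concatenate([[0.0], np.cumsum(vals)])
    csum_n = np.concatenate([[0.0], np.cumsum(valid)])
    win_sum = csum_v[k:] - csum_v[:-k]
    win_cnt = csum_n[k:] - csum_n[:-k]
    scoreable = win_cnt >= max(1.0, min_coverage * k)
    if not scoreable.any():
        return math.nan, math.nan
    with np.errstate(invalid="ignore"):
        score = np.where(scoreable, win_sum / np.where(win_cnt > 0, win_cnt, 1.0), np.nan)
    if mode == "brightest":
        best = np.nanmax(score)
    else:
        best = np.nanmin(score)
    start = int(np.flatnonzero(score == best)[0])  # earliest tie wins
    midpoint = float(day.times_h[start] + width_h / 2.0)
    return float(best), midpoint


def _metrics_for_day(day: DaySeries, cfg: MetricConfig) -> dict[str, float]:
    vals = day.valid_values
    mids = day.valid_mid_times
    out: dict[str, float] = {}
    if "gm" in cfg.metrics:
        out["gm"] = geometric_mean(vals, cfg.log_floor)
    if "gsd" in cfg.metrics:
        out["gsd"] = geometric_sd(vals, cfg.log_floor)
    if "le" in cfg.metrics:
        out["le"] = luminous_exposure(vals, day.delta_h)
    for thr in cfg.tat_thresholds:
        name = f"tat{thr:g}"
        if name in cfg.metrics:
            out[name] = time_above_threshold(vals, day.delta_h, thr)
    if "mtl_above250" in cfg.metrics:
        out["mtl_above250"] = mean_timing_relative_to_threshold(
            vals, mids, cfg.mtl_above, "above", cfg.circular_mtl
        )
    if "mtl_below10" in cfg.metrics:
        out["mtl_below10"] = mean_timing_relative_to_threshold(
            vals, mids, cfg.mtl_below, "below", cfg.circular_mtl
        )
    if "iv" in cfg.metrics:
        out["iv"] = intradaily_variability(day)
    if "m10_mean" in cfg.metrics or "m10_mid" in cfg.metrics:
        m, mid = conditional_window(day, cfg.m10_width_h, "brightest", cfg.window_min_coverage)
        out["m10_mean"], out["m10_mid"] = m, mid
    if "l5_mean" in cfg.metrics or "l5_mid" in cfg.metrics:
        m, mid = conditional_window(day, cfg.l5_width_h, "darkest", cfg.window_min_coverage)
        out["l5_mean"], out["l5_mid"] = m, mid
    return {k: v for k, v in out.items() if k in cfg.metrics}


def day_series_from_frame(grp: pd.DataFrame) -> DaySeries:
    """Build a :class:`DaySeries` from one participant-day of epoch rows."""
    ts = pd.to_datetime(grp["timestamp"])
    midnight = ts.dt.normalize()
    times_h = ((ts - midnight).dt.total_seconds() / 3600.0).to_numpy()
    delta_h = float(grp["epoch_s"].iloc[0]) / 3600.0
    return DaySeries(
        times_h=times_h,
        values=grp["mel_edi"].to_numpy(dtype=float),
        valid=grp["valid"].to_numpy(dtype=bool),
        delta_h=delta_h,
    )


def compute_day_metrics(
    series: pd.DataFrame, cfg: MetricConfig | None = None
) -> pd.DataFrame:
    """One row of daily metrics per (participant, day) from an epoch series.

    Expects a preprocessed, filtered epoch table (columns ``participant_id,
    timestamp, epoch_s, mel_edi, valid`` and optionally ``condition``).
    Cells where a metric is undefined are missing (NaN).
    """
    cfg = cfg or MetricConfig()
    rows = []
    keys = ["participant_id", "day"]
    for (pid, day), grp in series.groupby(keys, sort=True):
        rec: dict[str, object] = {"participant_id": pid, "day": day}
        if "condition" in grp.columns:
            rec["condition"] = grp["condition"].iloc[0]
        rec.update(_metrics_for_day(day_series_from_frame(grp), cfg))
        rows.append(rec)
    out = pd.DataFrame(rows)
    lead = [c for c in ("participant_id", "day", "condition") if c in out.columns]
    return out[lead + [c for c in cfg.metrics if c in out.columns]]
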