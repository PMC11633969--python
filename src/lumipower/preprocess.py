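"""Melanopic EDI computation and validity filtering.

Melanopic equivalent daylight (D65) illuminance (mel EDI, CIE S 026) is
derived from the green and blue irradiance channels of the Actiwatch
Spectrum class of devices by a calibrated linear combination:

    mel EDI [lx] = 4.3 * (G + B) [mW m^-2] / 1.3262 [mW lm^-1]

Day-level filtering keeps a participant-day only if at least 80% of its
grid cells are valid (worn, non-missing); participant-level filtering
keeps a participant only if at least two valid days survive in *every*
condition.  Invalid epochs on kept days are excluded from all metric
computations (non-wear light is not personal exposure), not zero-filled;
``zero_fill_nonwear`` flips that behaviour for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MEL_EDI_COEF",
    "MEL_EDI_DENOM",
    "compute_mel_edi",
    "add_mel_edi",
    "day_validity_fraction",
    "filter_days",
    "filter_participants",
    "ValidityReport",
]

MEL_EDI_COEF = 4.3        # lx per (mW m^-2 / (mW lm^-1))
MEL_EDI_DENOM = 1.3262    # mW lm^-1, device-specific calibration divisor


def compute_mel_edi(green, blue):
    """Melanopic EDI (lx) from green and blue channel irradiances (mW m^-2).

    Accepts scalars or arrays; only the channel sum enters the formula.
    Negative irradiance is a sensor/parse fault and raises.
    """
    g = np.asarray(green, dtype=float)
    b = np.asarray(blue, dtype=float)
    if np.any(g[~np.isnan(g)] < 0) or np.any(b[~np.isnan(b)] < 0):
        raise ValueError("negative sensor irradiance")
    out = MEL_EDI_COEF * (g + b) / MEL_EDI_DENOM
    if out.ndim == 0:
        return float(out)
    return out


def add_mel_edi(records: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``mel_edi`` column, computing it from green/blue if absent."""
    if "mel_edi" in records.columns:
        return records
    if not {"green", "blue"} <= set(records.columns):
        raise ValueError("need either a mel_edi column or green+blue channels")
    out = records.copy()
    out["mel_edi"] = compute_mel_edi(out["green"], out["blue"])
    return out


@dataclass
class ValidityReport:
    """Per-day and per-participant record of what filtering removed and why."""

    day_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    participant_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        day = self.day_table.assign(level="day")
        part = self.participant_table.assign(level="participant")
        pd.concat([day, part], ignore_index=True).to_csv(path, index=False)


def day_validity_fraction(series: pd.DataFrame, participant: str, day) -> float:
    """Fraction of a participant-day's grid cells that are valid (0-1)."""
    mask = (series["participant_id"] == str(participant)) & (series["day"] == day)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no grid cells for participant {participant!r} on {day}")
    return float(series.loc[mask, "valid"].sum()) / n


def filter_days(
    series: pd.DataFrame, day_threshold: float = 0.8
) -> tuple[pd.DataFrame, ValidityReport]:
    """Drop participant-days with less than ``day_threshold`` valid data.

    The comparison is inclusive: a day at exactly the threshold is kept
    ("a minimum of 80%").  Returns the surviving epoch series and a report
    listing every day with its validity fraction and keep decision.
    """
    grp = series.groupby(["participant_id", "day"], sort=True)
    frac = grp["valid"].mean()
    report = frac.rename("fraction_valid").reset_index()
    if "condition" in series.columns:
        cond = grp["condition"].first().reset_index(drop=True)
        report["condition"] = cond
    report["kept"] = report["fraction_valid"] >= day_threshold
    kept_keys = set(
        map(tuple, report.loc[report["kept"], ["participant_id", "day"]].to_numpy())
    )
    keep_mask = [
        (pid, day) in kept_keys
        for pid, day in zip(series["participant_id"], series["day"])
    ]
    out = series.loc[keep_mask].reset_index(drop=True)
    return out, ValidityReport(day_table=report)


def filter_participants(
    series: pd.DataFrame, min_days: int = 2
) -> tuple[pd.DataFrame, ValidityReport]:
    """Drop participants with fewer than ``min_days`` days in any condition.

    Requires condition labels.  The day count is over distinct surviving
    calendar days; a condition entirely absent for a participant counts
    as zero days.  Raises if nothing survives.
    """
    if "condition" not in series.columns or series["condition"].isna().all():
        raise ValueError("condition labels are required for participant filtering")
    levels = sorted(series["condition"].dropna().unique())
    days = (
        series.groupby(["participant_id", "condition"])["day"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=levels, fill_value=0)
    )
    kept = (days >= min_days).all(axis=1)
    report = days.rename(columns=lambda c: f"days_{c}").reset_index()
    report["kept"] = kept.to_numpy()
    out = series[series["participant_id"].map(kept).fillna(False)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no participants survive filters")
    return out, ValidityReport(participant_table=report)
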