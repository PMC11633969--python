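"""Reading, validating and regularizing wearable light-logger time series.

The raw substrate is a long-format CSV with one row per logger epoch:
participant id, local wall-clock timestamp, either a precomputed melanopic
EDI column or raw green/blue irradiance channels, a wear flag, and
optionally a condition label (e.g. season).  Column names are mapped
through a small schema dict so arbitrary logger export dialects can be
read without renaming files by hand.

Timestamps are treated as naive local wall-clock time throughout: the day
is local midnight to midnight, and no DST renormalization is attempted.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "EpochTieError",
    "read_light_csv",
    "write_light_csv",
    "detect_dominant_epoch",
    "regularize",
    "write_epoch_csv",
    "read_epoch_csv",
]

#: canonical column names of a raw record table
RAW_COLUMNS = ("participant_id", "timestamp", "green", "blue", "mel_edi", "wear", "condition")

#: canonical column names of a regularized epoch-series table
EPOCH_COLUMNS = ("participant_id", "timestamp", "epoch_s", "mel_edi", "valid", "condition", "day")

_TRUTHY = {"1", "true", "yes", "y", "t", "wear", "worn"}
_FALSY = {"0", "false", "no", "n", "f", "nonwear", "non-wear", "off", "off-wrist"}


class SchemaError(ValueError):
    """A mapped column is missing or the file violates a structural invariant."""


class EpochTieError(ValueError):
    """The modal epoch is ambiguous; carries the tied candidates in seconds."""

    def __init__(self, candidates: Sequence[float]):
        self.candidates = tuple(sorted(candidates))
        super().__init__(
            "dominant epoch is ambiguous; tied candidates (s): "
            + ", ".join(f"{c:g}" for c in self.candidates)
            + " — pass the epoch explicitly"
        )


def _coerce_wear(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float) != 0.0
    s = col.astype(str).str.strip().str.lower()
    unknown = set(s.unique()) - _TRUTHY - _FALSY
    if unknown:
        raise SchemaError(f"wear column has unrecognized values: {sorted(unknown)!r}")
    return s.isin(_TRUTHY)


def _conditions_from_ranges(
    days: pd.Series, ranges: Mapping[str, Sequence]
) -> pd.Series:
    """Assign condition labels from half-open local-date ranges [start, end)."""
    out = pd.Series(pd.NA, index=days.index, dtype="object")
    for label, (start, end) in ranges.items():
        start_d = pd.Timestamp(start).date()
        end_d = pd.Timestamp(end).date()
        mask = (days >= start_d) & (days < end_d)
        out[mask] = label
    return out


def read_light_csv(path, schema: Mapping[str, object]) -> pd.DataFrame:
    """Read a logger CSV into a canonical raw record table.

    Parameters
    ----------
    path
        CSV file (UTF-8, header row).
    schema
        Column mapping with keys ``id``, ``datetime``, ``wear`` and either
        ``mel_edi`` or both ``green`` and ``blue``; optionally ``condition``
        (a column name) or ``condition_ranges`` (mapping label ->
        ``[start_date, end_date)``, half-open on the local calendar date).

    Returns
    -------
    pandas.DataFrame
        Columns from :data:`RAW_COLUMNS` (value channels only if mapped),
        sorted by (participant, timestamp).

    Raises
    ------
    SchemaError
        On missing mapped columns, unparseable timestamps (reported with
        line numbers) or duplicated (participant, timestamp) pairs.
    """
    raw = pd.read_csv(path)
    required = {"id", "datetime", "wear"}
    missing_keys = required - set(schema)
    if missing_keys:
        raise SchemaError(f"schema is missing keys: {sorted(missing_keys)}")
    has_mel = "mel_edi" in schema
    has_gb = "green" in schema and "blue" in schema
    if not (has_mel or has_gb):
        raise SchemaError("schema must map either 'mel_edi' or both 'green' and 'blue'")

    value_keys = [k for k in ("green", "blue", "mel_edi") if k in schema]
    for key in ["id", "datetime", "wear", *value_keys]:
        col = schema[key]
        if col not in raw.columns:
            raise SchemaError(f"mapped column {col!r} (schema key {key!r}) not in file")

    out = pd.DataFrame(
        {
            "participant_id": raw[schema["id"]].astype(str),
            "timestamp": pd.to_datetime(raw[schema["datetime"]], errors="coerce"),
        }
    )
    bad = out["timestamp"].isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"unparseable timestamps at file line(s) {lines[:20]}")
    for key in value_keys:
        vals = pd.to_numeric(raw[schema[key]], errors="coerce")
        out[key] = vals
    out["wear"] = _coerce_wear(raw[schema["wear"]])

    if "condition" in schema and schema["condition"] in raw.columns:
        out["condition"] = raw[schema["condition"]].astype(str)
    elif "condition_ranges" in schema:
        out["condition"] = _conditions_from_ranges(
            out["timestamp"].dt.date, schema["condition_ranges"]
        )

    dup = out.duplicated(subset=["participant_id", "timestamp"])
    if dup.any():
        first = out.loc[dup.idxmax()]
        raise SchemaError(
            f"duplicate (participant, timestamp) pair: "
            f"({first['participant_id']!r}, {first['timestamp']})"
        )
    out = out.sort_values(["participant_id", "timestamp"], kind="mergesort")
    return out.reset_index(drop=True)


def write_light_csv(table: pd.DataFrame, path, schema: Mapping[str, object] | None = None) -> None:
    """Write a raw record table back to CSV (canonical or schema-mapped names)."""
    out = table.copy()
    if schema is not None:
        inverse = {
            "participant_id": schema.get("id"),
            "timestamp": schema.get("datetime"),
            "wear": schema.get("wear"),
            "green": schema.get("green"),
            "blue": schema.get("blue"),
            "mel_edi": schema.get("mel_edi"),
            "condition": schema.get("condition"),
        }
        out = out.rename(columns={k: v for k, v in inverse.items() if v})
    out.to_csv(path, index=False)


def detect_dominant_epoch(records: pd.DataFrame, participant: str) -> float:
    """Return the modal inter-timestamp interval (seconds) for one participant.

    The mode is robust to recording gaps (a gap contributes one oversized
    interval, not enough to displace the dominant epoch).  An ambiguous
    mode raises :class:`EpochTieError` rather than guessing: silently
    misgridding would corrupt every downstream duration.
    """
    ts = records.loc[records["participant_id"] == str(participant), "timestamp"]
    if len(ts) < 2:
        raise ValueError(f"participant {participant!r} has fewer than 2 records")
    diffs = ts.sort_values().diff().dropna().dt.total_seconds()
    counts = diffs.value_counts()
    top = counts[counts == counts.iloc[0]]
    if len(top) > 1:
        raise EpochTieError(top.index.tolist())
    return float(top.index[0])


def _regularize_one(grp: pd.DataFrame, epoch_s: float, value_cols: list[str]) -> pd.DataFrame:
    t = grp["timestamp"].to_numpy(dtype="datetime64[ns]")
    t0 = t[0]
    rel = (t - t0) / np.timedelta64(1, "s")
    n_cells = int(np.floor(rel[-1] / epoch_s)) + 1
    idx = np.rint(rel / epoch_s).astype(np.int64)
    # snapping tolerance is half an epoch by construction of rint
    if idx.max() >= n_cells:
        n_cells = int(idx.max()) + 1
    if len(np.unique(idx)) != len(idx):
        srt = np.sort(idx)
        dup_pos = srt[np.flatnonzero(np.diff(srt) == 0)[0]]
        raise SchemaError(
            f"participant {grp['participant_id'].iloc[0]!r}: two records snap to the "
            f"same grid point (cell {dup_pos}); check the epoch ({epoch_s:g} s)"
        )
    grid_ts = t0 + (np.arange(n_cells) * epoch_s * 1e9).astype("timedelta64[ns]")
    out = pd.DataFrame({"participant_id": grp["participant_id"].iloc[0], "timestamp": grid_ts})
    out["epoch_s"] = epoch_s
    observed = np.zeros(n_cells, dtype=bool)
    observed[idx] = True
    for col in value_cols:
        vals = np.full(n_cells, np.nan)
        vals[idx] = grp[col].to_numpy(dtype=float)
        out[col] = vals
    wear = np.zeros(n_cells, dtype=bool)
    wear[idx] = grp["wear"].to_numpy(dtype=bool)
    out["valid"] = observed & wear
    if "condition" in grp.columns:
        cond = np.full(n_cells, None, dtype=object)
        cond[idx] = grp["condition"].to_numpy(dtype=object)
        # grid cells inherit the condition of their calendar date
        out["condition"] = pd.Series(cond).ffill().bfill()
    out["day"] = out["timestamp"].dt.date
    return out


def regularize(records: pd.DataFrame, epoch_s: float) -> pd.DataFrame:
    """Project raw records onto a contiguous per-participant epoch grid.

    Every participant gets a grid from their first to their last
    observation at spacing ``epoch_s``.  Records are snapped to the
    nearest grid point (logger clock jitter is sub-epoch); a snapping
    collision is an error.  Grid cells fall into three states:

    - observed and worn: ``valid=True``, value kept;
    - observed but flagged non-wear: ``valid=False``, value retained;
    - unobserved gap: ``valid=False``, value missing.

    No value is ever invented: the number of non-missing cells equals the
    number of input records.
    """
    if epoch_s <= 0:
        raise ValueError("epoch must be positive")
    value_cols = [c for c in ("green", "blue", "mel_edi") if c in records.columns]
    if not value_cols:
        raise SchemaError("no value columns (green/blue/mel_edi) to regularize")
    parts = []
    for _, grp in records.groupby("participant_id", sort=True):
        parts.append(_regularize_one(grp.sort_values("timestamp"), float(epoch_s), value_cols))
    return pd.concat(parts, ignore_index=True)


def write_epoch_csv(series: pd.DataFrame, path) -> None:
    cols = [c for c in EPOCH_COLUMNS if c in series.columns]
    series.to_csv(path, index=False, columns=cols)


def read_epoch_csv(path) -> pd.DataFrame:
    out = pd.read_csv(path, parse_dates=["timestamp"])
    out["day"] = pd.to_datetime(out["day"]).dt.date
    out["valid"] = out["valid"].astype(bool)
    return out
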