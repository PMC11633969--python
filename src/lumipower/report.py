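"""Run configuration, pipeline orchestration, summaries and figures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, metrics as metrics_mod, preprocess, power as power_mod

__all__ = [
    "RunConfig",
    "run_pipeline",
    "summarize_metrics",
    "format_hhmm",
    "planned_resamples",
    "plot_power_curves",
]

#: metric columns holding clock times, rendered additionally as hh:mm
TIME_METRICS = ("mtl_above250", "mtl_below10", "m10_mid", "l5_mid")


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the standard analysis values
    (80% day validity, 2 days per condition, 250/1000/10 lx thresholds,
    10/5 h windows, n = 3..50, m = 1000, alpha 0.05, power threshold 0.8)."""

    schema: dict = field(default_factory=dict)
    epoch_s: float | None = None
    day_threshold: float = 0.8
    min_days: int = 2
    zero_fill_nonwear: bool = False
    metric_config: metrics_mod.MetricConfig = field(default_factory=metrics_mod.MetricConfig)
    condition_levels: tuple[str, str] | None = None
    n_min: int = 3
    n_max: int = 50
    m: int = 1000
    alpha_level: float = 0.05
    power_threshold: float = 0.8
    seed: int = 0
    jobs: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mc = raw.pop("metric_config", None)
        cfg = cls(**raw)
        if mc:
            for key in ("tat_thresholds", "metrics"):
                if key in mc:
                    mc[key] = tuple(mc[key])
            cfg.metric_config = metrics_mod.MetricConfig(**mc)
        if cfg.condition_levels is not None:
            cfg.condition_levels = tuple(cfg.condition_levels)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metric_config"] = dataclasses.asdict(self.metric_config)
        return d


def planned_resamples(config: RunConfig) -> int:
    """Total bootstrap resamples the power stage will draw
    (#metrics x #sample sizes x m)."""
    n_metrics = len(config.metric_config.metrics)
    n_sizes = config.n_max - config.n_min + 1
    return n_metrics * n_sizes * config.m


def format_hhmm(decimal_hours: float) -> str:
    """Render decimal hours-of-day as hh:mm, rounding half-up to the minute."""
    if decimal_hours is None or not np.isfinite(decimal_hours):
        return ""
    total_min = int(np.floor(decimal_hours * 60.0 + 0.5))
    h, m = divmod(total_min, 60)
    return f"{h % 24:02d}:{m:02d}"


def summarize_metrics(day_metrics: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) of every metric per condition, plus missing-day counts.

    Quantiles use linear interpolation.  Clock-time metrics additionally
    get hh:mm renderings of the median and quartiles.
    """
    rows = []
    metric_cols = [c for c in day_metrics.columns if c in metrics_mod.METRIC_COLUMNS]
    for cond, grp in day_metrics.groupby("condition", sort=True):
        for col in metric_cols:
            vals = grp[col].dropna()
            rec = {
                "condition": cond,
                "metric": col,
                "n_days": len(grp),
                "days_without_metric": int(grp[col].isna().sum()),
            }
            if len(vals):
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
                rec.update(median=med, q1=q1, q3=q3)
                if col in TIME_METRICS:
                    rec.update(
                        median_hhmm=format_hhmm(med),
                        q1_hhmm=format_hhmm(q1),
                        q3_hhmm=format_hhmm(q3),
                    )
            else:
                rec.update(median=np.nan, q1=np.nan, q3=np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)


def _metrics_with_hhmm(day_metrics: pd.DataFrame) -> pd.DataFrame:
    out = day_metrics.copy()
    for col in TIME_METRICS:
        if col in out.columns:
            out[col + "_hhmm"] = out[col].map(format_hhmm)
    return out


def plot_power_curves(curves, path, threshold: float = 0.8) -> None:
    """Per-metric bar panels of power vs sample size with the threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = list(curves)
    ncols = 3
    nrows = int(np.ceil(len(curves) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.6 * nrows), squeeze=False, sharey=True
    )
    for ax in axes.flat[len(curves):]:
        ax.set_visible(False)
    for ax, curve in zip(axes.flat, curves):
        ns = [r.n for r in curve.rows]
        ps = [r.power for r in curve.rows]
        colors = ["0.7" if p < threshold else "0.35" for p in ps]
        ax.bar(ns, ps, color=colors, width=0.85)
        ax.axhline(threshold, color="red", linestyle="--", linewidth=1)
        ax.set_title(curve.metric, fontsize=10)
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("sample size n")
        ax.set_ylabel("power")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, raw_csv, outdir, log=print) -> dict:
    """Execute preprocess -> metrics -> power and write the artifact bundle.

    Writes ``clean.csv``, ``validity.csv``, ``metrics.csv``,
    ``metrics_summary.csv``, ``power.csv``, ``summary.csv``,
    ``manifest.json`` and ``power_curves.png`` under ``outdir``; returns
    the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = io.read_light_csv(raw_csv, config.schema)
    records = preprocess.add_mel_edi(records)
    if config.epoch_s is not None:
        epoch_s = float(config.epoch_s)
    else:
        epoch_s = io.detect_dominant_epoch(records, records["participant_id"].iloc[0])
    series = io.regularize(records, epoch_s)
    log(f"[preprocess] {records.shape[0]} records -> {series.shape[0]} grid cells @ {epoch_s:g}s")

    series, day_report = preprocess.filter_days(series, config.day_threshold)
    series, part_report = preprocess.filter_participants(series, config.min_days)
    report = preprocess.ValidityReport(
        day_table=day_report.day_table, participant_table=part_report.participant_table
    )
    report.to_csv(outdir / "validity.csv")
    n_days = series.groupby(["participant_id", "day"]).ngroups
    log(
        f"[filter] kept {n_days} participant-days across "
        f"{series['participant_id'].nunique()} participants"
    )
    io.write_epoch_csv(series, outdir / "clean.csv")

    if config.zero_fill_nonwear:
        series = series.copy()
        nw = ~series["valid"] & series["mel_edi"].notna()
        series.loc[nw, "mel_edi"] = 0.0
        series.loc[nw, "valid"] = True

    day_metrics = metrics_mod.compute_day_metrics(series, config.metric_config)
    _metrics_with_hhmm(day_metrics).to_csv(outdir / "metrics.csv", index=False)
    summarize_metrics(day_metrics).to_csv(outdir / "metrics_summary.csv", index=False)
    log(f"[metrics] {len(day_metrics)} participant-day rows")

    metric_cols = [c for c in day_metrics.columns if c in config.metric_config.metrics]
    curves = []
    for metric in metric_cols:
        curve = power_mod.power_curve(
            day_metrics,
            metric,
            n_range=range(config.n_min, config.n_max + 1),
            m=config.m,
            alpha_level=config.alpha_level,
            threshold=config.power_threshold,
            seed=config.seed,
            condition_levels=config.condition_levels,
            jobs=config.jobs,
        )
        curves.append(curve)
        log(f"[power] {metric}: required n = {curve.required_n or 'not reached'}")
    power_table = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    power_table.to_csv(outdir / "power.csv", index=False)
    summary = power_mod.summarize_power(curves)
    summary.to_csv(outdir / "summary.csv", index=False)
    plot_power_curves(curves, outdir / "power_curves.png", config.power_threshold)

    cfg_dict = config.to_dict()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "epoch_s": epoch_s,
        "n_participants": int(series["participant_id"].nunique()),
        "n_days": int(n_days),
        "planned_resamples": planned_resamples(config),
        "executed_resamples": int(power_table["m"].sum()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
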