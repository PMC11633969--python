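"""Bootstrap power curves and minimum required sample size per metric.

For each target sample size ``n``, ``m`` two-level bootstrap resamples of
the daily-metrics table are drawn; each is fitted with the
random-intercept model ``metric ~ 1 + condition + (1 | pseudo_id)`` and
the condition effect tested at ``alpha_level``.  Power at ``n`` is the
fraction of the ``m`` resamples with a significant effect; fits that fail
(degenerate design, zero residual variance, missing condition) count as
*not* significant — dropping them would inflate power at small ``n``
where failures concentrate — and are tallied in ``n_failed``.  The
required sample size is the smallest ``n`` whose power reaches the
threshold (conventionally 0.8).

Randomness is keyed by ``(seed, metric, n, replicate)``: each metric gets
a stable 31-bit sub-seed derived by hashing, below which the bootstrap's
``(n, replicate)`` substreams apply, so results are independent of
evaluation order, scheduling and worker count.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .bootstrap import ResampleSpec, _CellIndex, replicate_rng
from .lmm import LmmFit, fit_random_intercept

__all__ = [
    "PowerRow",
    "PowerCurve",
    "metric_seed",
    "fit_condition_lmm",
    "power_at_n",
    "power_curve",
    "summarize_power",
]


def metric_seed(seed: int, metric: str) -> int:
    """Stable 31-bit sub-seed for one metric under a run seed."""
    digest = hashlib.blake2b(f"{seed}:{metric}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PowerRow:
    n: int
    power: float
    m: int
    n_significant: int
    n_failed: int


@dataclass
class PowerCurve:
    """Per-metric mapping n -> estimated power, with the minimum required n."""

    metric: str
    rows: list[PowerRow]
    threshold: float
    alpha_level: float
    required_n: int | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame([vars(r) for r in self.rows])
        out.insert(0, "metric", self.metric)
        return out

    @property
    def power_at_required_n(self) -> float | None:
        if self.required_n is None:
            return None
        return next(r.power for r in self.rows if r.n == self.required_n)


def _condition_levels(table: pd.DataFrame, levels=None) -> tuple[str, str]:
    if levels is not None:
        return tuple(levels)
    found = list(pd.unique(table["condition"].dropna()))
    if len(found) != 2:
        raise ValueError(f"expected exactly 2 condition levels, found {found!r}")
    return tuple(found)


def fit_condition_lmm(
    resample: pd.DataFrame,
    metric: str,
    condition_levels: tuple[str, str] | None = None,
) -> LmmFit:
    """Fit the random-intercept condition model to one (re)sampled table.

    The grouping factor is ``pseudo_id`` when present (bootstrap output),
    else ``participant_id``.  The first condition level is the reference;
    ``beta`` is the expected change of the metric in the contrast level.
    Rows with a missing metric value are dropped; a table that then lacks
    one of the conditions or a second group yields ``converged=False``.
    """
    ref, contrast = _condition_levels(resample, condition_levels)
    group_col = "pseudo_id" if "pseudo_id" in resample.columns else "participant_id"
    sub = resample[resample["condition"].isin([ref, contrast])]
    ok = sub[metric].notna()
    sub = sub[ok]
    if sub.empty or sub["condition"].nunique() < 2:
        return LmmFit(n_obs=int(ok.sum()))
    y = sub[metric].to_numpy(dtype=float)
    x = (sub["condition"] == contrast).to_numpy(dtype=float)
    codes = pd.factorize(sub[group_col])[0]
    return fit_random_intercept(y, x, codes)


def _power_one_n(
    values: np.ndarray,
    x: np.ndarray,
    group_of_row: np.ndarray,
    cells: list[np.ndarray],
    n_participants: int,
    n: int,
    m: int,
    alpha_level: float,
    seed: int,
) -> PowerRow:
    """Resample + fit loop at one sample size, on pre-extracted arrays."""
    n_sig = 0
    n_failed = 0
    cells_by_participant: list[list[np.ndarray]] = [[] for _ in range(n_participants)]
    for cell in cells:
        cells_by_participant[group_of_row[cell[0]]].append(cell)
    for j in range(m):
        rng = replicate_rng(seed, n, j)
        chosen = rng.integers(n_participants, size=n)
        rows = []
        groups = []
        for pseudo, src in enumerate(chosen):
            for cell in cells_by_participant[src]:
                take = cell[rng.integers(len(cell), size=len(cell))]
                rows.append(take)
                groups.append(np.full(len(take), pseudo, dtype=np.int64))
        ridx = np.concatenate(rows)
        g = np.concatenate(groups)
        yv = values[ridx]
        xv = x[ridx]
        keep = ~np.isnan(yv)
        fit = None
        if keep.any() and np.ptp(xv[keep]) > 0:
            fit = fit_random_intercept(yv[keep], xv[keep], g[keep])
        if fit is not None and fit.converged and np.isfinite(fit.p_value):
            if fit.p_value < alpha_level:
                n_sig += 1
        else:
            n_failed += 1
    return PowerRow(n=n, power=n_sig / m, m=m, n_significant=n_sig, n_failed=n_failed)


def _prepare_arrays(table: pd.DataFrame, metric: str, levels: tuple[str, str]):
    ref, contrast = levels
    sub = table[table["condition"].isin(levels)].reset_index(drop=True)
    values = sub[metric].to_numpy(dtype=float)
    x = (sub["condition"] == contrast).to_numpy(dtype=float)
    pids = pd.unique(sub["participant_id"])
    pid_code = pd.factorize(sub["participant_id"])[0]
    index = _CellIndex(sub, levels)
    cells = [index.cells[key] for key in sorted(index.cells, key=lambda k: (str(k[0]), str(k[1])))]
    return values, x, pid_code, cells, len(pids)


def power_at_n(
    table: pd.DataFrame,
    metric: str,
    n: int,
    m: int = 1000,
    alpha_level: float = 0.05,
    seed: int = 0,
    condition_levels: tuple[str, str] | None = None,
) -> PowerRow:
    """Estimated power for one metric at one target sample size."""
    levels = _condition_levels(table, condition_levels)
    values, x, pid_code, cells, n_src = _prepare_arrays(table, metric, levels)
    return _power_one_n(
        values, x, pid_code, cells, n_src, n, m, alpha_level, metric_seed(seed, metric)
    )


def power_curve(
    table: pd.DataFrame,
    metric: str,
    n_range=range(3, 51),
    m: int = 1000,
    alpha_level: float = 0.05,
    threshold: float = 0.8,
    seed: int = 0,
    condition_levels: tuple[str, str] | None = None,
    jobs: int = 1,
) -> PowerCurve:
    """Power across a range of sample sizes and the minimum n reaching
    the threshold (``required_n`` is None when never reached)."""
    n_list = sorted(n_range)
    if not n_list:
        raise ValueError("n_range must be non-empty")
    levels = _condition_levels(table, condition_levels)
    values, x, pid_code, cells, n_src = _prepare_arrays(table, metric, levels)
    mseed = metric_seed(seed, metric)
    args = [
        (values, x, pid_code, cells, n_src, n, m, alpha_level, mseed) for n in n_list
    ]
    if jobs and jobs != 1:
        rows = Parallel(n_jobs=jobs)(delayed(_power_one_n)(*a) for a in args)
    else:
        rows = [_power_one_n(*a) for a in args]
    curve = PowerCurve(metric=metric, rows=rows, threshold=threshold, alpha_level=alpha_level)
    for row in rows:
        if row.power >= threshold:
            curve.required_n = row.n
            break
    return curve


def summarize_power(curves) -> pd.DataFrame:
    """One row per metric: required n and the power achieved there.

    Metrics are sorted by ascending required n; metrics that never reach
    the threshold sort last and carry a missing ``required_n``.
    """
    rows = []
    for c in curves:
        rows.append(
            {
                "metric": c.metric,
                "required_n": c.required_n,
                "power_at_required_n": c.power_at_required_n,
                "reached": c.required_n is not None,
                "threshold": c.threshold,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["reached", "required_n", "metric"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out
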