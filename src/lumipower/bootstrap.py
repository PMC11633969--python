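"""Two-level (participant -> day) bootstrap of a daily-metrics table.

The hierarchical bootstrap draws, with replacement, *participants* up to a
target sample size ``n``, then — within every drawn participant and
condition cell — redraws that cell's *days* with replacement, preserving
the cell's size.  Resampling both levels propagates inter-individual and
intra-individual variance into every resample, unlike a flat or purely
clustered bootstrap.

Participants drawn more than once receive fresh ``pseudo_id`` labels so a
downstream random-intercept model sees exactly ``n`` groups; ``source_id``
keeps the provenance.

Randomness is counter-based: replicate ``j`` at size ``n`` under ``seed``
uses ``numpy`` ``SeedSequence(seed, spawn_key=(n, j))``, so any single
replicate is reproducible in isolation and results are independent of
scheduling or worker count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["ResampleSpec", "resample_once", "resample_batch", "replicate_rng"]


@dataclass(frozen=True)
class ResampleSpec:
    """Configuration of one bootstrap run at sample size ``n``."""

    n: int
    m: int = 1000
    seed: int = 0
    condition_levels: tuple[str, str] | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.m < 1:
            raise ValueError("m must be >= 1")


def replicate_rng(seed: int, n: int, j: int) -> np.random.Generator:
    """Deterministic substream for replicate ``j`` at sample size ``n``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(n, j)))


class _CellIndex:
    """Row indices of the source table by (participant, condition) cell."""

    def __init__(self, table: pd.DataFrame, condition_levels=None):
        if condition_levels is None:
            condition_levels = tuple(pd.unique(table["condition"].dropna()))
        self.levels = tuple(condition_levels)
        self.participants = list(pd.unique(table["participant_id"]))
        self.cells: dict[tuple[str, str], np.ndarray] = {}
        grouped = table.groupby(["participant_id", "condition"], sort=False).indices
        for (pid, cond), idx in grouped.items():
            self.cells[(pid, cond)] = np.asarray(idx)

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """(row indices, pseudo-group codes) of one two-level resample."""
        chosen = rng.integers(len(self.participants), size=n)
        rows: list[np.ndarray] = []
        groups: list[np.ndarray] = []
        for pseudo, src in enumerate(chosen):
            pid = self.participants[src]
            for cond in self.levels:
                cell = self.cells.get((pid, cond))
                if cell is None or len(cell) == 0:
                    continue  # empty cell stays empty; model fitting copes
                take = rng.integers(len(cell), size=len(cell))
                rows.append(cell[take])
                groups.append(np.full(len(cell), pseudo, dtype=np.int64))
        return np.concatenate(rows), np.concatenate(groups)


def resample_once(
    table: pd.DataFrame,
    spec: ResampleSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One two-level resample of a daily-metrics table.

    Returns the resampled rows with two extra columns: ``pseudo_id`` (a
    fresh label ``B0000``.. per drawn participant slot, exactly ``spec.n``
    distinct values) and ``source_id`` (the original participant).
    """
    index = _CellIndex(table, spec.condition_levels)
    rows, groups = index.draw(spec.n, rng)
    out = table.iloc[rows].reset_index(drop=True)
    out = out.rename(columns={"participant_id": "source_id"})
    out.insert(0, "pseudo_id", np.array([f"B{g:04d}" for g in groups]))
    return out


def resample_batch(table: pd.DataFrame, spec: ResampleSpec) -> Iterator[pd.DataFrame]:
    """``spec.m`` independent resamples, one deterministic substream each."""
    for j in range(spec.m):
        yield resample_once(table, spec, replicate_rng(spec.seed, spec.n, j))
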