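"""Synthetic inputs with the statistical structure the method assumes.

Two generator tiers:

* :func:`generate_day_metrics` draws day-level metric values directly from
  the random-intercept generative model
  ``y = alpha + beta*1[condition = contrast] + b_p + e`` with
  ``b_p ~ N(0, sigma_b^2)`` and ``e ~ N(0, sigma^2)`` — the fast path for
  exercising the bootstrap and power machinery.
* :func:`generate_epoch_series` emits raw logger records: a square-wave
  diurnal profile per condition (dim night baseline, bright plateau
  between lights-on and lights-off) multiplied by lognormal epoch noise
  and a lognormal participant level (random intercept on the log scale),
  with optional non-wear blocks — the full path through reading,
  regularization, filtering and metric computation.

Defaults for the epoch tier loosely mimic a central-European winter/summer
contrast for day workers (winter: ~70 lx plateau 07:00-17:00; summer:
~400 lx plateau 06:00-20:00; 0.05 lx nights) without claiming to
reproduce any particular cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenerativeSpec",
    "DiurnalSpec",
    "generate_day_metrics",
    "generate_epoch_series",
]


@dataclass(frozen=True)
class GenerativeSpec:
    """Parameters of the day-level random-intercept generative model."""

    n_participants: int = 13
    days_per_condition: int = 3
    alpha: float = 0.0
    beta: float = 0.0
    sigma_b: float = 1.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.sigma_b < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.days_per_condition < 1:
            raise ValueError("need at least one day per condition")


def generate_day_metrics(
    spec: GenerativeSpec,
    conditions: tuple[str, str] = ("summer", "winter"),
    metric: str = "metric",
) -> pd.DataFrame:
    """Day-level metric table drawn from the generative model.

    The second condition is the contrast level receiving ``beta``.
    Reproducible from ``spec.seed``; one row per participant-day.
    """
    rng = np.random.default_rng(spec.seed)
    ref, contrast = conditions
    n, d = spec.n_participants, spec.days_per_condition
    b = rng.normal(0.0, spec.sigma_b, size=n)
    rows = []
    for p in range(n):
        pid = f"P{p + 1:04d}"
        for ci, cond in enumerate((ref, contrast)):
            e = rng.normal(0.0, spec.sigma, size=d)
            y = spec.alpha + spec.beta * (cond == contrast) + b[p] + e
            for day_idx in range(d):
                rows.append(
                    {
                        "participant_id": pid,
                        "day": f"{cond}-{day_idx + 1}",
                        "condition": cond,
                        metric: y[day_idx],
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiurnalSpec:
    """Shape of the synthetic diurnal light profile, per condition.

    ``day_level``/``lights_on``/``lights_off`` map condition label to the
    plateau level (lx) and its clock-hour bounds.  ``lognormal_noise_sd``
    and ``participant_level_sd`` are epoch- and participant-level SDs in
    log10 units (multiplicative noise and random intercept respectively).
    ``nonwear`` lists (start hour, duration h, probability per day) blocks.
    """

    epoch_s: float = 60.0
    baseline_night: float = 0.05
    day_level: dict = field(default_factory=lambda: {"winter": 70.0, "summer": 400.0})
    lights_on: dict = field(default_factory=lambda: {"winter": 7.0, "summer": 6.0})
    lights_off: dict = field(default_factory=lambda: {"winter": 17.0, "summer": 20.0})
    lognormal_noise_sd: float = 0.2
    participant_level_sd: float = 0.15
    nonwear: tuple = ()

    def __post_init__(self):
        for cond in self.day_level:
            on, off = self.lights_on[cond], self.lights_off[cond]
            if not (0 <= on < off <= 24):
                raise ValueError(f"need 0 <= lights_on < lights_off <= 24 for {cond!r}")
            if self.day_level[cond] < 0 or self.baseline_night < 0:
                raise ValueError("light levels must be non-negative")


#: arbitrary full-week anchors for the two data-collection periods
_CONDITION_START = {"winter": "2015-01-12", "summer": "2015-06-15"}


def generate_epoch_series(
    spec: DiurnalSpec,
    n_participants: int = 13,
    days_per_condition: int = 5,
    conditions: tuple[str, str] = ("winter", "summer"),
    seed: int = 0,
) -> pd.DataFrame:
    """Raw logger record table with diurnal structure and non-wear gaps.

    Emits the canonical raw-record layout (``participant_id, timestamp,
    mel_edi, wear, condition``) that :func:`lumipower.io.regularize`
    consumes, covering whole calendar days (midnight to midnight) so that
    day-validity fractions behave as in a continuous field recording.
    """
    rng = np.random.default_rng(seed)
    per_day = int(round(24 * 3600 / spec.epoch_s))
    tod_h = np.arange(per_day) * (spec.epoch_s / 3600.0)
    frames = []
    for p in range(n_participants):
        pid = f"P{p + 1:04d}"
        level_mult = 10.0 ** rng.normal(0.0, spec.participant_level_sd)
        for cond in conditions:
            start = pd.Timestamp(_CONDITION_START.get(cond, "2015-03-02"))
            on, off = spec.lights_on[cond], spec.lights_off[cond]
            plateau = spec.day_level[cond]
            for d in range(days_per_condition):
                day0 = start + pd.Timedelta(days=d)
                ts = day0 + pd.to_timedelta(np.arange(per_day) * spec.epoch_s, unit="s")
                base = np.where(
                    (tod_h >= on) & (tod_h < off), plateau * level_mult, spec.baseline_night
                )
                noise = 10.0 ** rng.normal(0.0, spec.lognormal_noise_sd, size=per_day)
                values = base * noise
                wear = np.ones(per_day, dtype=bool)
                for start_h, dur_h, prob in spec.nonwear:
                    if rng.random() < prob:
                        block = (tod_h >= start_h) & (tod_h < start_h + dur_h)
                        wear[block] = False
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "timestamp": ts,
                            "mel_edi": values,
                            "wear": wear,
                            "condition": cond,
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)
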