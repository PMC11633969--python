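"""Independent brute-force oracles for the daily metrics.

Deliberately naive (plain Python loops, no vectorization, no shared code
with the package) so they provide an independent route to the same
quantities.  Missing is represented as float('nan').
"""

import math

import numpy as np


def gm_oracle(values, floor):
    logs = [math.log10(max(v, floor)) for v in values]
    if not logs:
        return math.nan
    return 10.0 ** (sum(logs) / len(logs))


def gsd_oracle(values, floor):
    logs = [math.log10(max(v, floor)) for v in values]
    n = len(logs)
    if n < 2:
        return math.nan
    mean = sum(logs) / n
    var = sum((x - mean) ** 2 for x in logs) / (n - 1)
    return 10.0 ** math.sqrt(var)


def le_oracle(values, delta_h):
    total = 0.0
    for v in values:
        total += v * delta_h
    return total


def tat_oracle(values, delta_h, threshold):
    count = 0
    for v in values:
        if v > threshold:
            count += 1
    return count * delta_h


def mtl_oracle(values, mid_times, threshold, direction):
    picked = []
    for v, t in zip(values, mid_times):
        if (direction == "above" and v > threshold) or (
            direction == "below" and v < threshold
        ):
            picked.append(t)
    if not picked:
        return math.nan
    return sum(picked) / len(picked)


def iv_oracle(times_h, values, valid):
    """Hourly-bin Van Someren ratio: mean squared clock-adjacent successive
    difference over population variance of the hourly means."""
    bins = {}
    for t, v, ok in zip(times_h, values, valid):
        if ok:
            bins.setdefault(int(math.floor(t)), []).append(v)
    hours = sorted(bins)
    if len(hours) < 2:
        return math.nan
    means = {h: sum(bins[h]) / len(bins[h]) for h in hours}
    diffs = []
    for a, b in zip(hours, hours[1:]):
        if b - a == 1:
            diffs.append((means[b] - means[a]) ** 2)
    if not diffs:
        return math.nan
    xbar = sum(means.values()) / len(means)
    var = sum((means[h] - xbar) ** 2 for h in hours) / len(hours)
    if var == 0:
        return math.nan
    return (sum(diffs) / len(diffs)) / var


def window_oracle(times_h, values, valid, delta_h, width_h, mode, min_coverage):
    """Exhaustive scan of every window start; earliest extreme wins."""
    k = int(round(width_h / delta_h))
    n = len(values)
    if k <= 0 or k > n:
        return math.nan, math.nan
    best_score, best_start = None, None
    for start in range(n - k + 1):
        inside_vals = [values[i] for i in range(start, start + k) if valid[i]]
        if len(inside_vals) < max(1, min_coverage * k):
            continue
        score = sum(inside_vals) / len(inside_vals)
        better = (
            best_score is None
            or (mode == "brightest" and score > best_score)
            or (mode == "darkest" and score < best_score)
        )
        if better:
            best_score, best_start = score, start
    if best_score is None:
        return math.nan, math.nan
    return best_score, times_h[best_start] + width_h / 2.0


def random_day(rng, delta_h=1 / 30):
    """A random synthetic day grid: lognormal values, random validity."""
    n = int(round(24 / delta_h))
    times = np.arange(n) * delta_h
    values = 10.0 ** rng.normal(rng.uniform(-1, 2.5), rng.uniform(0.3, 1.5), size=n)
    valid = rng.random(n) > rng.uniform(0.0, 0.4)
    if valid.sum() < 4:
        valid[:4] = True
    values[~valid] = np.where(rng.random((~valid).sum()) < 0.5, np.nan, values[~valid])
    return times, values, valid
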