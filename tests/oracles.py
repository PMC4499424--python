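"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the implementation's code paths (no calls into
pkval.nca / pkval.validation internals): plain loops, explicit normal
equations and dense numerical integration.
"""

import math

import numpy as np


def dense_linear_auc(times, conc, n_sub=10_000):
    """Integrate the piecewise-linear interpolant on a dense grid.

    The grid is the union of a uniform 10^4-point grid and the breakpoints,
    so the interpolant is integrated exactly (up to rounding).
    """
    times = np.asarray(times, dtype=float)
    grid = np.union1d(np.linspace(times[0], times[-1], n_sub + 1), times)
    vals = np.interp(grid, times, np.asarray(conc, dtype=float))
    total = 0.0
    for i in range(grid.size - 1):
        total += (grid[i + 1] - grid[i]) * (vals[i] + vals[i + 1]) / 2.0
    return total


def ols_line(x, y):
    """Straight-line least squares via explicit normal equations."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def mean_sd(values):
    """Arithmetic mean and sample SD (n−1) by explicit summation."""
    values = [float(v) for v in values]
    n = len(values)
    m = sum(values) / n
    var = sum((v - m) ** 2 for v in values) / (n - 1)
    return m, math.sqrt(var)


def precision_accuracy_rows(records):
    """Per-level mean/SD/RSD%/RE% from (level, value) pairs, loop-based."""
    by_level = {}
    for level, value in records:
        by_level.setdefault(float(level), []).append(float(value))
    rows = {}
    for level in sorted(by_level):
        vals = by_level[level]
        if len(vals) < 2:
            continue
        m, s = mean_sd(vals)
        rows[level] = {
            "measured_mean": m,
            "sd": s,
            "rsd_pct": 100.0 * s / m,
            "re_pct": 100.0 * abs(level - m) / level,
        }
    return rows


def recovery_oracle(processed, reference):
    ref_mean = sum(reference) / len(reference)
    ratios = [100.0 * p / ref_mean for p in processed]
    m, s = (ratios[0], 0.0) if len(ratios) == 1 else mean_sd(ratios)
    return m, s


def stability_oracle(rows, reference_by_level):
    """(condition, level) -> mean % remained and stability flag, loop-based."""
    grouped = {}
    for cond, level, value in rows:
        grouped.setdefault((cond, float(level)), []).append(float(value))
    out = {}
    for key, vals in grouped.items():
        ref = reference_by_level[key[1]]
        pct = [100.0 * v / ref for v in vals]
        m = sum(pct) / len(pct)
        out[key] = (m, abs(100.0 - m) <= 5.0)
    return out
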