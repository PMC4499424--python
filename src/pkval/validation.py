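"""Precision, accuracy, recovery and stability statistics for assay validation.

Conventions of the validated bioanalytical method:

* precision is RSD% = 100 × sample SD / mean of replicate measurements;
* accuracy is RE% = 100 × |nominal − measured mean| / nominal;
* a QC level passes when both RSD% and RE% are ≤ 15, relaxed to ≤ 20 at the
  LOQ level;
* a storage condition is stable when the remaining fraction deviates from
  100% by at most 5 percentage points.

Intra-day statistics use one analytical day's replicates; inter-day
statistics pool every replicate across days into a single mean/SD per level
(matching a single summary row per level, rather than averaging day means).
Sample SD uses the n−1 denominator throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import DomainError

ACCEPTANCE_LIMIT_PCT = 15.0
ACCEPTANCE_LIMIT_LOQ_PCT = 20.0
STABILITY_TOLERANCE_PCT = 5.0


def relative_error(nominal: float, measured_mean: float) -> float:
    """Accuracy as RE% = 100 × |nominal − measured| / nominal."""
    if not nominal > 0:
        raise DomainError("nominal concentration must be positive")
    return 100.0 * abs(nominal - measured_mean) / nominal


def rsd(measurements) -> float:
    """Precision as RSD% = 100 × sample SD / mean of replicate measurements."""
    x = np.asarray(measurements, dtype=float)
    if x.size < 2:
        raise ValueError("RSD needs at least 2 measurements")
    mean = x.mean()
    if not mean > 0:
        raise DomainError("mean of measurements must be positive")
    return 100.0 * x.std(ddof=1) / mean


def rsd_from_summary(mean: float, sd: float) -> float:
    """RSD% from a reported mean and SD."""
    if not mean > 0:
        raise DomainError("mean must be positive")
    if sd < 0:
        raise DomainError("sd must be non-negative")
    return 100.0 * sd / mean


def _level_rows(grouped) -> pd.DataFrame:
    records = []
    for level, values in grouped:
        if values.size < 2:
            warnings.warn(
                f"level {level:g} ng/mL has fewer than 2 replicates; skipped",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        m = values.mean()
        s = values.std(ddof=1)
        records.append(
            {
                "level_ng_per_ml": level,
                "n": int(values.size),
                "measured_mean": m,
                "sd": s,
                "rsd_pct": rsd_from_summary(m, s),
                "re_pct": relative_error(level, m),
            }
        )
    return pd.DataFrame.from_records(records).sort_values("level_ng_per_ml").reset_index(drop=True)


def intraday_table(batch: pd.DataFrame, day=None) -> pd.DataFrame:
    """Within-day precision and accuracy, one row per QC level.

    ``batch`` holds columns ``level_ng_per_ml``, ``day``, ``replicate``,
    ``value``. ``day`` selects the analytical day (default: the first day
    present). Levels with fewer than 2 replicates are skipped with a warning.
    """
    if day is None:
        day = batch["day"].min()
    sub = batch[batch["day"] == day]
    if sub.empty:
        raise ValueError(f"no measurements for day {day!r}")
    grouped = ((lvl, g["value"].to_numpy(dtype=float)) for lvl, g in sub.groupby("level_ng_per_ml"))
    return _level_rows(grouped)


def interday_table(batch: pd.DataFrame) -> pd.DataFrame:
    """Between-day precision and accuracy, pooling all replicates across days."""
    if batch["day"].nunique() < 2:
        raise ValueError("inter-day statistics need >= 2 distinct days; use intraday_table")
    grouped = ((lvl, g["value"].to_numpy(dtype=float)) for lvl, g in batch.groupby("level_ng_per_ml"))
    return _level_rows(grouped)


def acceptance_flags(rows: pd.DataFrame, loq_level: float) -> pd.DataFrame:
    """Annotate a precision/accuracy table with the pass/fail rule.

    A level passes when RSD% ≤ 15 and RE% ≤ 15; at the LOQ level both limits
    relax to 20. Comparison is inclusive (values *higher than* the limit are
    rejected). Returns a copy with ``limit_pct`` and ``pass_flag`` columns.
    """
    out = rows.copy()
    limits = np.where(
        np.isclose(out["level_ng_per_ml"], loq_level),
        ACCEPTANCE_LIMIT_LOQ_PCT,
        ACCEPTANCE_LIMIT_PCT,
    )
    out["limit_pct"] = limits
    out["pass_flag"] = (out["rsd_pct"] <= limits) & (out["re_pct"] <= limits)
    return out


def recovery(processed_responses, reference_responses) -> tuple[float, float]:
    """Extraction recovery: processed-sample response relative to neat standard.

    Returns (recovery %, SD %) where recovery = 100 × mean(processed) /
    mean(reference) and the SD is that of the per-replicate processed
    responses expressed against the reference mean.
    """
    p = np.asarray(processed_responses, dtype=float)
    r = np.asarray(reference_responses, dtype=float)
    if p.size == 0 or r.size == 0:
        raise ValueError("both response lists must be non-empty")
    ref_mean = r.mean()
    if not ref_mean > 0:
        raise DomainError("reference mean response must be positive")
    ratios = 100.0 * p / ref_mean
    sd = ratios.std(ddof=1) if p.size > 1 else 0.0
    return float(ratios.mean()), float(sd)


def stability_rows(measured_by_condition: pd.DataFrame, reference_by_level) -> pd.DataFrame:
    """Percent remaining per storage condition and level, with stability flag.

    ``measured_by_condition`` has columns ``condition``, ``level_ng_per_ml``,
    ``value`` (replicate measured concentrations); ``reference_by_level`` maps
    level -> initial/nominal concentration. Stable when |100 − % remained| ≤ 5.
    """
    records = []
    for (cond, level), g in measured_by_condition.groupby(["condition", "level_ng_per_ml"], sort=False):
        ref = float(reference_by_level[level])
        if not ref > 0:
            raise DomainError("reference concentration must be positive")
        pct = 100.0 * g["value"].to_numpy(dtype=float) / ref
        mean_pct = pct.mean()
        records.append(
            {
                "condition": cond,
                "level_ng_per_ml": level,
                "pct_remained": mean_pct,
                "sd": pct.std(ddof=1) if pct.size > 1 else 0.0,
                "stable_flag": abs(100.0 - mean_pct) <= STABILITY_TOLERANCE_PCT,
            }
        )
    return pd.DataFrame.from_records(records)
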