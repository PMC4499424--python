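"""Synthetic concentration–time cohorts, calibration and QC batches.

The generator emulates the structure of a single-dose IV-bolus rat study:
a tri-exponential disposition curve sampled at a 12-point schedule over 48 h
in n=6 animals, measured by an assay with a 5 ng/mL lower limit of
quantification, a 5–1000 ng/mL calibration range and 10-fold dilution of
over-range samples. Default macro-constants are illustrative — chosen so the
terminal half-life is 7.88 h, total exposure ~9.0 µg·h/mL, mean residence
time ~5.9 h and the 48-h concentration stays just above the 5 ng/mL limit —
not a reproduction of any measured curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    AssayConfig,
    ConcentrationTimeProfile,
    DispositionParams,
    NoiseModel,
    ResponseModel,
    SamplingSchedule,
)

#: Illustrative tri-exponential disposition: fast distribution, intermediate
#: and terminal elimination phases. Terminal rate 0.0879 1/h = 0.693/7.88.
DEFAULT_DISPOSITION = DispositionParams(
    terms=((4150.0, 3.0), (1665.0, 0.45), (345.0, 0.0879)),
    dose=5000.0,
)

#: Calibration standards, ng/mL.
DEFAULT_CALIBRATION_LEVELS = (5.0, 10.0, 20.0, 50.0, 70.0, 100.0, 200.0, 500.0, 700.0, 1000.0)

#: Quality-control sample levels, ng/mL.
DEFAULT_QC_LEVELS = (10.0, 50.0, 100.0, 500.0, 1000.0)


def model_concentration(params: DispositionParams, t):
    """Noise-free sum-of-exponentials concentration at time(s) ``t`` (hours).

    C(t) = sum_i A_i exp(-lambda_i t); scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    a = params.coefficients
    lam = params.rates
    c = np.sum(a * np.exp(-t_arr[..., None] * lam), axis=-1)
    return float(c) if t_arr.ndim == 0 else c


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative jitter with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_profile(
    params: DispositionParams,
    schedule: SamplingSchedule = SamplingSchedule(),
    noise: NoiseModel = NoiseModel(),
    seed=None,
    subject_id: str = "subj-1",
    _rng: np.random.Generator | None = None,
) -> ConcentrationTimeProfile:
    """Simulate one subject's measured profile.

    Each observation is ``model × (1 + proportional deviate) + additive
    deviate``, truncated below at zero. Deterministic for a fixed seed.
    ``inter_subject_cv`` is ignored here; it acts at the cohort level.
    """
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    t = schedule.as_array()
    c = model_concentration(params, t)
    if noise.proportional_cv > 0:
        c = c * (1 + rng.normal(0, noise.proportional_cv, size=t.size))
    if noise.additive_sd > 0:
        c = c + rng.normal(0, noise.additive_sd, size=t.size)
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    return ConcentrationTimeProfile(
        subject_id=subject_id, dose=params.dose, times=t, concentrations=c
    )


def simulate_cohort(
    params: DispositionParams = DEFAULT_DISPOSITION,
    schedule: SamplingSchedule = SamplingSchedule(),
    noise: NoiseModel = NoiseModel(),
    n_subjects: int = 6,
    seed=None,
) -> list[ConcentrationTimeProfile]:
    """Simulate an independent cohort (default n=6, the study design).

    Between-animal variability enters as a unit-mean lognormal multiplier on
    each subject's exponential coefficients (rates untouched), then per-sample
    assay noise is applied.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        jitter = _lognormal_unit_mean(rng, noise.inter_subject_cv, len(params.terms))
        terms = tuple(
            (a * j, lam) for (a, lam), j in zip(params.terms, jitter)
        )
        subject_params = DispositionParams(terms=terms, dose=params.dose)
        profiles.append(
            simulate_profile(
                subject_params,
                schedule,
                noise,
                subject_id=f"subj-{i + 1}",
                _rng=rng,
            )
        )
    return profiles


def apply_assay(
    profile: ConcentrationTimeProfile, assay: AssayConfig = AssayConfig()
) -> ConcentrationTimeProfile:
    """Flag records against the assay's quantification limits.

    Values below the LLOQ are marked below-limit (kept, but unusable
    downstream); values above the ULOQ are marked as assayed after dilution
    (provenance only — the value itself is already on the undiluted scale).
    Numeric values are never altered. The returned profile's ``n_usable``
    property gives the count of quantifiable records.
    """
    c = profile.concentrations
    return ConcentrationTimeProfile(
        subject_id=profile.subject_id,
        dose=profile.dose,
        times=profile.times,
        concentrations=c,
        blq_flags=c < assay.lloq,
        diluted_flags=c > assay.uloq,
    )


def simulate_calibration_batch(
    rm: ResponseModel = ResponseModel(),
    levels=DEFAULT_CALIBRATION_LEVELS,
    replicates: int = 1,
    seed=None,
) -> pd.DataFrame:
    """Simulate peak-area-ratio responses of calibration standards.

    Returns a table with columns ``level_ng_per_ml``, ``replicate``,
    ``response``: response = slope·level + intercept, perturbed by a
    proportional deviate with CV ``rm.response_cv``.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("calibration levels must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        mean = rm.response(levels)
        resp = mean * (1 + rng.normal(0, rm.response_cv, size=levels.size)) if rm.response_cv > 0 else mean
        rows.append(
            pd.DataFrame(
                {"level_ng_per_ml": levels, "replicate": rep, "response": resp}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_qc_batch(
    levels=DEFAULT_QC_LEVELS,
    replicates_per_day: int = 5,
    days: int = 3,
    intraday_cv: float = 0.03,
    interday_cv: float = 0.03,
    seed=None,
) -> pd.DataFrame:
    """Simulate replicate QC measurements over one or more analytical days.

    measured = level × (1 + day effect) × (1 + replicate effect), with the
    day effect shared by every measurement of that day. The default layout is
    the validation design: 5 levels × 5 replicates per day × 3 days.

    Returns a table with columns ``level_ng_per_ml``, ``day``, ``replicate``,
    ``value`` (measured concentration, ng/mL).
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("QC levels must be positive")
    if replicates_per_day < 1 or days < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for day in range(1, days + 1):
        day_effect = rng.normal(0, interday_cv) if interday_cv > 0 else 0.0
        for level in levels:
            for rep in range(1, replicates_per_day + 1):
                rep_effect = rng.normal(0, intraday_cv) if intraday_cv > 0 else 0.0
                records.append(
                    {
                        "level_ng_per_ml": level,
                        "day": day,
                        "replicate": rep,
                        "value": level * (1 + day_effect) * (1 + rep_effect),
                    }
                )
    return pd.DataFrame.from_records(records)
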