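"""Core containers shared across the pharmacokinetic and validation modules.

Concentrations are in ng/mL, times in hours, doses in µg per kg body weight
throughout; conversion to the µg·h/mL scale used for exposure parameters
happens inside the analysis, never at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's IV-bolus plasma concentration–time course.

    Parameters
    ----------
    subject_id : str
        Label for the animal/subject.
    dose : float
        Administered dose in µg per kg body weight.
    times : array-like of float
        Sampling times in hours, strictly increasing, all >= 0.
    concentrations : array-like of float
        Measured plasma concentrations in ng/mL, all >= 0.
    blq_flags : array-like of bool, optional
        True where the value is below the lower limit of quantification.
        Flagged records keep their numeric value but are excluded from
        regression and area calculations.
    diluted_flags : array-like of bool, optional
        True where the value was assayed after dilution because it exceeded
        the upper limit of the calibration range (provenance only).
    """

    subject_id: str
    dose: float
    times: np.ndarray
    concentrations: np.ndarray
    blq_flags: np.ndarray = None
    diluted_flags: np.ndarray = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.ndim != 1 or conc.shape != times.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if times.size and times[0] < 0:
            raise ValueError("sampling times must be >= 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"sampling times must be strictly increasing (subject {self.subject_id!r})"
            )
        if np.any(conc < 0):
            raise ValueError(
                f"concentrations must be non-negative (subject {self.subject_id!r})"
            )
        blq = self.blq_flags
        blq = np.zeros(times.size, dtype=bool) if blq is None else np.asarray(blq, dtype=bool)
        dil = self.diluted_flags
        dil = np.zeros(times.size, dtype=bool) if dil is None else np.asarray(dil, dtype=bool)
        if blq.shape != times.shape or dil.shape != times.shape:
            raise ValueError("flag arrays must match the number of samples")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "blq_flags", blq)
        object.__setattr__(self, "diluted_flags", dil)

    def __len__(self) -> int:
        return self.times.size

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of records usable for NCA (not below-limit)."""
        return ~self.blq_flags

    @property
    def n_usable(self) -> int:
        """Number of quantifiable (non-BLQ) records."""
        return int(self.usable.sum())


@dataclass(frozen=True)
class DispositionParams:
    """Sum-of-exponentials macro-constants for an IV-bolus disposition curve.

    ``terms`` is an ordered list of (coefficient ng/mL, rate 1/h) pairs,
    fastest phase first; the model curve is C(t) = sum_i A_i * exp(-l_i * t)
    so the value at t=0 equals the sum of coefficients.
    """

    terms: tuple
    dose: float = 5000.0  # µg/kg; the study design's 5 mg/kg

    def __post_init__(self):
        terms = tuple((float(a), float(l)) for a, l in self.terms)
        if len(terms) < 1:
            raise ValueError("at least one exponential term is required")
        if any(a <= 0 for a, _ in terms) or any(l <= 0 for _, l in terms):
            raise ValueError("coefficients and rates must be positive")
        rates = [l for _, l in terms]
        if any(r2 >= r1 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError("rates must be strictly decreasing (fastest phase first)")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        object.__setattr__(self, "terms", terms)

    @property
    def c0(self) -> float:
        """Model concentration at t=0 (sum of coefficients), ng/mL."""
        return sum(a for a, _ in self.terms)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([a for a, _ in self.terms])

    @property
    def rates(self) -> np.ndarray:
        return np.array([l for _, l in self.terms])

    @property
    def terminal_rate(self) -> float:
        """Slowest (terminal) exponential rate, 1/h."""
        return self.terms[-1][1]

    @property
    def auc_inf(self) -> float:
        """Analytic AUC from zero to infinity, ng·h/mL (= sum A_i / l_i)."""
        return float(np.sum(self.coefficients / self.rates))

    @property
    def aumc_inf(self) -> float:
        """Analytic first-moment area, ng·h²/mL (= sum A_i / l_i**2)."""
        return float(np.sum(self.coefficients / self.rates**2))


@dataclass(frozen=True)
class SamplingSchedule:
    """Blood-sampling times in hours, strictly increasing and non-negative.

    The default is the rat-study design: 5 min then 0.25, 0.5, 1, 2, 4, 6, 8,
    10, 12, 24 and 48 h post-dose.
    """

    times: tuple = (0.0833, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0, 48.0)

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        if len(times) == 0:
            raise ValueError("schedule must contain at least one time")
        if times[0] < 0:
            raise ValueError("times must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class NoiseModel:
    """Assay + biological noise configuration for the simulator.

    proportional_cv is the coefficient of variation of the multiplicative
    measurement error; additive_sd (ng/mL) models baseline noise near the
    quantification limit; inter_subject_cv jitters each subject's exponential
    coefficients multiplicatively (lognormal, unit mean). All zero makes the
    simulator output exactly the deterministic model curve.
    """

    proportional_cv: float = 0.10
    additive_sd: float = 0.0
    inter_subject_cv: float = 0.20

    def __post_init__(self):
        for name in ("proportional_cv", "additive_sd", "inter_subject_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def silent(self) -> bool:
        return self.proportional_cv == 0 and self.additive_sd == 0 and self.inter_subject_cv == 0


NOISE_FREE = NoiseModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class AssayConfig:
    """Quantification limits and dilution policy of the bioanalytical assay."""

    lloq: float = 5.0  # ng/mL
    uloq: float = 1000.0  # ng/mL, top of the calibration range
    dilution_factor: float = 10.0

    def __post_init__(self):
        if not 0 < self.lloq < self.uloq:
            raise ValueError("require 0 < lloq < uloq")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")


@dataclass(frozen=True)
class ResponseModel:
    """Linear detector response: peak-area ratio = slope·conc + intercept.

    Defaults reproduce the validated assay's printed regression
    (slope 0.0015 per ng/mL, intercept -0.0087).
    """

    slope: float = 0.0015
    intercept: float = -0.0087
    response_cv: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.response_cv < 0:
            raise ValueError("response_cv must be >= 0")

    def response(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept
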