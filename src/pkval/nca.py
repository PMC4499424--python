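"""Noncompartmental analysis (NCA) of IV-bolus plasma concentration data.

The analysis estimates the terminal elimination rate constant K (lambda_z) by
least-squares regression of log concentration on time over the terminal
log-linear region, then derives

    t1/2    = 0.693 / K
    AUC0-inf = trapezoidal area to the last quantifiable sample + C_last / K
    AUMC0-inf = trapezoidal area of C·t + C_last·t_last/K + C_last/K**2
    MRT     = AUMC0-inf / AUC0-inf
    Cl      = Dose / AUC0-inf
    Vss     = Cl × MRT  (conventional)   or   Cl / MRT  ("ratio" variant)

Both Vss variants are computed because the source protocol this package
reproduces defines Vss as Cl/MRT — dimensionally a volume per time squared,
but numerically the quantity its reference table reports — while the standard
pharmacokinetic relation is Cl × MRT. Half-life deliberately uses the literal
constant 0.693 rather than ln 2 (difference < 0.03%) to match the protocol's
stated formula.

Units: times h, concentrations ng/mL at input, dose µg/kg; concentrations are
converted to µg/mL before integration so AUC is reported in µg·h/mL, Cl in
mL·kg⁻¹·h⁻¹ and Vss in mL·kg⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConcentrationTimeProfile, DomainError

#: Half-life constant as stated by the protocol (not ln 2 = 0.693147...).
HALF_LIFE_CONSTANT = 0.693

#: ng/mL -> µg/mL, applied before area calculations.
CONC_TO_UG_PER_ML = 1e-3


class UnestimableError(RuntimeError):
    """The terminal phase (or a quantity depending on it) cannot be estimated."""


# ---------------------------------------------------------------------------
# terminal-phase regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminalFit:
    """Log-linear least-squares fit of the terminal elimination phase.

    ``lambda_z`` is the negative slope of ln(concentration) vs time (the
    elimination rate constant K, 1/h); NaN when the phase is not estimable
    (non-declining data). ``intercept_log`` is the fitted ln-concentration at
    t=0 of the terminal line.
    """

    lambda_z: float
    intercept_log: float
    n_points: int
    window: tuple
    r_squared: float
    adjusted_r_squared: float

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.lambda_z) and self.lambda_z > 0


def _ols_loglinear(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float, float]:
    """Plain OLS of logc on t; returns slope, intercept, r², adjusted r²."""
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), r2, adj


def fit_terminal_phase(
    profile: ConcentrationTimeProfile, selection="auto"
) -> TerminalFit:
    """Fit the terminal log-linear decline of a profile.

    Parameters
    ----------
    profile : ConcentrationTimeProfile
        Below-limit records and zero concentrations are excluded.
    selection : "auto" or (t_start, t_end)
        Manual mode regresses over all usable points inside the closed time
        window. Automatic mode evaluates every suffix of >= 3 points strictly
        after the observed peak, picks the fit with the highest adjusted r²
        and breaks ties toward more points — the usual pharmacometric
        best-fit convention.

    Raises
    ------
    UnestimableError
        Fewer than 3 positive usable points in the candidate region.
    """
    mask = profile.usable & (profile.concentrations > 0)
    t_all = profile.times[mask]
    c_all = profile.concentrations[mask]

    if selection != "auto":
        t_start, t_end = selection
        win = (t_all >= t_start) & (t_all <= t_end)
        t, c = t_all[win], c_all[win]
        if t.size < 3:
            raise UnestimableError(
                f"terminal fit needs >= 3 positive points; window has {t.size}"
            )
        return _fit_window(t, c)

    if t_all.size < 3:
        raise UnestimableError(
            f"terminal fit needs >= 3 positive points; profile has {t_all.size}"
        )
    peak = int(np.argmax(c_all))
    candidates_from = peak + 1  # terminal phase lies strictly after the peak
    best = None
    for start in range(candidates_from, t_all.size - 2):
        fit = _fit_window(t_all[start:], c_all[start:], _warn=False)
        if best is None or fit.adjusted_r_squared > best.adjusted_r_squared + 1e-12:
            best = fit
        elif abs(fit.adjusted_r_squared - best.adjusted_r_squared) <= 1e-12:
            if fit.n_points > best.n_points:
                best = fit
    if best is None:
        raise UnestimableError(
            "no suffix of >= 3 points exists after the observed peak"
        )
    if not best.estimable:
        warnings.warn(
            "terminal phase is not declining; lambda_z marked unestimable",
            RuntimeWarning,
            stacklevel=2,
        )
    return best


def _fit_window(t: np.ndarray, c: np.ndarray, _warn: bool = True) -> TerminalFit:
    slope, intercept, r2, adj = _ols_loglinear(t, np.log(c))
    lam = -slope
    # slopes at rounding-noise level (e.g. constant data) are not a decline
    if lam <= 1e-12:
        if _warn:
            warnings.warn(
                "terminal phase is not declining; lambda_z marked unestimable",
                RuntimeWarning,
                stacklevel=3,
            )
        lam = np.nan
    return TerminalFit(
        lambda_z=lam,
        intercept_log=intercept,
        n_points=int(t.size),
        window=(float(t[0]), float(t[-1])),
        r_squared=r2,
        adjusted_r_squared=adj,
    )


# ---------------------------------------------------------------------------
# elementary NCA quantities
# ---------------------------------------------------------------------------

def half_life(lambda_z: float) -> float:
    """Terminal half-life 0.693 / lambda_z, hours."""
    if not lambda_z > 0:
        raise DomainError("lambda_z must be positive")
    return HALF_LIFE_CONSTANT / lambda_z


def auc_trapezoid(times, concentrations, method: str = "linear") -> float:
    """Area under the curve over the observed range by the trapezoidal rule.

    ``method="linear"`` is the plain rule, Σ (t2−t1)(C1+C2)/2.
    ``method="linear-log"`` (linear-up/log-down) replaces declining segments
    with the log-trapezoid (t2−t1)(C1−C2)/ln(C1/C2) when C1 > C2 > 0, which is
    exact on exponential declines; rising or zero-bounded segments stay linear.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "linear-log":
        raise ValueError(f"unknown method {method!r}")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = dt * (c1 + c2) / 2.0
    logdown = c1 > c2
    logdown &= c2 > 0
    seg = lin.copy()
    seg[logdown] = (
        dt[logdown] * (c1[logdown] - c2[logdown]) / np.log(c1[logdown] / c2[logdown])
    )
    return float(seg.sum())


def auc_extrapolated_tail(c_last: float, lambda_z: float) -> float:
    """Extrapolated area beyond the last quantifiable sample, C_last / lambda_z."""
    if c_last < 0:
        raise DomainError("c_last must be non-negative")
    if not lambda_z > 0:
        raise DomainError("lambda_z must be positive")
    if c_last == 0:
        warnings.warn("c_last is zero: no extrapolation possible", RuntimeWarning, stacklevel=2)
        return 0.0
    return c_last / lambda_z


def aumc_inf(times, concentrations, c_last, t_last, lambda_z, method="linear") -> float:
    """First-moment area to infinity: trapezoids of C·t plus the analytic tail.

    Tail = C_last·t_last/lambda_z + C_last/lambda_z², the integral of the
    terminal mono-exponential times t from t_last to infinity.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    # C·t is not exponential even on exponential declines, so the moment curve
    # always uses the plain linear rule regardless of the AUC method.
    del method
    observed = auc_trapezoid(t, c * t, method="linear")
    if c_last < 0:
        raise DomainError("c_last must be non-negative")
    if c_last == 0:
        return observed
    if not lambda_z > 0:
        raise DomainError("lambda_z must be positive")
    tail = c_last * t_last / lambda_z + c_last / lambda_z**2
    return float(observed + tail)


def mrt(aumc: float, auc: float) -> float:
    """Mean residence time AUMC / AUC, hours."""
    if not auc > 0:
        raise DomainError("AUC must be positive")
    return aumc / auc


def clearance(dose: float, auc_inf: float) -> float:
    """Systemic clearance Dose / AUC0-inf.

    With dose in µg/kg and AUC in µg·h/mL the result is mL·kg⁻¹·h⁻¹.
    """
    if not (dose > 0 and auc_inf > 0):
        raise DomainError("dose and AUC must be positive")
    return dose / auc_inf


def vss(cl: float, mrt_h: float, mode: str = "paper") -> float:
    """Steady-state volume of distribution.

    ``mode="conventional"`` returns Cl × MRT (the standard relation);
    ``mode="paper"`` returns Cl / MRT, the ratio form used by the protocol
    this package reproduces. See the module docstring for the discrepancy.
    """
    if not (cl > 0 and mrt_h > 0):
        raise DomainError("cl and mrt must be positive")
    if mode == "paper":
        return cl / mrt_h
    if mode == "conventional":
        return cl * mrt_h
    raise ValueError(f"unknown vss mode {mode!r}")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

#: Display order of the cohort parameter table (reference-table layout).
PARAMETER_ORDER = [
    ("dose_mg_per_kg", "Dose (mg/kg)"),
    ("auc_inf", "AUC0-inf (ug h/mL)"),
    ("lambda_z", "K el (1/h)"),
    ("t_half", "t1/2 (h)"),
    ("mrt", "MRT (h)"),
    ("cl", "Cl (mL/kg/h)"),
    ("vss_paper", "Vss, Cl/MRT (mL/kg)"),
    ("vss_conventional", "Vss, Cl*MRT (mL/kg)"),
    ("auc_last", "AUC0-tlast (ug h/mL)"),
    ("aumc_inf", "AUMC0-inf (ug h2/mL)"),
    ("pct_extrapolated", "AUC extrapolated (%)"),
]


@dataclass(frozen=True)
class NCAResults:
    """Complete noncompartmental output for one profile.

    All exposure quantities are on the µg scale (AUC µg·h/mL, AUMC µg·h²/mL);
    fields that depend on an unestimable terminal phase are NaN and listed in
    ``unavailable``.
    """

    subject_id: str
    dose: float  # µg/kg
    lambda_z: float
    t_half: float
    auc_last: float
    auc_inf: float
    aumc_inf: float
    mrt: float
    cl: float
    vss_paper: float
    vss_conventional: float
    pct_extrapolated: float
    terminal_fit: TerminalFit
    unavailable: tuple = ()

    @property
    def dose_mg_per_kg(self) -> float:
        return self.dose / 1000.0

    def to_series(self) -> pd.Series:
        return pd.Series({key: getattr(self, key) for key, _ in PARAMETER_ORDER})

    def summary(self) -> str:
        lines = [
            f"Noncompartmental analysis — subject {self.subject_id}",
            f"  terminal fit: n={self.terminal_fit.n_points} points over "
            f"t = {self.terminal_fit.window[0]:g}–{self.terminal_fit.window[1]:g} h, "
            f"adj. r² = {self.terminal_fit.adjusted_r_squared:.4f}",
        ]
        for key, label in PARAMETER_ORDER:
            v = getattr(self, key)
            lines.append(f"  {label:<26s} {v:.2f}" if np.isfinite(v) else f"  {label:<26s} n/a")
        if self.unavailable:
            lines.append("  unavailable: " + ", ".join(self.unavailable))
        return "\n".join(lines)


class NCA:
    """Noncompartmental model of a single concentration–time profile.

    Parameters
    ----------
    profile : ConcentrationTimeProfile
        Needs at least 3 usable (non-BLQ) points.
    terminal : "auto" or (t_start, t_end)
        Terminal-phase point selection, see :func:`fit_terminal_phase`.
    auc_method : "linear" or "linear-log"
        Trapezoidal rule variant; the plain linear rule is the default.
    vss_mode : "paper" or "conventional"
        Which Vss variant ``results.vss`` aliases; both are always computed.

    Examples
    --------
    >>> res = NCA(profile).fit()
    >>> res.cl, res.t_half
    """

    def __init__(self, profile, terminal="auto", auc_method="linear", vss_mode="paper"):
        if profile.n_usable < 3:
            raise ValueError("NCA needs at least 3 usable (non-BLQ) points")
        if vss_mode not in ("paper", "conventional"):
            raise ValueError(f"unknown vss mode {vss_mode!r}")
        self.profile = profile
        self.terminal = terminal
        self.auc_method = auc_method
        self.vss_mode = vss_mode

    def fit(self) -> NCAResults:
        p = self.profile
        mask = p.usable
        t = p.times[mask]
        c = p.concentrations[mask] * CONC_TO_UG_PER_ML

        tfit = fit_terminal_phase(p, self.terminal)
        auc_obs = auc_trapezoid(t, c, method=self.auc_method)
        c_last, t_last = float(c[-1]), float(t[-1])

        unavailable = []
        if tfit.estimable:
            lam = tfit.lambda_z
            tail = auc_extrapolated_tail(c_last, lam) if c_last > 0 else 0.0
            auc_total = auc_obs + tail
            aumc_total = aumc_inf(t, c, c_last, t_last, lam, method=self.auc_method)
            t_half = half_life(lam)
            mrt_h = mrt(aumc_total, auc_total)
            cl_v = clearance(p.dose, auc_total)
            vss_p = vss(cl_v, mrt_h, "paper")
            vss_c = vss(cl_v, mrt_h, "conventional")
            pct = 100.0 * tail / auc_total
        else:
            lam = t_half = auc_total = aumc_total = mrt_h = cl_v = vss_p = vss_c = pct = np.nan
            unavailable = [
                "lambda_z", "t_half", "auc_inf", "aumc_inf",
                "mrt", "cl", "vss_paper", "vss_conventional", "pct_extrapolated",
            ]

        return NCAResults(
            subject_id=p.subject_id,
            dose=p.dose,
            lambda_z=lam,
            t_half=t_half,
            auc_last=auc_obs,
            auc_inf=auc_total,
            aumc_inf=aumc_total,
            mrt=mrt_h,
            cl=cl_v,
            vss_paper=vss_p,
            vss_conventional=vss_c,
            pct_extrapolated=pct,
            terminal_fit=tfit,
            unavailable=tuple(unavailable),
        )


def run_nca(profile, terminal="auto", auc_method="linear", vss_mode="paper") -> NCAResults:
    """Convenience wrapper: build the :class:`NCA` model and fit it."""
    return NCA(profile, terminal=terminal, auc_method=auc_method, vss_mode=vss_mode).fit()


def summarize_cohort(results: list[NCAResults]) -> pd.DataFrame:
    """Arithmetic mean ± sample SD (n−1) of each parameter across subjects.

    Parameters are averaged per subject and then summarized — derived
    quantities are never recomputed from averaged inputs, so e.g. the mean
    t1/2 is the mean of per-subject 0.693/K ratios, not 0.693 over the mean K.

    Returns a table indexed by parameter label with columns ``mean``, ``sd``
    and ``n``, in the reference-table row order.
    """
    if not results:
        raise ValueError("summarize_cohort needs at least one result")
    frame = pd.DataFrame([r.to_series() for r in results])
    mean = frame.mean()
    sd = frame.std(ddof=1) if len(results) > 1 else pd.Series(0.0, index=frame.columns)
    out = pd.DataFrame(
        {
            "mean": [mean[key] for key, _ in PARAMETER_ORDER],
            "sd": [sd[key] for key, _ in PARAMETER_ORDER],
            "n": len(results),
        },
        index=pd.Index([label for _, label in PARAMETER_ORDER], name="parameter"),
    )
    return out
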