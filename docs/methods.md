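# Methods

## Scope

`pkval` implements noncompartmental analysis (NCA) of single-dose IV-bolus
plasma data and the statistics of bioanalytical method validation, together
with a simulator that generates every input the analyses consume. Nothing
chromatographic is modelled: responses enter as peak-area ratios, profiles as
concentration–time tables. Oral/absorption models, compartmental fitting and
metabolite kinetics are out of scope.

## Disposition model and simulator

The simulator draws from C(t) = Σᵢ Aᵢ·e^(−λᵢt) (1–3 terms, rates strictly
decreasing). The default is tri-exponential with A = (4150, 1665, 345) ng/mL
and λ = (3.0, 0.45, 0.0879) h⁻¹ at a dose of 5000 µg/kg. These
macro-constants are illustrative, not fitted to any measured curve; they were
chosen once so that the terminal half-life is 0.693/0.0879 = 7.88 h, total
exposure AUC₀₋∞ ≈ 9.0 µg·h/mL, MRT ≈ 5.9 h, and the 48-h concentration
(≈5.07 ng/mL) stays just above the 5 ng/mL quantification limit — the
qualitative behaviour of a drug quantifiable over 6–7 half-lives of a 48-h
study.

Measurement error is the standard bioanalytical two-component model:
observed = model × (1 + εₚ) + εₐ, with εₚ ~ N(0, proportional_cv²) and
εₐ ~ N(0, additive_sd²), truncated at zero (concentrations are physically
non-negative). Defaults: proportional CV 10%, no additive noise. Between-
animal variability is a unit-mean lognormal multiplier (CV 20% by default) on
each subject's coefficients only — the minimal identifiable structure that
spreads exposures without perturbing the shared elimination rates. Normal
deviates were chosen for assay noise (symmetric, the conventional residual
model at the response level); the lognormal for biology keeps coefficients
positive.

The assay layer flags, and never alters: values below the 5 ng/mL LLOQ are
marked below-limit (retained but unusable downstream — downstream policy is
explicit rather than silently dropping rows), values above the 1000 ng/mL
ULOQ are marked as assayed after 10-fold dilution (provenance only; the
stored value is already on the undiluted scale).

What the simulator does **not** emulate: correlated residuals within a run,
heteroscedastic additive+proportional blends fitted from real QC data,
drift/carry-over between injections, non-lognormal animal-to-animal
differences, and any error in the sampling times. Passing tests therefore
demonstrate correctness of the computations under a well-specified error
model, not robustness to every artefact of real chromatography.

## NCA

- **Terminal fit.** Ordinary least squares of ln C on t. Automatic selection
  evaluates every suffix of ≥3 quantifiable points strictly after the
  observed peak, keeps the highest adjusted r² and breaks ties toward more
  points — the de-facto pharmacometric convention; a manual (t_start, t_end)
  window overrides it. Non-declining windows (slope ≥ −10⁻¹², i.e. zero at
  rounding level) warn and mark λz unestimable; dependent parameters become
  NaN and are listed in `results.unavailable`.
- **t½ = 0.693/λz** with the literal constant 0.693, not ln 2 — this matches
  the protocol formula the package reproduces; the difference is < 0.03%.
- **AUC.** Plain linear trapezoid by default (the unqualified "trapezoidal
  rule"); linear-up/log-down is opt-in and exact on exponentially declining
  segments. The first-moment curve C·t always uses the linear rule (C·t is
  not exponential even when C is). Tail terms: C_last/λz and
  C_last·t_last/λz + C_last/λz², using the last *observed* quantifiable
  concentration.
- **Units.** Input ng/mL is divided by 1000 before integration, so AUC is
  µg·h/mL, Cl = Dose/AUC is mL·kg⁻¹·h⁻¹ (dose in µg/kg), and Vss is mL·kg⁻¹.
- **Vss.** Two variants are computed: conventional Cl × MRT and the ratio
  Cl / MRT. The ratio form is dimensionally inconsistent as a volume, but it
  is what some protocols define and report (and is self-consistent with their
  printed Cl and MRT values), so it is provided as the default `vss_mode="paper"`
  label with the conventional product always available alongside. No intent
  is guessed; both numbers are reported.
- **Cohort summary.** Parameters are derived per subject and then averaged
  (mean ± sample SD, n−1). Averaging derived ratios, not deriving from
  averaged parameters, is what makes a cohort-mean t½ differ from
  0.693/(mean K) — the behaviour consistent with published summary tables.
- **BLQ policy.** Below-limit records are excluded from both the regression
  and the trapezoids (unbiased terminal slope), never substituted with 0 or
  LLOQ/2.

## Calibration and limits

Response = slope·concentration + intercept, fitted by (weighted) least
squares with weights 1, 1/x or 1/x². Unweighted is the default — it matches
a single reported regression line — with the inverse-variance weightings
available because the range spans 200-fold. Back-calculation inverts the line
and multiplies by the dilution factor; negative results are flagged
non-physical. LOD (S/N ≥ 3:1) and LOQ (RE < 20% and RSD < 20%, strict
inequalities) are selected among the discrete tested levels, never
interpolated, because the laboratory procedure itself is level-based. A curve
is flagged non-reportable below 6 distinct levels.

## Validation statistics

RSD% = 100·SD/mean and RE% = 100·|nominal − mean|/nominal, sample SD (n−1)
throughout. Intra-day tables use one analytical day; inter-day tables pool
all replicates across days into one mean/SD per level (pooling, rather than
averaging day means, reproduces a single summary row per level; with k
identical days the pooled n−1 SD is √((n−1)k/(nk−1)) times the within-day
SD — an effect of the denominator, documented rather than hidden). Acceptance
uses inclusive limits (≤15%, ≤20% at the LOQ): values *higher than* the limit
fail. Recovery is 100 × mean(processed)/mean(reference), its SD taken over
per-replicate processed ratios against the reference mean (a propagation the
protocol leaves unstated). Stability is % remaining vs the initial
concentration, stable iff the deviation is ≤5 percentage points, inclusive at
the boundary.

## Numerical choices

- Exact threshold comparisons at flag boundaries (15/20/±5) — no epsilon.
- λz ≤ 10⁻¹² is treated as a zero slope (rounding noise on constant data).
- File round trips are bit-faithful: shortest-repr floats on write, the
  round-trip float parser on read.
- Display rounding (2 decimals in reports) never feeds back into computation.
- Adjusted r² = 1 − (1−r²)(n−1)/(n−2); ties in automatic λz selection at
  10⁻¹² resolution go to the longer window.

## Problem sizes in tests

Monte-Carlo calibration checks use 10,000 replicate draws (assay CV), 1,000
subjects (between-animal CV) and 2,000–5,000 QC replicates; oracle
equivalence runs over 100 random QC batches; the stochastic recovery test
runs 20 replicate six-subject studies at the 12-point schedule. These sizes
give the convergence the asserted tolerances need while keeping the whole
suite to a few seconds.

## Known limitations

- Automatic λz selection needs at least three points after the peak; a
  three-point monotone profile requires a manual window.
- The LOQ search assumes the supplied accuracy/precision rows cover the
  candidate levels; it does not extrapolate below the lowest tested level.
- Inter-day RSD from pooled replicates mixes within- and between-day variance
  components; a variance-components decomposition is deliberately not
  attempted.
- The ratio-form Vss is reported as defined by its source protocol; users
  wanting a physically interpretable volume should read `vss_conventional`.
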