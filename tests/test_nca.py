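"""Noncompartmental analysis: closed forms, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pkval import (
    ConcentrationTimeProfile,
    DomainError,
    NCA,
    UnestimableError,
    auc_extrapolated_tail,
    auc_trapezoid,
    aumc_inf,
    clearance,
    fit_terminal_phase,
    half_life,
    model_concentration,
    mrt,
    run_nca,
    summarize_cohort,
    vss,
)
from oracles import dense_linear_auc, mean_sd, ols_line


def make_profile(times, conc, dose=5000.0, blq=None):
    return ConcentrationTimeProfile("s", dose, np.asarray(times, float),
                                    np.asarray(conc, float), blq_flags=blq)


@st.composite
def random_profiles(draw, min_points=4, max_points=12):
    n = draw(st.integers(min_points, max_points))
    dts = draw(st.lists(st.floats(0.1, 10.0), min_size=n - 1, max_size=n - 1))
    times = np.concatenate([[0.0], np.cumsum(dts)])
    conc = draw(st.lists(st.floats(0.0, 1000.0), min_size=n, max_size=n))
    return times, np.asarray(conc)


class TestTerminalFit:
    def test_exact_loglinear_data(self):
        t = np.array([8.0, 10.0, 12.0])
        prof = make_profile(t, 100 * np.exp(-0.2 * t))
        fit = fit_terminal_phase(prof, selection=(8.0, 12.0))
        assert fit.lambda_z == pytest.approx(0.2, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 3

    def test_manual_window_matches_brute_force_ols(self):
        t = np.array([1.0, 2.0, 4.0, 8.0, 10.0, 12.0])
        c = np.array([900.0, 400.0, 150.0, 40.0, 22.0, 13.0])
        fit = fit_terminal_phase(make_profile(t, c), selection=(8.0, 12.0))
        slope, intercept = ols_line(t[-3:], np.log(c[-3:]))
        assert fit.lambda_z == pytest.approx(-slope, rel=1e-12)
        assert fit.intercept_log == pytest.approx(intercept, rel=1e-9)

    def test_constant_concentrations_unestimable(self):
        prof = make_profile([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])
        with pytest.warns(RuntimeWarning, match="not declining"):
            fit = fit_terminal_phase(prof, selection=(1.0, 3.0))
        assert not fit.estimable

    def test_too_few_points_raises(self):
        prof = make_profile([1.0, 2.0, 3.0], [10.0, 8.0, 6.0])
        with pytest.raises(UnestimableError):
            fit_terminal_phase(prof, selection=(2.0, 3.0))

    def test_auto_excludes_peak_and_prefers_terminal_slope(self, noise_free_profile):
        fit = fit_terminal_phase(noise_free_profile, selection="auto")
        assert fit.window[0] > noise_free_profile.times[0]
        # generating terminal rate 0.0879 recovered within a few percent
        assert fit.lambda_z == pytest.approx(0.0879, rel=0.05)

    def test_blq_points_excluded_from_regression(self):
        t = np.array([6.0, 8.0, 10.0, 12.0])
        c = 100 * np.exp(-0.2 * t)
        c_corrupt = c.copy()
        c_corrupt[-1] = 3.0  # a BLQ record with a junk value
        blq = np.array([False, False, False, True])
        fit = fit_terminal_phase(make_profile(t, c_corrupt, blq=blq), selection=(6.0, 12.0))
        assert fit.n_points == 3
        assert fit.lambda_z == pytest.approx(0.2, rel=1e-12)


class TestHalfLife:
    @pytest.mark.parametrize(
        "lam,expected", [(0.1, 6.93), (0.693, 1.0), (0.693 / 7.88, 7.88)]
    )
    def test_formula(self, lam, expected):
        assert half_life(lam) == pytest.approx(expected, rel=1e-9)

    def test_domain(self):
        with pytest.raises(DomainError):
            half_life(0.0)


class TestTrapezoid:
    def test_rectangle(self):
        assert auc_trapezoid([0.0, 1.0], [10.0, 10.0]) == pytest.approx(10.0)

    def test_logdown_exact_on_exponential(self):
        # 100 -> 50 over 1 h: log trapezoid = 50/ln 2, the analytic integral
        got = auc_trapezoid([0.0, 1.0], [100.0, 50.0], method="linear-log")
        assert got == pytest.approx(50.0 / np.log(2.0), rel=1e-12)

    @given(random_profiles())
    def test_linear_matches_dense_integration_oracle(self, profile):
        times, conc = profile
        assert auc_trapezoid(times, conc) == pytest.approx(
            dense_linear_auc(times, conc), rel=1e-9, abs=1e-9
        )

    @given(
        st.floats(1.0, 1000.0),
        st.floats(0.01, 2.0),
        st.floats(0.1, 10.0),
        st.floats(0.1, 10.0),
    )
    def test_logdown_exact_on_any_exponential_segment(self, c0, lam, t0, dt):
        t = np.array([t0, t0 + dt])
        c = c0 * np.exp(-lam * t)
        analytic = (c[0] - c[1]) / lam
        assert auc_trapezoid(t, c, method="linear-log") == pytest.approx(analytic, rel=1e-12)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            auc_trapezoid([1.0], [5.0])


class TestTailAndMoments:
    def test_tail_formula(self):
        assert auc_extrapolated_tail(1.0, 0.1) == pytest.approx(10.0)

    def test_zero_clast_boundary(self):
        with pytest.warns(RuntimeWarning, match="no extrapolation"):
            assert auc_extrapolated_tail(0.0, 0.1) == 0.0

    def test_tail_domain(self):
        with pytest.raises(DomainError):
            auc_extrapolated_tail(1.0, 0.0)

    def test_monoexponential_total_auc(self):
        """auc_last + tail reproduces the analytic AUC0-inf = C0/lambda."""
        t = np.linspace(0.0, 12.0, 1201)
        c = 100 * np.exp(-0.2 * t)
        total = auc_trapezoid(t, c) + auc_extrapolated_tail(c[-1], 0.2)
        assert total == pytest.approx(100 / 0.2, rel=5e-4)

    def test_aumc_closed_form(self):
        t = np.linspace(0.0, 60.0, 6001)
        c = 100 * np.exp(-0.2 * t)
        got = aumc_inf(t, c, c_last=c[-1], t_last=60.0, lambda_z=0.2)
        assert got == pytest.approx(100 / 0.2**2, rel=5e-3)

    def test_aumc_tail_term(self):
        # pure tail: 10*12/0.1 + 10/0.01 = 2200 beyond a zero observed area
        got = aumc_inf([0.0, 12.0], [0.0, 0.0], c_last=10.0, t_last=12.0, lambda_z=0.1)
        assert got == pytest.approx(2200.0)

    def test_aumc_zero_curve(self):
        assert aumc_inf([0.0, 1.0], [0.0, 0.0], c_last=0.0, t_last=1.0, lambda_z=0.1) == 0.0


class TestScalarParameters:
    def test_mrt(self):
        assert mrt(2500.0, 500.0) == pytest.approx(5.0)
        assert mrt(0.0, 500.0) == 0.0
        with pytest.raises(DomainError):
            mrt(2500.0, 0.0)

    def test_clearance_reference_value(self):
        # 5 mg/kg over 9.01 µg·h/mL -> 554.94 mL/kg/h at 2 d.p.
        assert clearance(5000.0, 9.01) == pytest.approx(554.94, abs=5e-3)
        assert clearance(5.0, 5.0) == 1.0
        with pytest.raises(DomainError):
            clearance(0.0, 9.01)

    def test_vss_modes(self):
        assert vss(554.94, 5.92, mode="paper") == pytest.approx(93.74, abs=5e-3)
        assert vss(554.94, 5.92, mode="conventional") == pytest.approx(3285.24, abs=5e-2)
        assert vss(10.0, 1.0, "paper") == vss(10.0, 1.0, "conventional")
        with pytest.raises(DomainError):
            vss(-1.0, 5.0)


class TestRunNCA:
    def test_closed_form_recovery(self, dense_mono_profile):
        res = run_nca(dense_mono_profile)
        c0_ug = 0.1  # 100 ng/mL
        assert res.lambda_z == pytest.approx(0.2, rel=5e-3)
        assert res.cl == pytest.approx(5000.0 / (c0_ug / 0.2), rel=5e-3)
        assert res.t_half == pytest.approx(0.693 / 0.2, rel=5e-3)
        assert res.auc_inf == pytest.approx(c0_ug / 0.2, rel=5e-3)
        assert res.mrt == pytest.approx(1 / 0.2, rel=5e-3)

    def test_dose_identity(self, dense_mono_profile, noise_free_profile):
        for prof in (dense_mono_profile, noise_free_profile):
            res = run_nca(prof)
            assert res.cl * res.auc_inf == pytest.approx(prof.dose, rel=1e-9)

    def test_vss_invariants(self, noise_free_profile):
        res = run_nca(noise_free_profile)
        assert res.vss_paper == pytest.approx(res.cl / res.mrt, rel=1e-12)
        assert res.vss_conventional == pytest.approx(res.cl * res.mrt, rel=1e-12)
        assert res.t_half == pytest.approx(0.693 / res.lambda_z, rel=1e-12)
        assert 0 <= res.pct_extrapolated < 100
        assert res.auc_inf >= res.auc_last > 0

    def test_pct_extrapolated_decreases_with_tlast(self, mono_params):
        pcts = []
        for t_end in (12.0, 24.0, 36.0):
            t = np.linspace(0.0, t_end, 241)
            prof = make_profile(t, model_concentration(mono_params, t))
            pcts.append(run_nca(prof).pct_extrapolated)
        assert pcts[0] > pcts[1] > pcts[2]

    def test_unestimable_propagates(self):
        prof = make_profile([1.0, 2.0, 3.0, 4.0], [10.0, 12.0, 11.0, 12.0])
        with pytest.warns(RuntimeWarning):
            res = run_nca(prof, terminal=(1.0, 4.0))
        assert "cl" in res.unavailable
        assert np.isnan(res.cl) and np.isnan(res.auc_inf)
        assert np.isfinite(res.auc_last)

    def test_needs_three_usable_points(self):
        prof = make_profile([1.0, 2.0, 3.0], [10.0, 8.0, 6.0],
                            blq=np.array([False, False, True]))
        with pytest.raises(ValueError, match="3 usable"):
            NCA(prof)


class TestCohortSummary:
    def test_single_result_sd_zero(self, dense_mono_profile):
        table = summarize_cohort([run_nca(dense_mono_profile)])
        assert (table["sd"] == 0).all()
        assert (table["n"] == 1).all()

    def test_identical_results_sd_zero(self, dense_mono_profile):
        res = run_nca(dense_mono_profile)
        table = summarize_cohort([res, res])
        assert table["sd"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_mean_sd_denominator(self, dense_mono_profile, noise_free_profile):
        r1, r2 = run_nca(dense_mono_profile), run_nca(noise_free_profile)
        table = summarize_cohort([r1, r2])
        m, s = mean_sd([r1.cl, r2.cl])
        row = table.loc["Cl (mL/kg/h)"]
        assert row["mean"] == pytest.approx(m, rel=1e-12)
        assert row["sd"] == pytest.approx(s, rel=1e-12)

    def test_hand_computed_sd(self):
        # values {4, 6}: mean 5, sample SD sqrt(2) = 1.4142
        m, s = mean_sd([4.0, 6.0])
        assert m == 5.0
        assert s == pytest.approx(1.4142, abs=5e-5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
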