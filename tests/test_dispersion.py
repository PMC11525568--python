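"""CPMG dispersion models, an independent Bloch-McConnell oracle, fits
and F-test model selection."""

import numpy as np
import pytest
from scipy.linalg import expm

from relaxkit.data_io import ResidueKey
from relaxkit.dispersion import (
    MODEL_CR,
    MODEL_FAST,
    MODEL_NO_EXCHANGE,
    DispersionProfile,
    fit_dispersion,
    fit_no_exchange,
    intensities_to_r2eff,
    model_r2eff,
    r2eff_carver_richards,
    r2eff_fast_exchange,
    select_model,
)
from relaxkit.modelfree import FieldContext

RES = ResidueKey(141, "E")
NU = np.array([25, 50, 75, 100, 150, 200, 300, 400, 500, 600, 700, 800, 900, 1000.0])
T_RELAX = 0.04


def bloch_mcconnell_r2eff(nu_values, r2_0, k_ex, p_a, dw_rad, t_relax):
    """Numerical two-site CPMG simulation (tau-180-tau elements).

    Matrix-exponential propagation of the transverse magnetization with a
    180-degree pulse modelled as complex conjugation; independent of the
    closed-form implementation it checks.
    """
    p_b = 1 - p_a
    k = np.array([[-r2_0 - p_b * k_ex + 0j, p_a * k_ex],
                  [p_b * k_ex, -r2_0 - p_a * k_ex + 1j * dw_rad]])
    out = []
    for nu in np.atleast_1d(nu_values):
        n_el = int(round(2 * t_relax * nu))
        tau = t_relax / (2 * n_el)
        u = expm(k * tau)
        m = np.array([p_a, p_b], dtype=complex)
        for _ in range(n_el):
            m = u @ np.conj(u @ m)
        out.append(-np.log(abs(m[0]) / p_a) / t_relax)
    return np.array(out)


def make_profile(fieldctx, r2_0, k_ex=None, p_a=None, dw=None, noise=0.0,
                 rng=None, nu=NU, model=MODEL_CR):
    if k_ex is None:
        clean = np.full_like(nu, r2_0)
    else:
        clean = model_r2eff(model, nu, fieldctx, r2_0, k_ex, p_a, dw)
    i0 = 1000.0
    i = i0 * np.exp(-clean * T_RELAX)
    sigma = noise * i0
    if noise > 0:
        i = i + (rng or np.random.default_rng(0)).normal(0, sigma, len(nu))
    r2eff, err, exc = intensities_to_r2eff(i, i0, T_RELAX, sigma)
    return DispersionProfile(RES, fieldctx, nu[~exc], r2eff[~exc], err[~exc], T_RELAX)


class TestR2effConversion:
    def test_equal_intensities_give_zero(self):
        out = intensities_to_r2eff([1000.0], 1000.0, T_RELAX)
        assert out.r2eff[0] == 0.0

    def test_one_neper_over_40ms_is_25_per_s(self):
        out = intensities_to_r2eff([1000.0 * np.exp(-1)], 1000.0, 0.04)
        assert out.r2eff[0] == pytest.approx(25.0)

    def test_halving_t_relax_doubles_r2eff(self):
        i = [500.0]
        a = intensities_to_r2eff(i, 1000.0, 0.04).r2eff[0]
        b = intensities_to_r2eff(i, 1000.0, 0.02).r2eff[0]
        assert b == pytest.approx(2 * a)

    def test_forward_backward_identity(self):
        r2 = np.array([5.0, 20.0, 80.0])
        i = 1000.0 * np.exp(-r2 * T_RELAX)
        out = intensities_to_r2eff(i, 1000.0, T_RELAX)
        np.testing.assert_allclose(out.r2eff, r2, atol=1e-12)

    def test_nonpositive_intensity_excluded(self):
        out = intensities_to_r2eff([500.0, -2.0], 1000.0, T_RELAX)
        assert list(out.excluded) == [False, True]
        assert np.isnan(out.r2eff[1])


class TestDispersionModels:
    def test_zero_dw_is_flat_for_all_models(self, field600):
        for model in (MODEL_FAST, MODEL_CR):
            vals = model_r2eff(model, NU, field600, 18.0, 800.0, 0.95, 0.0)
            np.testing.assert_allclose(vals, 18.0, atol=1e-9)

    def test_fast_model_refocusing_limit(self, field600):
        val = r2eff_fast_exchange(1e6, 18.0, 800.0, 0.95, 2.0, field600)
        assert val == pytest.approx(18.0, abs=1e-6)

    def test_carver_richards_matches_bloch_mcconnell(self, field600):
        # independent numerical oracle; CR72 is a closed-form approximation,
        # accurate to a few percent in the intermediate regime
        for (kex, pa, dw_ppm, tol) in [(1000.0, 0.95, 2.0, 0.02),
                                       (3000.0, 0.97, 1.5, 0.005),
                                       (500.0, 0.9, 1.0, 0.04)]:
            dw_rad = dw_ppm * 1e-6 * abs(field600.omega_n)
            cr = r2eff_carver_richards(NU, 20.0, kex, pa, dw_ppm, field600)
            bm = bloch_mcconnell_r2eff(NU, 20.0, kex, pa, dw_rad, T_RELAX)
            assert np.max(np.abs(cr - bm) / bm) < tol

    def test_carver_richards_reduces_to_luz_meiboom_in_fast_limit(self, field600):
        # kex/dw_rad >= 20
        dw_ppm = 1.0
        kex = 20 * dw_ppm * 1e-6 * abs(field600.omega_n)
        cr = r2eff_carver_richards(NU, 20.0, kex, 0.9, dw_ppm, field600)
        lm = r2eff_fast_exchange(NU, 20.0, kex, 0.9, dw_ppm, field600)
        assert np.max(np.abs(cr - lm) / lm) < 0.02

    def test_profiles_monotone_non_increasing(self, field600):
        nu_fine = np.linspace(25, 2000, 200)
        lm = r2eff_fast_exchange(nu_fine, 20.0, 1500.0, 0.93, 1.5, field600)
        assert np.all(np.diff(lm) <= 1e-9)
        cr = r2eff_carver_richards(nu_fine, 20.0, 700.0, 0.95, 2.0, field600)
        assert np.all(np.diff(cr) <= 1e-6)

    def test_rex_field_scaling_in_fast_regime(self, field600, field850):
        # Rex scales with the square of the field when exchange is fast
        kex, pa, dw = 6000.0, 0.95, 1.0
        rex = {}
        for ctx in (field600, field850):
            lo = r2eff_fast_exchange(1e-3, 20.0, kex, pa, dw, ctx)
            hi = r2eff_fast_exchange(1e9, 20.0, kex, pa, dw, ctx)
            rex[ctx.proton_frequency_MHz] = lo - hi
        assert rex[850.0] / rex[600.0] == pytest.approx((850 / 600) ** 2, rel=0.05)


class TestFitDispersion:
    def test_noiseless_two_field_round_trip(self, field600, field850):
        profiles = [make_profile(field600, 20.0, 1000.0, 0.95, 2.0),
                    make_profile(field850, 22.0, 1000.0, 0.95, 2.0)]
        fit = fit_dispersion(profiles, MODEL_CR, mc_reps=0)
        assert fit.k_ex == pytest.approx(1000.0, rel=1e-3)
        assert fit.p_a == pytest.approx(0.95, rel=1e-3)
        assert fit.delta_omega_ppm == pytest.approx(2.0, rel=1e-3)
        assert fit.r2_0[600.0] == pytest.approx(20.0, rel=1e-3)
        assert fit.r2_0[850.0] == pytest.approx(22.0, rel=1e-3)
        assert fit.r_ex[850.0] > fit.r_ex[600.0] > 0

    def test_flat_noiseless_profile_null_fit_is_exact(self, field600):
        profile = make_profile(field600, 17.0)
        fit = fit_no_exchange([profile])
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)
        assert fit.r2_0[600.0] == pytest.approx(17.0)

    def test_noisy_kex_recovery_within_10_percent(self, field600, field850):
        # 2% relative errors on the R2eff observations the fit consumes
        rng = np.random.default_rng(17)
        rel_errors = []
        for _ in range(50):
            profiles = []
            for ctx, r2_0 in ((field600, 20.0), (field850, 22.0)):
                clean = model_r2eff(MODEL_CR, NU, ctx, r2_0, 1000.0, 0.95, 2.0)
                sig = 0.02 * clean
                profiles.append(DispersionProfile(
                    RES, ctx, NU, clean + rng.normal(0, sig), sig, T_RELAX))
            fit = fit_dispersion(profiles, MODEL_CR, mc_reps=0)
            rel_errors.append(abs(fit.k_ex - 1000.0) / 1000.0)
        assert np.median(rel_errors) <= 0.10


class TestSelectModel:
    def test_equal_chi2_keeps_null(self, field600):
        profile = make_profile(field600, 17.0, noise=0.02,
                               rng=np.random.default_rng(2))
        null = fit_no_exchange([profile])
        alt = fit_dispersion([profile], MODEL_FAST, mc_reps=0)
        alt.chi2 = null.chi2
        choice = select_model(null, alt, alt.n_points)
        assert choice.chosen == MODEL_NO_EXCHANGE
        assert choice.f_statistic == pytest.approx(0.0)
        assert choice.p_value == pytest.approx(1.0)

    def test_both_perfect_fits_resolve_to_null(self, field600):
        profile = make_profile(field600, 17.0)
        null = fit_no_exchange([profile])
        alt = fit_dispersion([profile], MODEL_FAST, mc_reps=0)
        choice = select_model(null, alt, alt.n_points)
        assert choice.chosen == MODEL_NO_EXCHANGE

    def test_selection_rate_under_null_is_conservative(self, field600):
        # the bounded monotone exchange family cannot chase upward-trending
        # noise, so the F-test rejects the null less often than its nominal
        # level: a valid (conservative) test
        rng = np.random.default_rng(31)
        reps, hits = 120, 0
        for _ in range(reps):
            profile = make_profile(field600, 20.0, noise=0.02, rng=rng)
            null = fit_no_exchange([profile])
            alt = fit_dispersion([profile], MODEL_FAST, mc_reps=0)
            if select_model(null, alt, alt.n_points, 0.1).chosen != MODEL_NO_EXCHANGE:
                hits += 1
        assert hits / reps <= 0.1

    def test_strong_exchange_always_detected(self, field600):
        rng = np.random.default_rng(23)
        profile = make_profile(field600, 20.0, 800.0, 0.95, 2.5,
                               noise=0.02, rng=rng)
        null = fit_no_exchange([profile])
        alt = fit_dispersion([profile], MODEL_CR, mc_reps=0)
        choice = select_model(null, alt, alt.n_points)
        assert choice.chosen == MODEL_CR
        assert choice.p_value < 1e-4
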