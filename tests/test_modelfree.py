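"""Spectral density identities, rate prediction and model-free recovery."""

import numpy as np
import pytest
from scipy.integrate import quad

from relaxkit.data_io import ResidueKey
from relaxkit.errors import ConsistencyError, InsufficientDataError
from relaxkit.modelfree import (
    DEFAULT_CONSTANTS,
    FieldContext,
    estimate_tau_m,
    fit_modelfree,
    predict_rates,
    spectral_density,
)
from relaxkit.rate_fitting import RateRecord

TAU_M = 28e-9


def records_from_rates(r1, r2, noe, field=600.0, sigma=0.0,
                       res=ResidueKey(42, "A")):
    s = (sigma, sigma, sigma) if np.isscalar(sigma) else sigma
    return [
        RateRecord(res, "R1", r1, s[0], field, 310.0),
        RateRecord(res, "R2", r2, s[1], field, 310.0),
        RateRecord(res, "NOE", min(noe, 1.2), s[2], field, 310.0),
    ]


class TestSpectralDensity:
    def test_rigid_limit_is_single_lorentzian(self):
        for omega in (0.0, 1e8, 5e9):
            expected = 0.4 * TAU_M / (1 + (omega * TAU_M) ** 2)
            assert spectral_density(omega, 1.0, TAU_M, 3e-9) == pytest.approx(expected)

    def test_zero_frequency_rigid_value(self):
        assert spectral_density(0.0, 1.0, TAU_M, 0.0) == pytest.approx(1.12e-8)

    def test_integral_conserved_at_pi_over_5(self):
        # integral of J over [0, inf) is pi/5 for any valid parameters
        rng = np.random.default_rng(12)
        for _ in range(20):
            s2 = rng.uniform(0.0, 1.0)
            tau_m = rng.uniform(5e-9, 40e-9)
            tau_e = rng.uniform(1e-12, 5e-9)
            tau = tau_m * tau_e / (tau_m + tau_e)
            # piecewise quadrature across the two Lorentzian widths
            cuts = [0.0, 1 / tau_m, 1 / tau, 1e4 / tau, 1e8 / tau]
            val = sum(quad(spectral_density, a, b, args=(s2, tau_m, tau_e),
                           limit=200)[0] for a, b in zip(cuts, cuts[1:]))
            assert val == pytest.approx(np.pi / 5, abs=1e-6)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            spectral_density(0.0, 1.2, TAU_M, 0.0)
        with pytest.raises(ValueError):
            spectral_density(0.0, 0.5, -1e-9, 0.0)


class TestPredictRates:
    def test_gyromagnetic_ratio_quotient(self, field600):
        assert field600.omega_n / field600.omega_h == pytest.approx(-0.1014, abs=4e-4)

    def test_rex_adds_only_to_r2(self, field600):
        base = predict_rates(0.85, 50e-12, TAU_M, field600)
        with_rex = predict_rates(0.85, 50e-12, TAU_M, field600, r_ex=5.0)
        assert with_rex[1] - base[1] == pytest.approx(5.0)
        assert with_rex[0] == base[0]
        assert with_rex[2] == base[2]

    def test_core_residue_noe_regression_value(self, field600):
        # frozen oracle value for (S2=0.85, tau_e=50 ps, tau_m=28 ns, 600 MHz);
        # at this long tau_m the NOE is strongly tau_e-sensitive
        _, _, noe = predict_rates(0.85, 50e-12, TAU_M, field600)
        assert noe == pytest.approx(0.52554, abs=1e-4)
        assert 0.4 < noe < 0.9

    def test_flexible_residue_noe_is_negative(self, field600):
        # sub-ns internal motion decoupled from tumbling drives the NOE negative
        _, _, noe = predict_rates(0.05, 0.3e-9, TAU_M, field600)
        assert noe < 0

    def test_slow_tumbling_orders_r2_above_r1(self, field600):
        r1, r2, _ = predict_rates(0.85, 50e-12, TAU_M, field600)
        assert r2 > r1 > 0

    def test_r2_monotone_in_s2(self, field600):
        r2s = [predict_rates(s2, 50e-12, TAU_M, field600)[1]
               for s2 in np.linspace(0.1, 1.0, 10)]
        assert np.all(np.diff(r2s) >= 0)


class TestEstimateTauM:
    def _rigid_records(self, n=20, field=600.0, tau_m=TAU_M, rng=None):
        rng = rng or np.random.default_rng(4)
        ctx = FieldContext(field)
        records = []
        for i in range(1, n + 1):
            s2 = rng.uniform(0.75, 0.95)
            r1, r2, noe = predict_rates(s2, 0.0, tau_m, ctx)
            records += records_from_rates(r1, r2, noe, field, res=ResidueKey(i, "A"))
        return records

    def test_round_trip_recovers_28ns(self):
        est = estimate_tau_m(self._rigid_records())
        assert est.tau_m == pytest.approx(TAU_M, rel=1e-3)
        assert est.n_used == 20

    def test_trimming_is_robust_to_exchange_contamination(self):
        records = self._rigid_records(n=40)
        ctx = FieldContext(600.0)
        rng = np.random.default_rng(8)
        contaminated = list(records)
        for i in range(41, 49):  # 20% of residues with strong Rex
            s2 = rng.uniform(0.75, 0.95)
            r1, r2, noe = predict_rates(s2, 0.0, TAU_M, ctx, r_ex=10.0)
            contaminated += records_from_rates(r1, r2, noe, res=ResidueKey(i, "A"))
        clean = estimate_tau_m(records).tau_m
        robust = estimate_tau_m(contaminated).tau_m
        assert abs(robust - clean) / clean < 0.05

    def test_identical_residues_share_the_common_root(self):
        ctx = FieldContext(600.0)
        r1, r2, noe = predict_rates(1.0, 0.0, TAU_M, ctx)
        records = []
        for i in range(1, 13):
            records += records_from_rates(r1, r2, noe, res=ResidueKey(i, "A"))
        est = estimate_tau_m(records)
        assert est.n_used == 12
        assert est.tau_m == pytest.approx(TAU_M, rel=1e-6)

    def test_too_few_residues_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_tau_m(self._rigid_records(n=5))

    def test_mixed_fields_rejected(self):
        records = self._rigid_records(n=6) + self._rigid_records(n=6, field=850.0)
        with pytest.raises(ConsistencyError):
            estimate_tau_m(records)


class TestFitModelfree:
    def test_model2_noiseless_self_consistency(self, field600):
        r1, r2, noe = predict_rates(0.85, 50e-12, TAU_M, field600)
        mf = fit_modelfree(records_from_rates(r1, r2, noe), 2, TAU_M, mc_reps=0)
        assert mf.s2 == pytest.approx(0.85, rel=1e-6)
        assert mf.tau_e == pytest.approx(50e-12, rel=1e-6)
        assert mf.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_model4_noiseless_round_trip(self, field600, field850):
        records = []
        for ctx in (field600, field850):
            scale = (ctx.proton_frequency_MHz / 600.0) ** 2
            r1, r2, noe = predict_rates(0.9, 30e-12, TAU_M, ctx, r_ex=4.0 * scale)
            records += records_from_rates(r1, r2, noe, ctx.proton_frequency_MHz)
        mf = fit_modelfree(records, 4, TAU_M, mc_reps=0)
        assert mf.s2 == pytest.approx(0.9, rel=1e-4)
        assert mf.tau_e == pytest.approx(30e-12, rel=1e-4)
        assert mf.r_ex == pytest.approx(4.0, rel=1e-4)

    def test_model4_needs_two_fields(self, field600):
        r1, r2, noe = predict_rates(0.9, 30e-12, TAU_M, field600)
        with pytest.raises(InsufficientDataError):
            fit_modelfree(records_from_rates(r1, r2, noe), 4, TAU_M)

    def test_noisy_s2_accuracy_small_study(self, field600):
        rng = np.random.default_rng(21)
        errs = []
        for i in range(40):
            s2 = rng.uniform(0.75, 0.95)
            tau_e = rng.uniform(10e-12, 100e-12)
            vals = np.array(predict_rates(s2, tau_e, TAU_M, field600))
            sig = 0.02 * np.abs(vals)
            obs = vals + rng.normal(0, sig)
            mf = fit_modelfree(records_from_rates(*obs, sigma=tuple(sig)), 2,
                               TAU_M, mc_reps=0)
            errs.append(abs(mf.s2 - s2))
        assert np.median(errs) <= 0.02

    def test_flexible_residues_fit_below_core_residues(self, field600):
        # the C-terminal-arm signature: fitted S2 separates low-S2 from
        # high-S2 ground truths in virtually every noisy draw
        rng = np.random.default_rng(33)
        hits = 0
        reps = 500
        for _ in range(reps):
            s2_core = rng.uniform(0.8, 0.95)
            s2_arm = rng.uniform(0.05, 0.3)
            fits = []
            for s2, tau_e in ((s2_core, rng.uniform(10e-12, 100e-12)),
                              (s2_arm, rng.uniform(0.1e-9, 0.6e-9))):
                vals = np.array(predict_rates(s2, tau_e, TAU_M, field600))
                sig = 0.02 * np.abs(vals)
                obs = vals + rng.normal(0, sig)
                obs[2] = min(obs[2], 1.2)
                mf = fit_modelfree(records_from_rates(*obs, sigma=tuple(sig)),
                                   2, TAU_M, mc_reps=0, n_starts=6)
                fits.append(mf.s2)
            if fits[1] < fits[0]:
                hits += 1
        assert hits >= 0.98 * reps

    def test_mc_errors_are_reported_and_positive(self, field600):
        vals = np.array(predict_rates(0.85, 50e-12, TAU_M, field600))
        sig = 0.02 * np.abs(vals)
        mf = fit_modelfree(records_from_rates(*vals, sigma=tuple(sig)), 2,
                           TAU_M, mc_reps=50, seed=7)
        assert mf.errors["s2"] > 0
        assert mf.errors["tau_e"] > 0
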