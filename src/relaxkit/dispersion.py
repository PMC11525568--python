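"""CPMG relaxation-dispersion analysis for two-site chemical exchange.

Effective transverse rates R2eff(nu_cpmg) are computed from constant-time
intensities, modelled either as exchange-free (flat), fast-limit
two-site exchange (Luz-Meiboom) or general two-site exchange
(Carver-Richards closed form, valid on all time scales), fitted jointly
over two static fields with the chemical-shift difference delta_omega
shared in ppm, and compared by an F-test at a configurable P cut-off
(default 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .data_io import ResidueKey
from .errors import ConsistencyError, InsufficientDataError
from .modelfree import FieldContext

MODEL_NO_EXCHANGE = "no_exchange"
MODEL_FAST = "fast_exchange"
MODEL_CR = "carver_richards"

FLAG_NON_CONVERGED = "non_converged"

KEX_BOUNDS = (100.0, 10000.0)
PA_BOUNDS = (0.6, 0.999)
DW_BOUNDS = (0.1, 8.0)  # ppm

_NU_INFINITE = 1e9  # Hz; proxy for the full-refocusing limit


@dataclass
class DispersionProfile:
    """R2eff versus CPMG refocusing frequency for one residue at one field."""

    residue: ResidueKey
    fieldctx: FieldContext
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    errors: np.ndarray
    t_relax: float

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if not (len(self.nu_cpmg) == len(self.r2eff) == len(self.errors)):
            raise ValueError("nu_cpmg, r2eff and errors must have equal length")
        if np.any(self.nu_cpmg <= 0) or np.any(np.diff(self.nu_cpmg) <= 0):
            raise ValueError("nu_cpmg must be positive and strictly increasing")
        if not (self.t_relax > 0):
            raise ValueError("t_relax must be positive")


@dataclass
class ExchangeFit:
    """A fitted dispersion model for one residue (one or two fields).

    ``r2_0`` maps proton frequency (MHz) to the exchange-free plateau;
    ``delta_omega_ppm`` is shared across fields; ``r_ex`` maps field to
    model(nu_min) - model(nu -> infinity).  ``f_statistic``/``p_value``
    are filled by :func:`select_model`.
    """

    residue: ResidueKey
    model_id: str
    r2_0: dict[float, float]
    k_ex: float | None
    p_a: float | None
    delta_omega_ppm: float | None
    chi2: float
    n_points: int
    n_params: int
    r_ex: dict[float, float] = field(default_factory=dict)
    errors: dict[str, float] = field(default_factory=dict)
    f_statistic: float | None = None
    p_value: float | None = None
    flags: tuple[str, ...] = ()


class R2effResult(NamedTuple):
    r2eff: np.ndarray
    errors: np.ndarray
    excluded: np.ndarray  # boolean mask of dropped (non-positive) intensities


def intensities_to_r2eff(intensities, i0: float, t_relax: float,
                         noise_sigma: float = 0.0) -> R2effResult:
    """R2eff = -(1/T) ln(I/I0) with error sigma_I/(I*T).

    Points with non-positive intensity (signal below noise) are flagged in
    ``excluded`` and returned as NaN.
    """
    if not (i0 > 0):
        raise ValueError("reference intensity I0 must be positive")
    if not (t_relax > 0):
        raise ValueError("t_relax must be positive")
    i = np.asarray(intensities, dtype=float)
    excluded = i <= 0
    safe = np.where(excluded, np.nan, i)
    r2eff = -np.log(safe / i0) / t_relax
    errors = noise_sigma / (safe * t_relax)
    return R2effResult(r2eff, errors, excluded)


def _dw_rad(delta_omega_ppm: float, fieldctx: FieldContext) -> float:
    return delta_omega_ppm * 1e-6 * abs(fieldctx.omega_n)


def r2eff_fast_exchange(nu_cpmg, r2_0: float, k_ex: float, p_a: float,
                        delta_omega_ppm: float, fieldctx: FieldContext):
    """Luz-Meiboom fast-exchange profile.

    R2eff = R2_0 + (Phi/kex)[1 - (4 nu/kex) tanh(kex/(4 nu))],
    Phi = pA pB dw^2 (rad^2/s^2).
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    dw = _dw_rad(delta_omega_ppm, fieldctx)
    phi = p_a * (1.0 - p_a) * dw * dw
    x = k_ex / (4.0 * nu)
    out = r2_0 + (phi / k_ex) * (1.0 - np.tanh(x) / x)
    return float(out) if out.ndim == 0 else out


def r2eff_carver_richards(nu_cpmg, r2_0: float, k_ex: float, p_a: float,
                          delta_omega_ppm: float, fieldctx: FieldContext):
    """Carver-Richards closed-form two-site profile (equal intrinsic R2).

    Valid on all exchange time scales; reduces to Luz-Meiboom for
    kex >> dw and to a flat line as dw -> 0.  nu_cpmg = 1/(2 tau_cp) with
    tau_cp the duration of one tau-180-tau refocusing element.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    p_b = 1.0 - p_a
    dw = _dw_rad(delta_omega_ppm, fieldctx)
    if dw == 0.0:
        out = np.full_like(nu, float(r2_0))
        return float(out) if out.ndim == 0 else out
    psi = k_ex * k_ex - dw * dw
    zeta = -2.0 * dw * k_ex * (p_a - p_b)
    root = math.hypot(psi, zeta)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)
    tau_cp = 1.0 / (2.0 * nu)
    eta_plus = (tau_cp / math.sqrt(2.0)) * math.sqrt(max(psi + root, 0.0))
    eta_minus = (tau_cp / math.sqrt(2.0)) * math.sqrt(max(root - psi, 0.0))
    arg = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
    out = r2_0 + 0.5 * k_ex - nu * np.arccosh(np.maximum(arg, 1.0))
    return float(out) if out.ndim == 0 else out


def model_r2eff(model_id: str, nu_cpmg, fieldctx: FieldContext, r2_0: float,
                k_ex: float | None = None, p_a: float | None = None,
                delta_omega_ppm: float | None = None):
    """Dispatch to the requested dispersion model (delta_omega in ppm)."""
    nu = np.asarray(nu_cpmg, dtype=float)
    if model_id == MODEL_NO_EXCHANGE:
        out = np.full_like(nu, float(r2_0))
        return float(out) if out.ndim == 0 else out
    if model_id == MODEL_FAST:
        return r2eff_fast_exchange(nu, r2_0, k_ex, p_a, delta_omega_ppm, fieldctx)
    if model_id == MODEL_CR:
        return r2eff_carver_richards(nu, r2_0, k_ex, p_a, delta_omega_ppm, fieldctx)
    raise ValueError(f"unknown model {model_id!r}")


def _check_profiles(profiles: Sequence[DispersionProfile]) -> ResidueKey:
    residues = {p.residue for p in profiles}
    if len(residues) != 1:
        raise ConsistencyError("fit_dispersion expects profiles for exactly one residue")
    if len({p.fieldctx.proton_frequency_MHz for p in profiles}) != len(profiles):
        raise ConsistencyError("one profile per field expected")
    for p in profiles:
        ok = np.isfinite(p.r2eff)
        if ok.sum() < 6:
            raise InsufficientDataError(
                f"{p.residue.label} at {p.fieldctx.proton_frequency_MHz} MHz: "
                f"need >= 6 points, got {int(ok.sum())}")
    return residues.pop()


def fit_no_exchange(profiles: Sequence[DispersionProfile]) -> ExchangeFit:
    """Weighted per-field constant (closed form)."""
    residue = _check_profiles(profiles)
    r2_0: dict[float, float] = {}
    chi2 = 0.0
    n = 0
    for p in profiles:
        ok = np.isfinite(p.r2eff)
        w = np.where(p.errors[ok] > 0, 1.0 / np.where(p.errors[ok] > 0, p.errors[ok], 1.0), 1.0)
        mean = float(np.sum(w * w * p.r2eff[ok]) / np.sum(w * w))
        r2_0[p.fieldctx.proton_frequency_MHz] = mean
        chi2 += float(np.sum(((p.r2eff[ok] - mean) * w) ** 2))
        n += int(ok.sum())
    return ExchangeFit(residue, MODEL_NO_EXCHANGE, r2_0, None, None, None,
                       chi2, n, len(r2_0),
                       r_ex={f: 0.0 for f in r2_0})


_KEX_STARTS = (200.0, 1000.0, 5000.0)
_PA_STARTS = (0.7, 0.95)
_DW_STARTS = (0.5, 2.0, 5.0)


def fit_dispersion(profiles: Sequence[DispersionProfile], model_id: str = MODEL_CR,
                   mc_reps: int = 100, seed: int = 0,
                   starts: Sequence[tuple[float, float, float]] | None = None) -> ExchangeFit:
    """Joint bounded least-squares fit of an exchange model over 1-2 fields.

    delta_omega is shared across fields in ppm; R2_0 is per field.
    Multi-start over a (kex, pA, dw) grid; Monte-Carlo parameter errors;
    Rex reported per field as model(nu_min) - model(nu -> infinity).
    """
    if model_id == MODEL_NO_EXCHANGE:
        return fit_no_exchange(profiles)
    if model_id not in (MODEL_FAST, MODEL_CR):
        raise ValueError(f"unknown model {model_id!r}")
    residue = _check_profiles(profiles)
    profiles = sorted(profiles, key=lambda p: p.fieldctx.proton_frequency_MHz)
    fields = [p.fieldctx.proton_frequency_MHz for p in profiles]

    masks = [np.isfinite(p.r2eff) for p in profiles]
    ys = [p.r2eff[m] for p, m in zip(profiles, masks)]
    ws = [np.where(p.errors[m] > 0, 1.0 / np.where(p.errors[m] > 0, p.errors[m], 1.0), 1.0)
          for p, m in zip(profiles, masks)]
    nus = [p.nu_cpmg[m] for p, m in zip(profiles, masks)]
    n_points = sum(len(y) for y in ys)
    nf = len(profiles)

    def unpack(x):
        return x[:nf], x[nf], x[nf + 1], x[nf + 2]

    def resid(x):
        r2_0s, kex, pa, dw = unpack(x)
        parts = []
        for i, p in enumerate(profiles):
            pred = model_r2eff(model_id, nus[i], p.fieldctx, r2_0s[i], kex, pa, dw)
            parts.append((pred - ys[i]) * ws[i])
        return np.concatenate(parts)

    lb = [0.0] * nf + [KEX_BOUNDS[0], PA_BOUNDS[0], DW_BOUNDS[0]]
    ub = [500.0] * nf + [KEX_BOUNDS[1], PA_BOUNDS[1], DW_BOUNDS[1]]
    x_scale = [10.0] * nf + [1000.0, 0.1, 1.0]
    r2_0_guess = [float(np.min(y)) for y in ys]
    grid = starts if starts is not None else [
        (k, a, d) for k in _KEX_STARTS for a in _PA_STARTS for d in _DW_STARTS]

    best = None
    for (k0, a0, d0) in grid:
        x0 = np.array(r2_0_guess + [k0, a0, d0])
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                x_scale=x_scale, diff_step=1e-6, xtol=1e-10, ftol=1e-10,
                                gtol=None, max_nfev=150)
        except Exception:
            continue
        chi2 = float(np.sum(sol.fun ** 2))
        if best is None or chi2 < best[1]:
            best = (sol, chi2)
    flags: tuple[str, ...] = ()
    if best is None:
        raise InsufficientDataError(f"{residue.label}: no dispersion start converged")
    sol = least_squares(resid, best[0].x, bounds=(lb, ub), method="trf",
                        x_scale=x_scale, diff_step=1e-6, xtol=2.3e-16, ftol=2.3e-16,
                        gtol=None, max_nfev=400)
    chi2 = float(np.sum(sol.fun ** 2))
    r2_0s, kex, pa, dw = unpack(sol.x)
    r2_0 = {f: float(v) for f, v in zip(fields, r2_0s)}

    def rex_map(x) -> dict[float, float]:
        r2_0s_, kex_, pa_, dw_ = unpack(x)
        out = {}
        for i, p in enumerate(profiles):
            lo = model_r2eff(model_id, float(p.nu_cpmg[0]), p.fieldctx, r2_0s_[i], kex_, pa_, dw_)
            hi = model_r2eff(model_id, _NU_INFINITE, p.fieldctx, r2_0s_[i], kex_, pa_, dw_)
            out[p.fieldctx.proton_frequency_MHz] = float(lo - hi)
        return out

    errors: dict[str, float] = {}
    if mc_reps > 0 and any(np.any(p.errors > 0) for p in profiles):
        rng = np.random.default_rng(seed)
        clean = [model_r2eff(model_id, nus[i], p.fieldctx, r2_0s[i], kex, pa, dw)
                 for i, p in enumerate(profiles)]
        sig = [p.errors[m] for p, m in zip(profiles, masks)]
        draws = np.empty((mc_reps, len(sol.x)))
        for rep in range(mc_reps):
            ys_mc = [c + rng.normal(0.0, np.where(s > 0, s, 0.0)) for c, s in zip(clean, sig)]

            def resid_mc(x):
                r2_0s_, kex_, pa_, dw_ = unpack(x)
                parts = []
                for i, p in enumerate(profiles):
                    pred = model_r2eff(model_id, nus[i], p.fieldctx, r2_0s_[i], kex_, pa_, dw_)
                    parts.append((pred - ys_mc[i]) * ws[i])
                return np.concatenate(parts)

            sol_mc = least_squares(resid_mc, sol.x, bounds=(lb, ub), method="trf",
                                   x_scale=x_scale, diff_step=1e-6, xtol=1e-10, ftol=1e-10, max_nfev=200)
            draws[rep] = sol_mc.x
        for j, name in enumerate([f"r2_0_{f:g}" for f in fields] + ["k_ex", "p_a", "delta_omega_ppm"]):
            errors[name] = float(np.std(draws[:, j], ddof=1))

    return ExchangeFit(residue, model_id, r2_0, float(kex), float(pa), float(dw),
                       chi2, n_points, nf + 3, r_ex=rex_map(sol.x),
                       errors=errors, flags=flags)


class ModelChoice(NamedTuple):
    chosen: str
    f_statistic: float
    p_value: float


def select_model(fit_null: ExchangeFit, fit_alt: ExchangeFit, n_points: int,
                 p_cutoff: float = 0.1) -> ModelChoice:
    """F-test between nested dispersion fits on identical data.

    F = [(chi2_null - chi2_alt)/(df_null - df_alt)] / [chi2_alt/df_alt];
    the exchange model is chosen iff P < p_cutoff.  A perfect alternative
    fit over a perfect null fit resolves to the null model (parsimony).
    """
    if fit_alt.n_params <= fit_null.n_params:
        raise ValueError("alternative model must have more parameters than the null")
    df_null = n_points - fit_null.n_params
    df_alt = n_points - fit_alt.n_params
    if df_alt <= 0:
        raise InsufficientDataError("not enough points for the alternative model")
    if fit_alt.chi2 <= 0.0:
        if fit_null.chi2 <= 0.0:
            return ModelChoice(fit_null.model_id, 0.0, 1.0)
        return ModelChoice(fit_alt.model_id, math.inf, 0.0)
    f_stat = max(fit_null.chi2 - fit_alt.chi2, 0.0) / (df_null - df_alt) / (fit_alt.chi2 / df_alt)
    p = float(f_dist.sf(f_stat, df_null - df_alt, df_alt))
    chosen = fit_alt.model_id if p < p_cutoff else fit_null.model_id
    return ModelChoice(chosen, float(f_stat), p)
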