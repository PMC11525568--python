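"""Lipari-Szabo model-free analysis of backbone 15N relaxation.

The spectral density is the classic two-Lorentzian form

    J(w) = (2/5) [ S^2 tau_m / (1 + (w tau_m)^2)
                   + (1 - S^2) tau / (1 + (w tau)^2) ],   1/tau = 1/tau_m + 1/tau_e

with S^2 the generalized order parameter, tau_m the global rotational
correlation time and tau_e the effective internal correlation time.
R1, R2 and the heteronuclear NOE follow from the standard 15N dipolar +
CSA expressions.  Two per-residue models are supported:

* model 2 - fit (S^2, tau_e), suitable for single-field data;
* model 4 - fit (S^2, tau_e, Rex), requiring two static fields; the
  exchange term is parameterized at the lowest field and scaled with the
  square of the field ratio.

The global tau_m is estimated once from the trimmed R2/R1 ratio of
rigid-looking residues and then held fixed for the per-residue fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .data_io import ResidueKey
from .errors import ConsistencyError, InsufficientDataError
from .rate_fitting import RateRecord

FLAG_AT_BOUND = "at_bound"


@dataclass(frozen=True)
class PhysicalConstants:
    """Interaction constants for the 15N-1H spin pair.

    Defaults are the common literature choices: N-H bond length 1.02 A and
    an axially symmetric 15N CSA of -160 ppm.  They are overridable via
    configuration; changing them shifts absolute S^2 only slightly.
    """

    nh_bond_length_A: float = 1.02
    csa_ppm: float = -160.0
    gamma_h: float = 2.6752218744e8   # rad s^-1 T^-1
    gamma_n: float = -2.7126e7        # rad s^-1 T^-1
    mu0: float = 1.25663706212e-6     # N A^-2
    hbar: float = 1.054571817e-34     # J s

    @property
    def gamma_ratio(self) -> float:
        """gamma_N / gamma_H (about -0.1014)."""
        return self.gamma_n / self.gamma_h

    @property
    def dipolar_constant(self) -> float:
        """d = (mu0/4pi) hbar gamma_H gamma_N / r_NH^3, rad/s (sign carried)."""
        r = self.nh_bond_length_A * 1e-10
        return self.mu0 * self.hbar * self.gamma_h * self.gamma_n / (4 * math.pi * r ** 3)


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class FieldContext:
    """A static magnetic field stated as the proton Larmor frequency in MHz."""

    proton_frequency_MHz: float
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if not (self.proton_frequency_MHz > 0):
            raise ValueError("proton frequency must be positive")

    @property
    def omega_h(self) -> float:
        """1H angular frequency, rad/s (positive by convention)."""
        return 2 * math.pi * self.proton_frequency_MHz * 1e6

    @property
    def omega_n(self) -> float:
        """15N angular frequency, rad/s (negative: gamma_N < 0)."""
        return self.omega_h * self.constants.gamma_ratio

    @property
    def csa_constant(self) -> float:
        """c = omega_N * delta_sigma / sqrt(3), rad/s."""
        return self.omega_n * self.constants.csa_ppm * 1e-6 / math.sqrt(3.0)


def spectral_density(omega, s2: float, tau_m: float, tau_e: float):
    """Lipari-Szabo spectral density J(omega) in s/rad.

    Accepts scalar or array omega (even in omega).  tau_e = 0 collapses
    the internal-motion Lorentzian.
    """
    if not (0.0 <= s2 <= 1.0):
        raise ValueError("S^2 must lie in [0, 1]")
    if not (tau_m > 0) or tau_e < 0:
        raise ValueError("tau_m must be positive and tau_e non-negative")
    omega = np.asarray(omega, dtype=float)
    j = s2 * tau_m / (1.0 + (omega * tau_m) ** 2)
    if tau_e > 0:
        tau = tau_m * tau_e / (tau_m + tau_e)
        j = j + (1.0 - s2) * tau / (1.0 + (omega * tau) ** 2)
    out = 0.4 * j
    return float(out) if out.ndim == 0 else out


def predict_rates(s2: float, tau_e: float, tau_m: float, fieldctx: FieldContext,
                  r_ex: float = 0.0,
                  constants: PhysicalConstants | None = None) -> tuple[float, float, float]:
    """Forward-predict (R1, R2, NOE) from model-free parameters at one field.

    Standard 15N dipolar + CSA expressions; ``r_ex`` adds directly to R2.
    """
    c0 = constants if constants is not None else fieldctx.constants
    wh = fieldctx.omega_h
    wn = abs(fieldctx.omega_n)
    jw = spectral_density(np.array([0.0, wn, wh - wn, wh, wh + wn]), s2, tau_m, tau_e)
    j0, jn, jhmn, jh, jhpn = jw
    dd = c0.dipolar_constant ** 2 / 4.0
    cc = fieldctx.csa_constant ** 2
    r1 = dd * (jhmn + 3 * jn + 6 * jhpn) + cc * jn
    r2 = (dd / 2.0) * (4 * j0 + jhmn + 3 * jn + 6 * jh + 6 * jhpn) \
        + (cc / 6.0) * (4 * j0 + 3 * jn) + r_ex
    noe = 1.0 + dd * (1.0 / c0.gamma_ratio) * (6 * jhpn - jhmn) / r1
    return float(r1), float(r2), float(noe)


@dataclass
class ModelFreeResult:
    """Per-residue model-free fit.

    ``r_ex`` (s^-1, at the reference field) is present only for model 4.
    ``errors`` holds Monte-Carlo standard deviations keyed by parameter
    name; ``chi2`` is the weighted sum of squared residuals.
    """

    residue: ResidueKey
    model_id: int
    s2: float
    tau_e: float
    tau_m_global: float
    r_ex: float | None = None
    errors: dict[str, float] = field(default_factory=dict)
    chi2: float = math.nan
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model_id not in (2, 4):
            raise ValueError("model_id must be 2 or 4")
        if not (0.0 <= self.s2 <= 1.0):
            raise ValueError("S^2 out of [0, 1]")
        if self.tau_e >= self.tau_m_global:
            raise ValueError("tau_e must be below the global tau_m")
        if (self.r_ex is not None) != (self.model_id == 4):
            raise ValueError("Rex present iff model 4")


@dataclass
class TauMEstimate:
    tau_m: float
    n_used: int
    per_residue: dict[ResidueKey, float]


def _group_by_residue(rates: Iterable[RateRecord]) -> dict[ResidueKey, dict[tuple[float, str], RateRecord]]:
    grouped: dict[ResidueKey, dict[tuple[float, str], RateRecord]] = {}
    for r in rates:
        grouped.setdefault(r.residue, {})[(r.field_MHz, r.observable)] = r
    return grouped


def _rigid_ratio(tau_m: float, fieldctx: FieldContext) -> float:
    r1, r2, _ = predict_rates(1.0, 0.0, tau_m, fieldctx)
    return r2 / r1


def estimate_tau_m(rates: Sequence[RateRecord], trim_noe_min: float = 0.65,
                   trim_fraction: float = 0.1,
                   tau_bounds_ns: tuple[float, float] = (1.0, 100.0)) -> TauMEstimate:
    """Global rotational correlation time from the R2/R1 ratio.

    For each residue with R1, R2 and NOE at one common field, the rigid
    (S^2-independent) R2/R1 ratio equation is solved for tau_m by 1-D root
    finding.  Residues with NOE below ``trim_noe_min`` (fast internal
    motion) are excluded, and the result is the median after symmetric
    trimming of ``trim_fraction`` of the per-residue values from each end
    (exchange-broadened residues sit in the upper tail).
    """
    fields = {r.field_MHz for r in rates}
    if len(fields) != 1:
        raise ConsistencyError(f"tau_m estimation expects rates at one field, got {sorted(fields)}")
    fieldctx = FieldContext(fields.pop())
    grouped = _group_by_residue(rates)
    if len(grouped) < 10:
        raise InsufficientDataError(f"need >= 10 residues, got {len(grouped)}")

    lo, hi = tau_bounds_ns[0] * 1e-9, tau_bounds_ns[1] * 1e-9
    per_residue: dict[ResidueKey, float] = {}
    key = fieldctx.proton_frequency_MHz
    for res, obs in grouped.items():
        try:
            r1 = obs[(key, "R1")]
            r2 = obs[(key, "R2")]
            noe = obs[(key, "NOE")]
        except KeyError:
            continue
        if noe.value < trim_noe_min:
            continue
        target = r2.value / r1.value
        f_lo = _rigid_ratio(lo, fieldctx) - target
        f_hi = _rigid_ratio(hi, fieldctx) - target
        if f_lo * f_hi > 0:
            continue  # ratio outside the achievable rigid range
        per_residue[res] = brentq(lambda tm: _rigid_ratio(tm, fieldctx) - target, lo, hi,
                                  xtol=1e-15)
    n_used = len(per_residue)
    if n_used < 5:
        raise InsufficientDataError(f"only {n_used} residues usable for tau_m")
    values = np.sort(np.array(list(per_residue.values())))
    k = int(math.floor(trim_fraction * n_used))
    trimmed = values[k:len(values) - k] if k > 0 else values
    return TauMEstimate(float(np.median(trimmed)), n_used, per_residue)


_S2_STARTS = (0.2, 0.5, 0.8, 0.95)
_TAUE_STARTS = (1e-11, 1e-10, 1e-9, 5e-9)
_REX_STARTS = (0.0, 2.0, 8.0, 30.0)
REX_MAX = 100.0


def _collect_observables(rates: Sequence[RateRecord]) -> tuple[list[FieldContext], np.ndarray, np.ndarray]:
    """Sort records into per-field (R1, R2, NOE) triples."""
    by_field: dict[float, dict[str, RateRecord]] = {}
    for r in rates:
        by_field.setdefault(r.field_MHz, {})[r.observable] = r
    fields = sorted(by_field)
    obs, sig = [], []
    ctxs = []
    for f in fields:
        triple = by_field[f]
        missing = {"R1", "R2", "NOE"} - set(triple)
        if missing:
            raise InsufficientDataError(f"field {f}: missing observables {sorted(missing)}")
        ctxs.append(FieldContext(f))
        for kind in ("R1", "R2", "NOE"):
            obs.append(triple[kind].value)
            sig.append(triple[kind].error)
    return ctxs, np.array(obs), np.array(sig)


def fit_modelfree(rates: Sequence[RateRecord], model_id: int, tau_m: float,
                  mc_reps: int = 200, seed: int = 0,
                  constants: PhysicalConstants | None = None,
                  n_starts: int | None = None) -> ModelFreeResult:
    """Fit model 2 (S^2, tau_e) or model 4 (S^2, tau_e, Rex) for one residue.

    Bounded least squares with a multi-start grid to escape the
    tau_e/S^2 trade-off; ties broken by lowest chi^2, then lowest tau_e.
    Records with zero error are weighted uniformly (noiseless closure).
    Model 4 exchange is parameterized at the lowest field and scaled by
    the squared field ratio at the other field.
    """
    residues = {r.residue for r in rates}
    if len(residues) != 1:
        raise ConsistencyError("fit_modelfree expects records for exactly one residue")
    residue = residues.pop()
    ctxs, obs, sig = _collect_observables(rates)
    if model_id == 4 and len(ctxs) < 2:
        raise InsufficientDataError("model 4 requires observables at two fields")
    if model_id not in (2, 4):
        raise ValueError("model_id must be 2 or 4")
    # zero-error records (noiseless closure) get relative weighting so the
    # large R2 values do not drown the R1/NOE residuals
    weights = np.where(sig > 0, 1.0 / np.where(sig > 0, sig, 1.0),
                       1.0 / np.maximum(np.abs(obs), 1e-3))
    f_ref = ctxs[0].proton_frequency_MHz

    def predict_vec(x: np.ndarray) -> np.ndarray:
        s2, tau_e = x[0], x[1]
        rex = x[2] if model_id == 4 else 0.0
        out = []
        for ctx in ctxs:
            scale = (ctx.proton_frequency_MHz / f_ref) ** 2
            out.extend(predict_rates(s2, tau_e, tau_m, ctx, r_ex=rex * scale,
                                     constants=constants))
        return np.array(out)

    def resid(x: np.ndarray) -> np.ndarray:
        return (predict_vec(x) - obs) * weights

    if model_id == 2:
        lb, ub = [0.0, 0.0], [1.0, tau_m * (1 - 1e-9)]
        x_scale = [0.1, 0.05 * tau_m]
        starts = [(a, min(b, 0.9 * tau_m)) for a in _S2_STARTS for b in _TAUE_STARTS]
    else:
        lb, ub = [0.0, 0.0, 0.0], [1.0, tau_m * (1 - 1e-9), REX_MAX]
        x_scale = [0.1, 0.05 * tau_m, 1.0]
        starts = [(a, min(b, 0.9 * tau_m), c)
                  for a in _S2_STARTS for b in _TAUE_STARTS for c in _REX_STARTS]
    if n_starts is not None:
        starts = starts[::max(1, len(starts) // n_starts)][:n_starts]

    # coarse multi-start, then polish the leading candidates to machine
    # precision (the tau_e/S^2 valley can mis-rank coarse fits)
    coarse = []
    for x0 in starts:
        sol = least_squares(resid, np.array(x0), bounds=(lb, ub), method="trf",
                            x_scale=x_scale, diff_step=1e-6, xtol=1e-10, ftol=1e-10,
                            gtol=None, max_nfev=100)
        coarse.append((float(np.sum(sol.fun ** 2)), sol.x))
    coarse.sort(key=lambda c: c[0])
    polished = []
    for _, x0 in coarse[:3]:
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            x_scale=x_scale, diff_step=1e-6, xtol=2.3e-16, ftol=2.3e-16,
                            gtol=None, max_nfev=400)
        polished.append((float(np.sum(sol.fun ** 2)), sol))
    # lowest chi^2 wins; a tie (within 1e-6 relative) breaks to lowest tau_e
    chi2_min = min(c for c, _ in polished)
    ties = [(c, s) for c, s in polished if c <= chi2_min * (1 + 1e-6) + 1e-30]
    chi2, sol = min(ties, key=lambda t: t[1].x[1])
    x_hat = sol.x

    flags: tuple[str, ...] = ()
    at_upper = [x_hat[0] > 1 - 1e-9, x_hat[1] > ub[1] * (1 - 1e-9)]
    if model_id == 4:
        at_upper.append(x_hat[2] > REX_MAX * (1 - 1e-9))
    if any(at_upper) or x_hat[0] < 1e-12:
        flags += (FLAG_AT_BOUND,)

    names = ["s2", "tau_e"] + (["r_ex"] if model_id == 4 else [])
    errors: dict[str, float] = {}
    if mc_reps > 0 and np.any(sig > 0):
        rng = np.random.default_rng(seed)
        clean = predict_vec(x_hat)
        draws = np.empty((mc_reps, len(x_hat)))
        for i in range(mc_reps):
            obs_mc = clean + rng.normal(0.0, np.where(sig > 0, sig, 0.0))
            sol_mc = least_squares(lambda x: (predict_vec(x) - obs_mc) * weights,
                                   x_hat, bounds=(lb, ub), method="trf",
                                   x_scale=x_scale, diff_step=1e-6, xtol=1e-12, ftol=1e-12,
                                   max_nfev=200)
            draws[i] = sol_mc.x
        for j, name in enumerate(names):
            errors[name] = float(np.std(draws[:, j], ddof=1))

    return ModelFreeResult(
        residue=residue, model_id=model_id, s2=float(x_hat[0]),
        tau_e=float(x_hat[1]), tau_m_global=tau_m,
        r_ex=float(x_hat[2]) if model_id == 4 else None,
        errors=errors, chi2=chi2, flags=flags,
    )


def aic(result: ModelFreeResult, n_obs: int) -> float:
    """Akaike information criterion chi^2 + 2k (informational only; model
    choice between 2 and 4 is a configuration decision, not automated)."""
    k = 2 if result.model_id == 2 else 3
    return result.chi2 + 2 * k
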