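"""Relaxation observables from peak-intensity series.

Monoexponential decay fits give R1, R1rho or R2 (depending on the
experiment the delay series came from), saturated/reference intensity
pairs give the steady-state heteronuclear NOE, and the standard tilted
rotating-frame correction converts R1rho to R2.  Uncertainties come from
seeded parametric Monte-Carlo refits at the spectral noise level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .data_io import IntensitySeries, ResidueKey
from .errors import ConsistencyError, InsufficientDataError

OBSERVABLES = ("R1", "R1rho", "R2", "NOE")

FLAG_NON_CONVERGED = "non_converged"
FLAG_LOW_SIGNAL = "low_signal"
FLAG_UNRELIABLE_TILT = "unreliable_tilt"


@dataclass(frozen=True)
class RateRecord:
    """One fitted relaxation observable for one residue.

    ``value`` is in s^-1 (dimensionless for NOE); ``field_MHz`` is the
    proton Larmor frequency; quality flags travel with the record so
    downstream stages can see weak or non-converged residues instead of
    losing them.
    """

    residue: ResidueKey
    observable: str
    value: float
    error: float
    field_MHz: float
    temperature_K: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLES:
            raise ValueError(f"observable must be one of {OBSERVABLES}")
        if self.error < 0:
            raise ValueError("error must be non-negative")
        if self.observable in ("R1", "R1rho", "R2") and not self.flags and self.value <= 0:
            raise ValueError(f"{self.observable} must be positive (got {self.value})")
        if self.observable == "NOE" and self.value > 1.2:
            raise ValueError(f"NOE above sanity bound 1.2: {self.value}")

    def with_flag(self, flag: str) -> "RateRecord":
        return replace(self, flags=self.flags + (flag,))


@dataclass(frozen=True)
class SpinLockGeometry:
    """Spin-lock field strength omega1/2pi and resonance offset Omega/2pi (Hz)."""

    spinlock_strength_Hz: float
    offset_Hz: float

    def __post_init__(self) -> None:
        if not (self.spinlock_strength_Hz > 0):
            raise ValueError("spinlock_strength_Hz must be positive")

    @property
    def tilt_rad(self) -> float:
        """Tilt angle theta = arctan(omega1/Omega); pi/2 on resonance."""
        return math.atan2(self.spinlock_strength_Hz, abs(self.offset_Hz))


class MonoExpFit(NamedTuple):
    rate: float
    error: float
    i0: float
    flags: tuple[str, ...]


def _decay(t: np.ndarray, i0: float, rate: float) -> np.ndarray:
    return i0 * np.exp(-rate * t)


def _decay_offset(t: np.ndarray, i0: float, rate: float, base: float) -> np.ndarray:
    return i0 * np.exp(-rate * t) + base


def fit_monoexponential(series: IntensitySeries, mc_reps: int = 500, seed: int = 0,
                        fit_offset: bool = False) -> MonoExpFit:
    """Least-squares fit of I(t) = I0 exp(-R t) (+ optional baseline).

    The rate uncertainty is the standard deviation of the rate over
    ``mc_reps`` refits of the model-predicted intensities perturbed by
    Gaussian noise of scale ``series.noise_sigma`` (parametric bootstrap,
    reproducible under ``seed``).  ``mc_reps = 0`` skips the bootstrap and
    reports error 0.
    """
    if series.axis_kind != "delay_s":
        raise ValueError(f"expected axis_kind 'delay_s', got {series.axis_kind!r}")
    t = series.axis_values
    y = series.intensities
    if len(t) < 3:
        raise InsufficientDataError(f"{series.residue.label}: need >= 3 delay points, got {len(t)}")
    if np.ptp(y) == 0:
        raise InsufficientDataError(f"{series.residue.label}: intensities are all equal")

    # log-linear initial guess from the positive points
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = [math.exp(intercept), max(-slope, 1e-3)]
    else:
        p0 = [y[0] if y[0] != 0 else 1.0, 1.0]
    model = _decay_offset if fit_offset else _decay
    if fit_offset:
        p0 = p0 + [0.0]

    flags: tuple[str, ...] = ()
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=10000,
                            xtol=1e-14, ftol=1e-14)
    except RuntimeError:
        return MonoExpFit(math.nan, math.nan, math.nan, (FLAG_NON_CONVERGED,))
    i0_hat, rate_hat = popt[0], popt[1]

    err = 0.0
    if mc_reps > 0:
        rng = np.random.default_rng(seed)
        clean = model(t, *popt)
        rates = np.empty(mc_reps)
        for i in range(mc_reps):
            y_mc = clean + rng.normal(0.0, series.noise_sigma, size=len(t))
            try:
                p_mc, _ = curve_fit(model, t, y_mc, p0=popt, maxfev=2000)
                rates[i] = p_mc[1]
            except RuntimeError:
                rates[i] = math.nan
        ok = np.isfinite(rates)
        if ok.sum() < mc_reps // 2:
            flags += (FLAG_NON_CONVERGED,)
        err = float(np.std(rates[ok], ddof=1)) if ok.sum() > 1 else math.nan
    if abs(i0_hat) < 3 * series.noise_sigma:
        flags += (FLAG_LOW_SIGNAL,)
    return MonoExpFit(float(rate_hat), err, float(i0_hat), flags)


def monoexp_asymptotic_error(series: IntensitySeries, rate: float, i0: float) -> float:
    """Asymptotic (covariance-matrix) rate standard error for the same model.

    Provided as an independent check of the Monte-Carlo estimate: the
    Jacobian of I0*exp(-R t) is evaluated at the fit and sigma^2 (J^T J)^-1
    is returned for the rate entry.
    """
    t = series.axis_values
    e = np.exp(-rate * t)
    jac = np.column_stack([e, -i0 * t * e])
    cov = series.noise_sigma ** 2 * np.linalg.inv(jac.T @ jac)
    return float(math.sqrt(cov[1, 1]))


class NoeValue(NamedTuple):
    noe: float
    error: float
    flags: tuple[str, ...]


def compute_noe(i_sat: float, i_ref: float, noise_sigma: float) -> NoeValue:
    """Steady-state heteronuclear NOE = I_sat / I_ref.

    First-order propagation of the common noise level on both
    intensities:  sigma_NOE = (sigma/|I_ref|) sqrt(1 + (I_sat/I_ref)^2).
    Negative NOE is physical (flexible C-terminal residues); an
    ``i_ref`` within 3 sigma of zero is flagged low-signal.
    """
    if i_ref == 0:
        raise ValueError("reference intensity must be nonzero")
    noe = i_sat / i_ref
    error = abs(noise_sigma / i_ref) * math.sqrt(1.0 + noe * noe)
    flags = (FLAG_LOW_SIGNAL,) if abs(i_ref) < 3 * noise_sigma else ()
    return NoeValue(noe, error, flags)


def noe_from_series(series: IntensitySeries, field_MHz: float,
                    temperature_K: float) -> RateRecord:
    """NOE record from a noe_pair series (axis value 0 = reference, 1 = saturated)."""
    if series.axis_kind != "noe_pair":
        raise ValueError("expected a noe_pair series")
    axis = series.axis_values
    ref = series.intensities[axis == 0]
    sat = series.intensities[axis == 1]
    if len(ref) != 1 or len(sat) != 1:
        raise ConsistencyError("noe_pair series must hold exactly one reference and one saturated intensity")
    v = compute_noe(float(sat[0]), float(ref[0]), series.noise_sigma)
    return RateRecord(series.residue, "NOE", min(v.noe, 1.2), v.error,
                      field_MHz, temperature_K, v.flags)


def r1rho_to_r2(r1rho: RateRecord, r1: RateRecord, geom: SpinLockGeometry,
                min_tilt_deg: float = 30.0) -> RateRecord:
    """Tilted-frame correction R2 = R1rho/sin^2(theta) - R1 cos^2(theta)/sin^2(theta).

    theta = arctan(omega1/Omega) is the effective-field tilt.  Errors are
    propagated in quadrature.  Tilt angles below ``min_tilt_deg`` make the
    correction ill-conditioned and flag the record instead of failing.
    """
    if r1rho.observable != "R1rho" or r1.observable != "R1":
        raise ConsistencyError("expected an R1rho and an R1 record")
    if (r1rho.residue != r1.residue or r1rho.field_MHz != r1.field_MHz
            or r1rho.temperature_K != r1.temperature_K):
        raise ConsistencyError("R1rho and R1 records must share residue, field and temperature")
    theta = geom.tilt_rad
    sin2, cos2 = math.sin(theta) ** 2, math.cos(theta) ** 2
    r2 = (r1rho.value - r1.value * cos2) / sin2
    err = math.sqrt((r1rho.error / sin2) ** 2 + (r1.error * cos2 / sin2) ** 2)
    flags = r1rho.flags + r1.flags
    if theta < math.radians(min_tilt_deg):
        flags += (FLAG_UNRELIABLE_TILT,)
    return RateRecord(r1rho.residue, "R2", r2, err, r1rho.field_MHz,
                      r1rho.temperature_K, flags)
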