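"""Synthetic relaxation, dispersion and chemical-shift data generator.

Emulates the study conditions of a ~50 kDa homotrimer: global rotational
correlation time 28 ns, a rigid core (high S^2), a highly flexible
C-terminal arm (low S^2, negative NOE), an active-site patch with
millisecond-microsecond exchange, two static fields (600 and 850 MHz)
and Gaussian intensity noise.  Forward models are imported from the
analysis modules themselves, so closure tests exercise the fitting, not
a second transcription of the equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import IntensitySeries, ResidueKey, ShiftTable
from .dispersion import MODEL_CR, DispersionProfile, intensities_to_r2eff, model_r2eff
from .errors import ConfigError
from .modelfree import FieldContext, predict_rates

REGIONS = ("core", "c_terminal_arm", "active_site_patch")

_AA = "ACDEFGHIKLMNPQRSTVWY"

I0 = 1000.0  # reference peak intensity for all synthetic series

# parameter ranges per region (uniform draws)
CORE_S2 = (0.75, 0.95)
CORE_TAUE = (10e-12, 100e-12)
ARM_S2 = (0.02, 0.3)
# 0.1-0.6 ns at low S^2 puts the arm in the negative-NOE regime at 600 MHz
# (tau_e near 1/omega_N would instead boost R1 and push the NOE positive)
ARM_TAUE = (0.1e-9, 0.6e-9)
PATCH_KEX = (500.0, 3000.0)
PATCH_PA = (0.9, 0.99)
PATCH_DW = (0.5, 3.0)  # ppm


@dataclass(frozen=True)
class GroundTruthResidue:
    """True dynamics parameters behind one synthetic residue."""

    residue: ResidueKey
    region_label: str
    s2_true: float
    tau_e_true: float
    exchange_params_true: tuple[float, float, float] | None = None  # (kex, pA, dw_ppm)
    r_ex_true: dict[float, float] = field(default_factory=dict)  # per field MHz

    def __post_init__(self) -> None:
        if self.region_label not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.region_label == "c_terminal_arm" and self.s2_true > 0.3:
            raise ValueError("arm residues must have S^2 <= 0.3")
        if self.region_label == "core" and self.s2_true < 0.75:
            raise ValueError("core residues must have S^2 >= 0.75")
        if (self.exchange_params_true is not None) != (self.region_label == "active_site_patch"):
            raise ValueError("exchange parameters present iff active_site_patch")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults follow the system being emulated: tau_m = 28 ns, fields 600
    and 850 MHz, constant-time CPMG of 40 ms, 2% Gaussian intensity
    noise.  ``seed`` is mandatory; every generator is bit-reproducible
    under (config, seed).
    """

    seed: int
    n_residues: int = 120
    proportions: tuple[float, float, float] = (0.65, 0.12, 0.23)  # core, arm, patch
    tau_m: float = 28e-9
    fields_MHz: tuple[float, ...] = (600.0, 850.0)
    delays_r1: tuple[float, ...] = (0.01, 0.12, 0.3, 0.55, 0.9, 1.4, 2.1, 3.0)
    delays_r2: tuple[float, ...] = (0.002, 0.006, 0.011, 0.018, 0.028, 0.042, 0.062, 0.09)
    nu_cpmg: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0,
                                  400.0, 500.0, 600.0, 700.0, 800.0, 900.0, 1000.0)
    t_relax: float = 0.04
    noise: float = 0.02  # fractional intensity noise relative to I0
    temperature_K: float = 310.0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ConfigError("region proportions must sum to 1")
        if self.n_residues < 1:
            raise ConfigError("n_residues must be positive")
        if self.noise < 0:
            raise ConfigError("noise must be non-negative")

    @property
    def noise_sigma(self) -> float:
        """Absolute intensity noise; strictly positive even at noise = 0
        so series stay valid (the floor is far below one intensity count)."""
        return max(self.noise, 1e-9) * I0


def generate_ground_truth(config: SimulationConfig) -> list[GroundTruthResidue]:
    """Draw per-residue ground-truth parameters.

    The flexible arm occupies the C-terminal end of the sequence (as in
    the real construct); exchange-bearing patch residues are scattered
    through the remainder.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    n_arm = int(round(config.proportions[1] * n))
    n_patch = int(round(config.proportions[2] * n))
    n_core = n - n_arm - n_patch

    labels = ["core"] * n_core + ["active_site_patch"] * n_patch
    rng.shuffle(labels)
    labels += ["c_terminal_arm"] * n_arm  # arm at the C-terminus

    out: list[GroundTruthResidue] = []
    for i, region in enumerate(labels, start=1):
        res = ResidueKey(i, _AA[rng.integers(len(_AA))])
        if region == "c_terminal_arm":
            s2 = rng.uniform(*ARM_S2)
            tau_e = rng.uniform(*ARM_TAUE)
            exch = None
        else:
            s2 = rng.uniform(*CORE_S2)
            tau_e = rng.uniform(*CORE_TAUE)
            exch = None
            if region == "active_site_patch":
                exch = (rng.uniform(*PATCH_KEX), rng.uniform(*PATCH_PA),
                        rng.uniform(*PATCH_DW))
        r_ex = {}
        if exch is not None:
            kex, pa, dw = exch
            for f in config.fields_MHz:
                ctx = FieldContext(f)
                lo = model_r2eff(MODEL_CR, float(min(config.nu_cpmg)), ctx, 0.0, kex, pa, dw)
                hi = model_r2eff(MODEL_CR, 1e9, ctx, 0.0, kex, pa, dw)
                r_ex[f] = float(lo - hi)
        out.append(GroundTruthResidue(res, region, s2, tau_e, exch, r_ex))
    return out


def true_rates(truth: GroundTruthResidue, config: SimulationConfig,
               field_MHz: float, include_rex: bool = True) -> tuple[float, float, float]:
    """Noise-free (R1, R2, NOE) for one residue at one field."""
    rex = truth.r_ex_true.get(field_MHz, 0.0) if include_rex else 0.0
    return predict_rates(truth.s2_true, truth.tau_e_true, config.tau_m,
                         FieldContext(field_MHz), r_ex=rex)


def generate_relaxation_dataset(truth: Sequence[GroundTruthResidue],
                                config: SimulationConfig) -> dict:
    """Intensity tables for the relaxation experiments.

    Returns ``{"r1"|"r2": {field: [IntensitySeries (delay_s)]},
    "noe": {field: [IntensitySeries (noe_pair)]}}`` with
    I(t) = I0 exp(-R t) + N(0, noise * I0); the R2 decay of
    exchange-bearing residues includes their Rex at that field.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sigma = config.noise_sigma
    noise_on = config.noise > 0
    data: dict = {"r1": {}, "r2": {}, "noe": {}}
    for f in config.fields_MHz:
        r1_list, r2_list, noe_list = [], [], []
        for t in truth:
            r1, r2, noe = true_rates(t, config, f)
            t1 = np.array(config.delays_r1)
            t2 = np.array(config.delays_r2)
            y1 = I0 * np.exp(-r1 * t1)
            y2 = I0 * np.exp(-r2 * t2)
            pair = np.array([I0, noe * I0])  # reference, saturated
            if noise_on:
                y1 = y1 + rng.normal(0.0, sigma, len(y1))
                y2 = y2 + rng.normal(0.0, sigma, len(y2))
                pair = pair + rng.normal(0.0, sigma, 2)
            r1_list.append(IntensitySeries(t.residue, "delay_s", t1, y1, sigma))
            r2_list.append(IntensitySeries(t.residue, "delay_s", t2, y2, sigma))
            noe_list.append(IntensitySeries(t.residue, "noe_pair",
                                            np.array([0.0, 1.0]), pair, sigma))
        data["r1"][f] = r1_list
        data["r2"][f] = r2_list
        data["noe"][f] = noe_list
    return data


def generate_dispersion_dataset(truth: Sequence[GroundTruthResidue],
                                config: SimulationConfig) -> dict[float, list[DispersionProfile]]:
    """Constant-time CPMG profiles per field.

    Intensities I = I0 exp(-R2eff * T) + N(0, noise * I0) are generated
    and converted back through :func:`intensities_to_r2eff`, so the
    profile errors carry the propagated spectral noise.  Non-exchanging
    residues are flat at their predicted R2; delta_omega is shared across
    fields in ppm by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sigma = config.noise_sigma
    noise_on = config.noise > 0
    nu = np.array(config.nu_cpmg)
    out: dict[float, list[DispersionProfile]] = {}
    for f in config.fields_MHz:
        ctx = FieldContext(f)
        profiles = []
        for t in truth:
            _, r2_0, _ = true_rates(t, config, f, include_rex=False)
            if t.exchange_params_true is not None:
                kex, pa, dw = t.exchange_params_true
                r2eff_true = model_r2eff(MODEL_CR, nu, ctx, r2_0, kex, pa, dw)
            else:
                r2eff_true = np.full_like(nu, r2_0)
            i = I0 * np.exp(-r2eff_true * config.t_relax)
            if noise_on:
                i = i + rng.normal(0.0, sigma, len(i))
            r2eff, errors, excluded = intensities_to_r2eff(i, I0, config.t_relax, sigma)
            keep = ~excluded
            profiles.append(DispersionProfile(t.residue, ctx, nu[keep],
                                              r2eff[keep], errors[keep], config.t_relax))
        out[f] = profiles
    return out


@dataclass(frozen=True)
class PerturbationSpec:
    """Binding response per region for the apo/holo shift tables.

    ``csp_magnitude`` is the composite-CSP magnitude (ppm) applied to a
    region (realized as ddH = m, ddN = m/0.14 and ddC = m/0.35, so the
    default-weight mean-mode composite equals m exactly); ``undetectable_prob`` is the chance a
    residue of that region gives no detectable holo resonance.
    """

    csp_magnitude: dict[str, float] = field(
        default_factory=lambda: {"core": 0.01, "c_terminal_arm": 0.08,
                                 "active_site_patch": 0.15})
    undetectable_prob: dict[str, float] = field(
        default_factory=lambda: {"core": 0.0, "c_terminal_arm": 0.3,
                                 "active_site_patch": 0.05})


def _base_shifts(truth: Sequence[GroundTruthResidue], rng) -> dict:
    return {
        t.residue: {
            "H": float(rng.normal(8.3, 0.4)),
            "N": float(rng.normal(119.0, 4.0)),
            "C": float(rng.normal(176.0, 2.0)),
        }
        for t in truth
    }


def generate_shift_tables(truth: Sequence[GroundTruthResidue], config: SimulationConfig,
                          spec: PerturbationSpec | None = None,
                          temperatures: Sequence[float] = tuple(range(277, 311, 3)),
                          drift_ppm_per_K: float = 0.002,
                          ) -> tuple[ShiftTable, ShiftTable, list[ShiftTable]]:
    """Apo/holo shift tables plus a temperature series.

    Holo shifts move by the per-region CSP magnitude (sign random per
    residue); undetectable holo residues are dropped from the holo table.
    The temperature series drifts the amide nitrogen linearly, with a
    per-residue slope scattered around ``drift_ppm_per_K`` and larger
    drifts in the dynamic regions.
    """
    if spec is None:
        spec = PerturbationSpec()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    base = _base_shifts(truth, rng)
    apo = ShiftTable("apo", {r: dict(v) for r, v in base.items()},
                     temperature_K=config.temperature_K)

    holo_shifts: dict[ResidueKey, dict[str, float]] = {}
    for t in truth:
        if rng.uniform() < spec.undetectable_prob.get(t.region_label, 0.0):
            continue  # vanishes in the holo spectrum
        # +/-20% per-residue scatter keeps the regional mean but avoids a
        # degenerate (constant) CSP distribution
        m = spec.csp_magnitude.get(t.region_label, 0.0) * rng.uniform(0.8, 1.2)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        row = dict(base[t.residue])
        row["H"] += sign * m
        row["N"] += sign * m / 0.14
        row["C"] += sign * m / 0.35
        holo_shifts[t.residue] = row
    holo = ShiftTable("holo", holo_shifts, temperature_K=config.temperature_K)

    region_scale = {"core": 0.5, "c_terminal_arm": 2.0, "active_site_patch": 1.5}
    slopes = {t.residue: float(rng.normal(drift_ppm_per_K * region_scale[t.region_label],
                                          0.3 * drift_ppm_per_K)) * (1 if rng.uniform() < 0.5 else -1)
              for t in truth}
    t_ref = temperatures[0]
    series = []
    for temp in temperatures:
        shifts = {}
        for t in truth:
            row = dict(base[t.residue])
            row["N"] += slopes[t.residue] * (temp - t_ref)
            shifts[t.residue] = row
        series.append(ShiftTable(f"T{temp:g}K", shifts, temperature_K=float(temp)))
    return apo, holo, series


def generate_temperature_intensity_series(truth: Sequence[GroundTruthResidue],
                                          config: SimulationConfig,
                                          temperatures: Sequence[float] = tuple(range(277, 311, 3)),
                                          ) -> list[IntensitySeries]:
    """Per-residue intensity-vs-temperature series mirroring the
    qualitative trend map: arm residues lose intensity on heating,
    exchange-patch residues lose intensity on cooling, core flat."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    temps = np.array(sorted(temperatures), dtype=float)
    sigma = config.noise_sigma
    trend = {"core": 0.0, "c_terminal_arm": -0.02 * I0, "active_site_patch": 0.02 * I0}
    out = []
    for t in truth:
        slope = trend[t.region_label] / np.ptp(temps) if np.ptp(temps) else 0.0
        y = I0 * 0.6 + slope * (temps - temps.mean()) * np.ptp(temps)
        if config.noise > 0:
            y = y + rng.normal(0.0, sigma, len(temps))
        out.append(IntensitySeries(t.residue, "temperature_K", temps, y, sigma))
    return out
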