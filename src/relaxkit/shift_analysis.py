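"""Chemical-shift perturbation (CSP) and related spectral classifications.

The composite CSP between two conditions is the root of the mean of the
squared, nucleus-weighted shift differences,

    CSP = sqrt( sum_i (alpha_i * ddelta_i)^2 / N ),

with default weights alpha_H = 1.0, alpha_N = 0.14 and alpha_C' = 0.35
(the nitrogen and carbonyl weights estimated from average shift standard
deviations in the BMRB database; taken as given here).  Dividing by the
number of nuclei N keeps H,N and H,N,C' analyses on a comparable scale;
the pure-sum variant is available via ``mode='sum'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import NUCLEI, ResidueKey, ShiftTable
from .errors import InsufficientDataError, UndefinedCorrelationError

DEFAULT_WEIGHTS = {"H": 1.0, "N": 0.14, "C": 0.35}

STATUS_OK = "ok"
STATUS_UNDETECTABLE_REFERENCE = "undetectable_reference"
STATUS_UNDETECTABLE_TARGET = "undetectable_target"

CHEMICAL_EXCHANGE = "chemical_exchange"
DIPOLAR_ROE = "dipolar_roe"


@dataclass(frozen=True)
class CSPResult:
    residue: ResidueKey
    delta_composite: float | None
    nuclei_used: tuple[str, ...]
    status: str

    def __post_init__(self) -> None:
        if self.status == STATUS_OK:
            if self.delta_composite is None or self.delta_composite < 0:
                raise ValueError("ok status requires a non-negative composite CSP")
        elif self.delta_composite is not None:
            raise ValueError("non-ok status must carry no value")


@dataclass(frozen=True)
class TrendLabel:
    """Sign of the intensity-versus-temperature trend for one residue."""

    residue: ResidueKey
    direction: str  # increasing | decreasing | flat
    slope: float
    p_slope: float


def composite_csp(shifts_ref: Mapping[str, float], shifts_target: Mapping[str, float],
                  residue: ResidueKey,
                  weights: Mapping[str, float] | None = None,
                  mode: str = "mean") -> CSPResult:
    """Weighted composite CSP between a reference and a target shift row.

    Only nuclei present (finite) in both rows enter; a target row with no
    usable nucleus yields status ``undetectable_target`` (the red-bar
    case), an empty reference row ``undetectable_reference``.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    ref = {k: v for k, v in shifts_ref.items() if k in NUCLEI and np.isfinite(v)}
    tgt = {k: v for k, v in shifts_target.items() if k in NUCLEI and np.isfinite(v)}
    if not ref:
        return CSPResult(residue, None, (), STATUS_UNDETECTABLE_REFERENCE)
    if not tgt:
        return CSPResult(residue, None, (), STATUS_UNDETECTABLE_TARGET)
    shared = tuple(n for n in NUCLEI if n in ref and n in tgt)
    if not shared:
        return CSPResult(residue, None, (), STATUS_UNDETECTABLE_TARGET)
    ss = sum((w[n] * (tgt[n] - ref[n])) ** 2 for n in shared)
    if mode == "mean":
        ss /= len(shared)
    return CSPResult(residue, math.sqrt(ss), shared, STATUS_OK)


def csp_between_tables(reference: ShiftTable, target: ShiftTable,
                       weights: Mapping[str, float] | None = None,
                       mode: str = "mean") -> list[CSPResult]:
    """Composite CSP for every residue of the reference table."""
    return [composite_csp(reference.get(res), target.get(res), res, weights, mode)
            for res in reference.residues()]


def temperature_csp_series(tables: Sequence[ShiftTable], reference_T: float,
                           weights: Mapping[str, float] | None = None,
                           mode: str = "mean") -> pd.DataFrame:
    """Cumulative composite CSP of each temperature against a reference.

    ``tables`` must be ordered by strictly increasing temperature and one
    of them must sit at ``reference_T``.  The result is a residue x
    temperature DataFrame of composite CSPs; residues undetectable at the
    reference get NaN everywhere and ``flag = undetectable_reference``.
    """
    if len(tables) < 2:
        raise InsufficientDataError("need at least two temperatures")
    temps = [t.temperature_K for t in tables]
    if any(t is None for t in temps) or any(np.diff(temps) <= 0):
        raise ValueError("tables must carry strictly increasing temperature_K")
    try:
        ref = next(t for t in tables if t.temperature_K == reference_T)
    except StopIteration:
        raise ValueError(f"no table at reference temperature {reference_T}")

    residues = sorted({r for t in tables for r in t.residues()})
    data = {}
    flagged = []
    for res in residues:
        row = {}
        if not ref.get(res):
            flagged.append(res.label)
            row = {t.temperature_K: math.nan for t in tables}
        else:
            for t in tables:
                result = composite_csp(ref.get(res), t.get(res), res, weights, mode)
                row[t.temperature_K] = result.delta_composite if result.status == STATUS_OK else math.nan
        data[res.label] = row
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "residue"
    df["flag"] = ["undetectable_reference" if lbl in flagged else "-" for lbl in df.index]
    return df


def classify_intensity_trend(series, p_threshold: float = 0.05) -> TrendLabel:
    """Label the intensity-vs-temperature trend of one residue.

    Ordinary least-squares slope; the direction is the slope sign when
    its two-sided p-value is below ``p_threshold``, otherwise ``flat``.
    Constant series are flat by definition.
    """
    if series.axis_kind != "temperature_K":
        raise ValueError("expected a temperature_K series")
    t, y = series.axis_values, series.intensities
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 temperatures")
    if np.ptp(y) == 0:
        return TrendLabel(series.residue, "flat", 0.0, 1.0)
    fit = stats.linregress(t, y)
    p = float(fit.pvalue)
    if p < p_threshold:
        direction = "increasing" if fit.slope > 0 else "decreasing"
    else:
        direction = "flat"
    return TrendLabel(series.residue, direction, float(fit.slope), p)


class CorrelationResult(NamedTuple):
    r_squared: float
    n: int
    flags: tuple[str, ...]


def correlate_dw_csp(dw_by_residue: Mapping[ResidueKey, float],
                     csp_results: Sequence[CSPResult]) -> CorrelationResult:
    """Squared Pearson correlation between fitted |delta_omega| and binding CSP.

    Residues missing from either input are excluded pairwise; fewer than
    five pairs is flagged as degenerate.
    """
    csp_ok = {c.residue: c.delta_composite for c in csp_results if c.status == STATUS_OK}
    shared = sorted(set(dw_by_residue) & set(csp_ok))
    if len(shared) < 3:
        raise InsufficientDataError(f"need >= 3 shared residues, got {len(shared)}")
    x = np.array([dw_by_residue[r] for r in shared])
    y = np.array([csp_ok[r] for r in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r, _ = stats.pearsonr(x, y)
    flags = ("small_n",) if len(shared) < 5 else ()
    return CorrelationResult(float(r * r), len(shared), flags)


def classify_water_peak(cross_peak_sign: int, exchange_reference_sign: int) -> str:
    """Classify a water-amide cross peak by its sign relative to exchange peaks.

    Same sign as the exchange reference means chemical exchange with bulk
    water; opposite sign means a dipolar (ROE) contact.
    """
    if cross_peak_sign == 0 or exchange_reference_sign == 0:
        raise ValueError("signs must be nonzero")
    same = (cross_peak_sign > 0) == (exchange_reference_sign > 0)
    return CHEMICAL_EXCHANGE if same else DIPOLAR_ROE
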