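"""Composite CSP arithmetic, temperature series, trend and peak-sign rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxkit.data_io import IntensitySeries, ResidueKey, ShiftTable
from relaxkit.errors import InsufficientDataError, UndefinedCorrelationError
from relaxkit.shift_analysis import (
    CHEMICAL_EXCHANGE,
    DIPOLAR_ROE,
    STATUS_OK,
    STATUS_UNDETECTABLE_REFERENCE,
    STATUS_UNDETECTABLE_TARGET,
    classify_intensity_trend,
    classify_water_peak,
    composite_csp,
    correlate_dw_csp,
    temperature_csp_series,
)

RES = ResidueKey(80, "G")

finite_shift = st.floats(min_value=-5.0, max_value=5.0, allow_nan=False)


class TestCompositeCsp:
    def test_identical_rows_give_zero(self):
        row = {"H": 8.3, "N": 119.0, "C": 176.0}
        out = composite_csp(row, dict(row), RES)
        assert out.delta_composite == 0.0
        assert out.status == STATUS_OK

    def test_hand_evaluated_hn_value(self):
        # ddH = 0.10, ddN = 0.50 with alpha_N = 0.14:
        # sqrt((0.1^2 + (0.14*0.5)^2)/2) = 0.08631
        out = composite_csp({"H": 8.0, "N": 119.0}, {"H": 8.1, "N": 119.5}, RES)
        assert out.delta_composite == pytest.approx(0.08631, abs=1e-5)
        assert out.nuclei_used == ("H", "N")

    def test_single_nucleus_reduces_to_weighted_absolute_difference(self):
        out = composite_csp({"N": 119.0}, {"N": 120.0}, RES)
        assert out.delta_composite == pytest.approx(0.14)

    def test_sum_mode_skips_normalization(self):
        ref, tgt = {"H": 8.0, "N": 119.0}, {"H": 8.1, "N": 119.5}
        mean = composite_csp(ref, tgt, RES, mode="mean").delta_composite
        total = composite_csp(ref, tgt, RES, mode="sum").delta_composite
        assert total == pytest.approx(mean * math.sqrt(2))

    def test_missing_target_row_flagged(self):
        out = composite_csp({"H": 8.0}, {}, RES)
        assert out.status == STATUS_UNDETECTABLE_TARGET
        assert out.delta_composite is None

    def test_missing_reference_row_flagged(self):
        assert composite_csp({}, {"H": 8.0}, RES).status == STATUS_UNDETECTABLE_REFERENCE

    @given(h=finite_shift, n=finite_shift)
    @settings(deadline=None, max_examples=50)
    def test_symmetric_in_the_two_conditions(self, h, n):
        a = {"H": 8.0, "N": 119.0}
        b = {"H": 8.0 + h, "N": 119.0 + n}
        assert composite_csp(a, b, RES).delta_composite == pytest.approx(
            composite_csp(b, a, RES).delta_composite)

    def test_unit_weight_single_nucleus_is_absolute_difference(self):
        out = composite_csp({"H": 8.0}, {"H": 7.4}, RES, weights={"H": 1.0})
        assert out.delta_composite == pytest.approx(0.6)


def _table(temp, n_shift):
    return ShiftTable(f"T{temp}", {RES: {"N": n_shift}}, temperature_K=float(temp))


class TestTemperatureSeries:
    def test_identical_tables_give_zero_everywhere(self):
        tables = [_table(298, 119.0), _table(310, 119.0)]
        df = temperature_csp_series(tables, 298.0)
        assert df.loc[RES.label, 310.0] == 0.0

    def test_linear_nitrogen_drift_hand_value(self):
        # 0.002 ppm/K over 12 K, N only: 0.14 * 0.024
        tables = [_table(298, 119.0), _table(310, 119.0 + 0.002 * 12)]
        df = temperature_csp_series(tables, 298.0)
        assert df.loc[RES.label, 310.0] == pytest.approx(0.00336, abs=1e-6)

    def test_cumulative_csp_monotone_for_linear_drift(self):
        temps = [277, 283, 289, 295]
        tables = [_table(t, 119.0 + 0.003 * (t - 277)) for t in temps]
        df = temperature_csp_series(tables, 277.0)
        vals = df.loc[RES.label, [float(t) for t in temps]].to_numpy(dtype=float)
        assert np.all(np.diff(vals) >= 0)

    def test_residue_missing_at_reference_is_flagged(self):
        other = ResidueKey(81, "A")
        t1 = ShiftTable("a", {other: {"N": 120.0}}, temperature_K=298.0)
        t2 = ShiftTable("b", {RES: {"N": 119.0}, other: {"N": 120.1}}, temperature_K=310.0)
        df = temperature_csp_series([t1, t2], 298.0)
        assert df.loc[RES.label, "flag"] == "undetectable_reference"
        assert math.isnan(df.loc[RES.label, 310.0])

    def test_unordered_temperatures_rejected(self):
        with pytest.raises(ValueError):
            temperature_csp_series([_table(310, 119.0), _table(298, 119.0)], 310.0)


class TestIntensityTrend:
    def _series(self, y, temps=None):
        temps = temps if temps is not None else 277 + 3 * np.arange(len(y))
        return IntensitySeries(RES, "temperature_K", np.asarray(temps, float),
                               np.asarray(y, float), 1.0)

    def test_noiseless_increase_labelled_increasing(self):
        label = classify_intensity_trend(self._series([1, 2, 3, 4, 5.0]))
        assert label.direction == "increasing"

    def test_constant_series_is_flat(self):
        assert classify_intensity_trend(self._series([2, 2, 2, 2.0])).direction == "flat"

    def test_weak_slope_power(self):
        # slope of -2 sigma per 10 K over 12 points: detected in >= 90%
        rng = np.random.default_rng(5)
        temps = 277 + 3 * np.arange(12)
        hits = 0
        for _ in range(200):
            y = 100 - 0.2 * (temps - 277) + rng.normal(0, 1.0, 12)
            if classify_intensity_trend(self._series(y, temps)).direction == "decreasing":
                hits += 1
        assert hits >= 180


class TestDwCspCorrelation:
    def _csp(self, residue, value):
        from relaxkit.shift_analysis import CSPResult
        return CSPResult(residue, value, ("H", "N"), STATUS_OK)

    def test_proportional_inputs_give_r2_of_one(self):
        residues = [ResidueKey(i, "A") for i in range(1, 9)]
        dw = {r: 0.5 * i for i, r in enumerate(residues, 1)}
        csp = [self._csp(r, 2 * dw[r]) for r in residues]
        out = correlate_dw_csp(dw, csp)
        assert out.r_squared == pytest.approx(1.0)
        assert out.n == 8

    def test_independent_inputs_rarely_correlate(self):
        rng = np.random.default_rng(9)
        residues = [ResidueKey(i, "A") for i in range(1, 101)]
        hits = 0
        reps = 40
        for _ in range(reps):
            dw = {r: rng.uniform(0.1, 3.0) for r in residues}
            perm = rng.permutation(100)
            csp = [self._csp(r, list(dw.values())[perm[i]])
                   for i, r in enumerate(residues)]
            if correlate_dw_csp(dw, csp).r_squared < 0.1:
                hits += 1
        assert hits >= 0.95 * reps

    def test_two_points_not_enough(self):
        residues = [ResidueKey(1, "A"), ResidueKey(2, "A")]
        with pytest.raises(InsufficientDataError):
            correlate_dw_csp({r: 1.0 * i for i, r in enumerate(residues, 1)},
                             [self._csp(r, 1.0) for r in residues])

    def test_small_n_flagged(self):
        residues = [ResidueKey(i, "A") for i in range(1, 5)]
        dw = {r: float(i) for i, r in enumerate(residues, 1)}
        out = correlate_dw_csp(dw, [self._csp(r, dw[r] + 0.1 * i)
                                    for i, r in enumerate(residues)])
        assert "small_n" in out.flags

    def test_zero_variance_rejected(self):
        residues = [ResidueKey(i, "A") for i in range(1, 6)]
        with pytest.raises(UndefinedCorrelationError):
            correlate_dw_csp({r: 1.0 for r in residues},
                             [self._csp(r, float(i)) for i, r in enumerate(residues)])


class TestWaterPeakSign:
    def test_same_sign_is_chemical_exchange(self):
        assert classify_water_peak(+1, +1) == CHEMICAL_EXCHANGE

    def test_opposite_sign_is_dipolar_roe(self):
        assert classify_water_peak(-1, +1) == DIPOLAR_ROE

    def test_symmetric_under_global_sign_flip(self):
        for a in (+1, -1):
            for b in (+1, -1):
                assert classify_water_peak(a, b) == classify_water_peak(-a, -b)

    def test_zero_sign_rejected(self):
        with pytest.raises(ValueError):
            classify_water_peak(0, 1)
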