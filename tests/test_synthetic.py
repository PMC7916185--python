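"""Synthetic sky generator: clear-sky laws, determinism, calibration."""

from __future__ import annotations

from dataclasses import replace
from datetime import date

import numpy as np
import pytest

from luxuvi.lightdb import write_records
from luxuvi.synthetic import (
    CalibrationError,
    CalibrationTargets,
    SkyModelParams,
    calibrate,
    clear_sky,
    evaluate_targets,
    generate,
    true_uvi,
)

from .conftest import SITE


class TestClearSky:
    def test_zero_below_horizon(self, default_params):
        for zen in (90.0, 95.0, 180.0):
            assert clear_sky(zen, 6, default_params) == (0.0, 0.0)

    def test_overhead_returns_amplitudes(self, default_params):
        lux, uvi = clear_sky(0.0, 6, default_params)
        assert lux == default_params.e0
        assert uvi == default_params.u_month[5]

    def test_cos_power_law_at_60_degrees(self):
        p = replace(SkyModelParams(), a=1.0, b=2.0)
        lux, uvi = clear_sky(60.0, 3, p)
        assert lux == pytest.approx(p.e0 / 2)
        assert uvi == pytest.approx(p.u_month[2] / 4)

    def test_invalid_inputs_rejected(self, default_params):
        with pytest.raises(ValueError):
            clear_sky(-1.0, 6, default_params)
        with pytest.raises(ValueError):
            clear_sky(30.0, 13, default_params)

    def test_invariants_enforced_on_params(self):
        with pytest.raises(ValueError):
            SkyModelParams(b=0.1)  # b must exceed a
        with pytest.raises(ValueError):
            SkyModelParams(u_month=(1.0,) * 11)

    def test_uv_amplitudes_peak_summer_trough_winter(self, default_params):
        u = default_params.u_month
        assert max(u) in (u[5], u[6])  # June-July
        assert min(u) in (u[10], u[11], u[0])  # Nov-Jan


class TestGenerate:
    def test_cloudless_noiseless_day_on_clear_sky_curve(self, default_params):
        p = replace(default_params, cloud_clear_prob=1.0, sigma_uvi=0.0)
        recs = generate(p, date(2018, 6, 1), date(2018, 6, 1), 30, **SITE)
        assert recs
        for r in recs:
            lux, uvi = clear_sky(r.zenith, 6, p)
            assert r.illuminance == pytest.approx(lux)
            assert r.uvi == pytest.approx(uvi)

    def test_same_seed_identical_streams(self, default_params):
        kw = dict(cadence_minutes=60, **SITE)
        a = generate(default_params, date(2018, 3, 1), date(2018, 3, 7), **kw)
        b = generate(default_params, date(2018, 3, 1), date(2018, 3, 7), **kw)
        assert a == b

    def test_different_seed_differs(self, default_params):
        kw = dict(cadence_minutes=60, **SITE)
        a = generate(default_params, date(2018, 3, 1), date(2018, 3, 7), **kw)
        b = generate(replace(default_params, seed=7), date(2018, 3, 1), date(2018, 3, 7), **kw)
        assert a != b

    def test_byte_identical_csv_output(self, tmp_path, default_params):
        paths = [tmp_path / "a.csv", tmp_path / "b.csv"]
        for p in paths:
            recs = generate(default_params, date(2018, 5, 1), date(2018, 5, 3), 10, **SITE)
            write_records(recs, p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_empty_range_rejected(self, default_params):
        with pytest.raises(ValueError):
            generate(default_params, date(2018, 2, 2), date(2018, 2, 1), 10, **SITE)

    def test_records_daytime_only_with_increasing_timestamps(self, synthetic_year):
        assert all(r.zenith < 90 for r in synthetic_year)
        ts = [r.timestamp for r in synthetic_year]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_annual_max_illuminance_in_campaign_band(self, synthetic_year):
        peak = max(r.illuminance for r in synthetic_year)
        assert 95_000 <= peak <= 125_000

    def test_month_effect_at_fixed_illuminance(self, synthetic_year):
        """~110 klux maps to several-fold higher UVI in May than December."""
        may, dec = [], []
        for r in synthetic_year:
            if 108_000 < r.illuminance < 112_000:
                if r.timestamp.month == 5:
                    may.append(r.uvi)
                elif r.timestamp.month == 12:
                    dec.append(r.uvi)
        assert may and dec
        assert np.mean(may) / np.mean(dec) >= 3.0


class TestTrueUvi:
    def test_cloudless_record_equals_clear_sky(self, default_params):
        lux, uvi = clear_sky(35.0, 7, default_params)
        assert true_uvi(35.0, 7, lux, default_params) == pytest.approx(uvi)

    def test_half_attenuation_algebra(self, default_params):
        p = default_params
        lux, uvi = clear_sky(40.0, 5, p)
        att_lux = lux / 2**p.p_lux
        assert true_uvi(40.0, 5, att_lux, p) == pytest.approx(uvi / 2**p.q_uvi)

    def test_illuminance_above_clear_sky_clamped(self, default_params):
        lux, uvi = clear_sky(30.0, 6, default_params)
        assert true_uvi(30.0, 6, lux * 1.5, default_params) == pytest.approx(uvi)

    def test_inverts_noiseless_generation_exactly(self, noiseless_year, noiseless_params):
        sample = noiseless_year[:: max(1, len(noiseless_year) // 1000)]
        for r in sample:
            est = true_uvi(r.zenith, r.timestamp.month, r.illuminance, noiseless_params)
            assert est == pytest.approx(r.uvi, abs=1e-9)


class TestCalibration:
    def test_default_params_meet_all_targets(self, default_params):
        m = evaluate_targets(default_params)
        assert sum(v for k, v in m.items() if k.startswith("residual_")) == 0.0
        assert m["r_lux_uvi"] == pytest.approx(0.766, abs=0.05)
        assert m["r_zenith_uvi"] == pytest.approx(-0.931, abs=0.03)

    def test_calibrate_returns_met_params_unchanged(self, default_params):
        assert calibrate(default_params) == default_params

    def test_calibrate_reports_failure_with_residuals(self):
        # absurd targets no search can reach in one round
        targets = CalibrationTargets(r_lux_uvi=0.0, r_lux_uvi_tol=0.001)
        with pytest.raises(CalibrationError) as err:
            calibrate(SkyModelParams(), targets, max_rounds=1)
        assert err.value.residuals

    def test_calibrate_recovers_from_detuned_noise(self, default_params):
        """A too-noisy start is pulled back inside the target bands."""
        detuned = replace(default_params, sigma_uvi=0.35)
        fixed = calibrate(detuned, max_rounds=4)
        m = evaluate_targets(fixed)
        assert sum(v for k, v in m.items() if k.startswith("residual_")) == 0.0
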