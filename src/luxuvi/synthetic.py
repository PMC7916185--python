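"""Seeded synthetic natural-light generator.

Emulates a multi-year daylight measurement campaign at a fixed site:
diurnal/seasonal illuminance and UV-index curves driven by the solar zenith
angle, month-dependent UV amplitudes, a shared stochastic cloud attenuation
that dims UV more strongly than visible light, and residual multiplicative
UV noise.  The model is statistical, not radiative-transfer: its parameters
are calibrated so that a simulated year reproduces the summary statistics
of a real mid-latitude campaign (illuminance-UVI correlation near 0.77,
zenith-UVI correlation near -0.93, annual maximum illuminance near 120 klux,
early-afternoon June UVI maxima in the 12-15 band, and a strong month effect:
the same illuminance maps to several-fold higher UVI in late spring than in
December).

The clear-sky laws are power laws in the cosine of the zenith angle,

    illuminance = e0 * cos(z)^a ,    uvi = u_month * cos(z)^b ,  b > a,

with per-month UV amplitudes ``u_month``.  Clouds multiply illuminance by
``c^p_lux`` and UVI by ``c^q_uvi`` (q_uvi > p_lux) where c is 1 on clear
draws and Beta-distributed otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta, timezone
from typing import Sequence

import numpy as np

from .lightdb import LightRecord
from .solar import solar_zenith

__all__ = [
    "SkyModelParams",
    "CalibrationTargets",
    "CalibrationError",
    "clear_sky",
    "generate",
    "true_uvi",
    "calibrate",
    "evaluate_targets",
]

#: local-time window of the simulated measurement campaign
DAY_START_HOUR = 5
DAY_END_HOUR = 20

#: per-month clear-sky UVI amplitudes (UVI at zenith 0), January..December.
#: Peak in June, trough in November-January; values are calibration output,
#: chosen so a simulated year matches the campaign statistics listed above.
DEFAULT_U_MONTH = (5.0, 5.2, 7.6, 8.6, 10.4, 11.4, 10.9, 9.9, 8.9, 7.3, 4.2, 3.4)


@dataclass(frozen=True)
class SkyModelParams:
    """Parameters of the clear-sky + cloud-attenuation light model."""

    e0: float = 125000.0  # clear-sky illuminance scale, lux
    a: float = 0.20  # illuminance zenith exponent
    u_month: tuple[float, ...] = DEFAULT_U_MONTH  # monthly clear-sky UVI amplitudes
    b: float = 1.25  # UVI zenith exponent; must exceed a
    cloud_clear_prob: float = 0.80  # probability a draw is perfectly clear
    cloud_alpha: float = 3.0  # Beta shape of the attenuation factor c
    cloud_beta: float = 1.2
    p_lux: float = 0.55  # illuminance cloud-sensitivity exponent
    q_uvi: float = 0.90  # UVI cloud-sensitivity exponent; exceeds p_lux
    sigma_uvi: float = 0.10  # std of multiplicative log-normal UVI noise
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.u_month) != 12 or any(u <= 0 for u in self.u_month):
            raise ValueError("u_month must hold 12 positive amplitudes")
        if self.b <= self.a:
            raise ValueError("UVI exponent b must exceed illuminance exponent a")
        if not 0.0 <= self.cloud_clear_prob <= 1.0:
            raise ValueError("cloud_clear_prob must lie in [0, 1]")
        if min(self.e0, self.cloud_alpha, self.cloud_beta, self.p_lux, self.q_uvi) <= 0:
            raise ValueError("scale and shape parameters must be positive")
        if self.sigma_uvi < 0:
            raise ValueError("sigma_uvi must be non-negative")


def clear_sky(zenith: float, month: int, params: SkyModelParams) -> tuple[float, float]:
    """Cloud-free (illuminance, uvi) at the given zenith angle and month.

    Both are zero when the sun is at or below the horizon.
    """
    if not 0.0 <= zenith <= 180.0:
        raise ValueError(f"zenith {zenith!r} outside [0, 180]")
    if not 1 <= month <= 12:
        raise ValueError(f"month {month!r} outside 1..12")
    if zenith >= 90.0:
        return 0.0, 0.0
    mu = math.cos(math.radians(zenith))
    return params.e0 * mu**params.a, params.u_month[month - 1] * mu**params.b


def true_uvi(zenith: float, month: int, illuminance: float, params: SkyModelParams) -> float:
    """Conditional-expectation UVI implied by an observed illuminance.

    Inverts the illuminance cloud law for the attenuation factor
    ``c = (illuminance / clear_lux)^(1/p_lux)`` (clamped to 1 when the
    observation exceeds the clear-sky value) and applies it to the clear-sky
    UVI.  With ``sigma_uvi = 0`` this reproduces generated UVI exactly, so it
    serves as the ground-truth oracle for model-recovery experiments.
    """
    clear_lux, clear_uvi = clear_sky(zenith, month, params)
    if clear_lux <= 0.0:
        return 0.0
    c = min((max(illuminance, 0.0) / clear_lux) ** (1.0 / params.p_lux), 1.0)
    return clear_uvi * c**params.q_uvi


def _local_timezone(utc_offset_hours: float) -> timezone:
    return timezone(timedelta(hours=utc_offset_hours))


def generate(
    params: SkyModelParams,
    start_date: date,
    end_date: date,
    cadence_minutes: int,
    latitude: float,
    longitude: float,
    utc_offset_hours: float = 9.0,
) -> list[LightRecord]:
    """Simulate a daytime light-measurement campaign.

    Records are emitted on a fixed cadence between 05:00 and 20:00 local
    time, ``start_date`` through ``end_date`` inclusive; instants with the
    sun below the horizon are omitted.  Each record draws one cloud
    attenuation factor shared between illuminance and UVI, plus independent
    log-normal UVI noise.  The stream is fully reproducible from
    ``params.seed``.
    """
    if cadence_minutes < 1:
        raise ValueError("cadence must be at least one minute")
    if end_date < start_date:
        raise ValueError("empty date range")
    tz = _local_timezone(utc_offset_hours)
    rng = np.random.default_rng(params.seed)
    records: list[LightRecord] = []
    day = start_date
    while day <= end_date:
        t = datetime.combine(day, time(DAY_START_HOUR, 0), tzinfo=tz)
        end_t = datetime.combine(day, time(DAY_END_HOUR, 0), tzinfo=tz)
        while t <= end_t:
            # Draws happen for every slot so the stream does not depend on
            # sunrise/sunset round-off.
            clear_draw = rng.random() < params.cloud_clear_prob
            c = 1.0 if clear_draw else float(rng.beta(params.cloud_alpha, params.cloud_beta))
            eps = float(rng.normal(0.0, params.sigma_uvi)) if params.sigma_uvi > 0 else 0.0
            zen = solar_zenith(latitude, longitude, t)
            if zen < 90.0:
                clear_lux, clear_uvi = clear_sky(zen, t.month, params)
                lux = clear_lux * c**params.p_lux
                uvi = max(clear_uvi * c**params.q_uvi * math.exp(eps), 0.0)
                records.append(
                    LightRecord(timestamp=t, illuminance=lux, uvi=uvi, zenith=zen)
                )
            t += timedelta(minutes=cadence_minutes)
        day += timedelta(days=1)
    return records


# --------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationTargets:
    """Statistics a simulated year must reproduce, with tolerances/bands."""

    r_lux_uvi: float = 0.766
    r_lux_uvi_tol: float = 0.05
    r_zenith_uvi: float = -0.931
    r_zenith_uvi_tol: float = 0.03
    june_max_uvi_band: tuple[float, float] = (12.0, 15.0)
    max_lux_band: tuple[float, float] = (95000.0, 125000.0)
    may_dec_uvi_ratio_min: float = 3.0  # mean UVI at ~110 klux, May vs December
    latitude: float = 36.85
    longitude: float = 127.15
    utc_offset_hours: float = 9.0
    year: int = 2018
    cadence_minutes: int = 10


class CalibrationError(RuntimeError):
    """Coordinate search exhausted its budget without meeting all targets."""

    def __init__(self, message: str, residuals: dict[str, float]):
        super().__init__(f"{message}; residuals: {residuals}")
        self.residuals = residuals


def _simulate_year(params: SkyModelParams, targets: CalibrationTargets) -> list[LightRecord]:
    return generate(
        params,
        date(targets.year, 1, 1),
        date(targets.year, 12, 31),
        targets.cadence_minutes,
        targets.latitude,
        targets.longitude,
        targets.utc_offset_hours,
    )


def evaluate_targets(
    params: SkyModelParams, targets: CalibrationTargets | None = None
) -> dict[str, float]:
    """Simulate one year and measure each calibration statistic.

    Returns the raw measured values keyed by target name; ``residual_*``
    entries give the (non-negative) distance outside each tolerance band,
    zero when the target is met.
    """
    targets = targets or CalibrationTargets()
    recs = _simulate_year(params, targets)
    lux = np.array([r.illuminance for r in recs])
    uvi = np.array([r.uvi for r in recs])
    zen = np.array([r.zenith for r in recs])
    months = np.array([r.timestamp.month for r in recs])
    hours = np.array([r.timestamp.hour for r in recs])

    r_lu = float(np.corrcoef(lux, uvi)[0, 1])
    r_zu = float(np.corrcoef(zen, uvi)[0, 1])
    june13 = uvi[(months == 6) & (hours == 13)]
    june_max = float(june13.max()) if june13.size else 0.0
    max_lux = float(lux.max())
    band = (lux > 108000.0) & (lux < 112000.0)
    may_mean = float(uvi[band & (months == 5)].mean()) if (band & (months == 5)).any() else 0.0
    dec_mean = float(uvi[band & (months == 12)].mean()) if (band & (months == 12)).any() else math.inf
    ratio = may_mean / dec_mean if dec_mean > 0 else math.inf

    def outside(v: float, lo: float, hi: float) -> float:
        return max(lo - v, 0.0) + max(v - hi, 0.0)

    out = {
        "r_lux_uvi": r_lu,
        "r_zenith_uvi": r_zu,
        "june_max_uvi": june_max,
        "max_lux": max_lux,
        "may_dec_uvi_ratio": ratio,
    }
    out["residual_r_lux_uvi"] = outside(
        r_lu, targets.r_lux_uvi - targets.r_lux_uvi_tol, targets.r_lux_uvi + targets.r_lux_uvi_tol
    )
    out["residual_r_zenith_uvi"] = outside(
        r_zu,
        targets.r_zenith_uvi - targets.r_zenith_uvi_tol,
        targets.r_zenith_uvi + targets.r_zenith_uvi_tol,
    )
    out["residual_june_max_uvi"] = outside(june_max, *targets.june_max_uvi_band)
    out["residual_max_lux"] = outside(max_lux, *targets.max_lux_band) / 1000.0
    out["residual_may_dec_ratio"] = max(targets.may_dec_uvi_ratio_min - ratio, 0.0)
    return out


def _total_residual(measures: dict[str, float]) -> float:
    return sum(v for k, v in measures.items() if k.startswith("residual_"))


# knobs the coordinate search may move, with multiplicative step proposals
_SEARCH_KNOBS = ("cloud_alpha", "cloud_beta", "p_lux", "q_uvi", "sigma_uvi", "u_scale")


def calibrate(
    initial: SkyModelParams,
    targets: CalibrationTargets | None = None,
    max_rounds: int = 8,
    step: float = 1.2,
) -> SkyModelParams:
    """Coordinate search tuning the cloud/noise knobs until targets are met.

    Each round proposes multiplying one knob (cloud shape parameters, the
    two cloud-sensitivity exponents, the UVI noise scale, or a common scale
    on the monthly UVI amplitudes) by ``step`` or ``1/step`` and keeps the
    proposal that most reduces the summed out-of-band residual.  Returns the
    first parameter set meeting every target; raises
    :class:`CalibrationError` when the budget is exhausted.
    """
    targets = targets or CalibrationTargets()
    current = initial
    measures = evaluate_targets(current, targets)
    best = _total_residual(measures)
    if best == 0.0:
        return current
    for _ in range(max_rounds):
        improved = False
        for knob in _SEARCH_KNOBS:
            for factor in (step, 1.0 / step):
                cand = _apply_knob(current, knob, factor)
                if cand is None:
                    continue
                m = evaluate_targets(cand, targets)
                r = _total_residual(m)
                if r < best - 1e-9:
                    current, best, measures, improved = cand, r, m, True
                    if best == 0.0:
                        return current
        if not improved:
            break
    raise CalibrationError(
        "calibration failed to meet all targets",
        {k: v for k, v in measures.items() if k.startswith("residual_") and v > 0},
    )


def _apply_knob(params: SkyModelParams, knob: str, factor: float) -> SkyModelParams | None:
    try:
        if knob == "u_scale":
            return replace(params, u_month=tuple(u * factor for u in params.u_month))
        value = getattr(params, knob) * factor
        if knob == "q_uvi" and value <= params.p_lux:
            return None
        if knob == "p_lux" and value >= params.q_uvi:
            return None
        return replace(params, **{knob: value})
    except ValueError:
        return None
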