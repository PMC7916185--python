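"""Vitamin-D synthesis dosimetry from the UV index.

Implements the published dose chain for a constant-UVI exposure:

    E_UV  = UVI / k                      erythemally weighted irradiance, k = 40 m^2/W
    DUV   = E_UV * ASCF * GCF            vitamin-D-effective irradiance on the body
    VUD   = integral of DUV over time    vitamin-D-weighted dose, J/m^2
    VitD  = 49 * VUD * STF * PBE * AF * SPF          expected synthesis, IU

ASCF converts the erythemal action-spectrum weighting to the vitamin-D
action spectrum and GCF the horizontal-plane irradiance to the body
surface; both are tabulated by season for latitude 35 N.  STF scales for
Fitzpatrick skin type, PBE is the exposed body fraction, AF the age factor,
and SPF the sunscreen transmission in (0, 1] (1 = no sunscreen).  The
``AF``/``SPF`` pair enters multiplicatively: SPF is a transmission, so full
blocking (SPF -> 0) must drive the dose to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "K_ERYTHEMAL",
    "VITD_IU_PER_J",
    "STF_BY_SKIN_TYPE",
    "age_factor",
    "SeasonFactors",
    "SEASON_FACTORS",
    "season_of_month",
    "ExposureProfile",
    "DoseResult",
    "euv_from_uvi",
    "duv_out",
    "vud",
    "vitamin_d",
    "dose_from_uvi",
    "TABLE_PRESET_FACTORS",
    "TABLE_PRESET_PROFILE",
]

#: UVI = K_ERYTHEMAL [m^2/W] * E_UV
K_ERYTHEMAL = 40.0
#: IU of vitamin D per (J/m^2 of vitamin-D-weighted dose x factor product)
VITD_IU_PER_J = 49.0

#: skin-type factor for Fitzpatrick types II-V
STF_BY_SKIN_TYPE = {
    "II": 3.2 / 3.0,
    "III": 3.2 / 4.0,
    "IV": 3.2 / 5.25,
    "V": 3.2 / 7.5,
}


def age_factor(age: float) -> float:
    """Age-dependent synthesis multiplier (piecewise by age band)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if age <= 21:
        return 1.0
    if age <= 40:
        return 0.83
    if age <= 59:
        return 0.66
    return 0.49


@dataclass(frozen=True)
class SeasonFactors:
    """Seasonal conversion factors (latitude-35N table)."""

    season: str
    ascf: float  # action-spectrum conversion factor
    gcf: float  # geometric conversion factor


SEASON_FACTORS = {
    "spring": SeasonFactors("spring", 1.049, 0.600),
    "summer": SeasonFactors("summer", 1.104, 0.600),
    "autumn": SeasonFactors("autumn", 1.029, 0.655),
    "winter": SeasonFactors("winter", 0.842, 0.655),
}


def season_of_month(month: int) -> str:
    """Meteorological season: Mar-May spring, Jun-Aug summer, etc."""
    if not 1 <= month <= 12:
        raise ValueError(f"month {month!r} outside 1..12")
    return ("winter", "winter", "spring", "spring", "spring", "summer",
            "summer", "summer", "autumn", "autumn", "autumn", "winter")[month - 1]


@dataclass(frozen=True)
class ExposureProfile:
    """Who is exposed, how much skin, sunscreen, and for how long."""

    skin_type: str = "II"
    age: float = 21.0
    pbe: float = 0.15  # exposed body fraction
    spf: float = 1.0  # sunscreen transmission, (0, 1], 1 = none
    duration_s: float = 1200.0
    af_override: float | None = None  # explicit age factor, bypassing the age bands

    def __post_init__(self) -> None:
        if self.skin_type not in STF_BY_SKIN_TYPE:
            raise ValueError(f"skin_type must be one of {sorted(STF_BY_SKIN_TYPE)}")
        if not 0.0 <= self.pbe <= 1.0:
            raise ValueError("pbe must lie in [0, 1]")
        if not 0.0 < self.spf <= 1.0:
            raise ValueError("spf (transmission) must lie in (0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        age_factor(self.age)  # range check

    @property
    def stf(self) -> float:
        return STF_BY_SKIN_TYPE[self.skin_type]

    @property
    def af(self) -> float:
        return self.af_override if self.af_override is not None else age_factor(self.age)


@dataclass(frozen=True)
class DoseResult:
    """All stages of the dose chain for one exposure."""

    euv: float  # W/m^2
    duv_out: float  # W/m^2
    vud: float  # J/m^2
    vitd: float  # IU


def euv_from_uvi(uvi: float) -> float:
    """Erythemally weighted irradiance in W/m^2 from the UV index."""
    if uvi < 0:
        raise ValueError("uvi must be non-negative")
    return uvi / K_ERYTHEMAL


def duv_out(euv: float, factors: SeasonFactors) -> float:
    """Vitamin-D-effective irradiance on the body surface, W/m^2."""
    if euv < 0:
        raise ValueError("euv must be non-negative")
    return euv * factors.ascf * factors.gcf


def vud(
    duv: float | Sequence[float],
    duration_s: float,
    times_s: Sequence[float] | None = None,
) -> float:
    """Vitamin-D-weighted dose in J/m^2 over an exposure interval.

    A scalar ``duv`` is treated as constant over ``duration_s``; a sampled
    series (with matching sample times in seconds, strictly increasing,
    spanning [0, duration_s]) is integrated by the trapezoid rule.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if np.isscalar(duv):
        return float(duv) * duration_s
    series = np.asarray(duv, dtype=float)
    if series.size == 0:
        raise ValueError("empty irradiance series")
    if times_s is None:
        times_s = np.linspace(0.0, duration_s, series.size)
    t = np.asarray(times_s, dtype=float)
    if t.shape != series.shape or np.any(np.diff(t) <= 0):
        raise ValueError("sample times must match the series and be strictly increasing")
    return float(np.trapezoid(series, t))


def vitamin_d(vud_j: float, profile: ExposureProfile) -> float:
    """Expected vitamin-D synthesis in IU for an accumulated dose."""
    if vud_j < 0:
        raise ValueError("vud must be non-negative")
    return VITD_IU_PER_J * vud_j * profile.stf * profile.pbe * profile.af * profile.spf


def dose_from_uvi(
    uvi: float, factors: SeasonFactors, profile: ExposureProfile
) -> DoseResult:
    """Full dose chain for a constant-UVI exposure of ``profile.duration_s``."""
    euv = euv_from_uvi(uvi)
    duv = duv_out(euv, factors)
    dose = vud(duv, profile.duration_s)
    return DoseResult(euv=euv, duv_out=duv, vud=dose, vitd=vitamin_d(dose, profile))


# --------------------------------------------------------------------------
# worked-example preset

#: factor set that reproduces the published hour-by-hour dose table: winter
#: conversion factors and unit age factor in *both* seasons.  Fitting the
#: per-UVI dose constant across all printed cells shows the published doses
#: use ASCF*GCF = 0.842*0.655 and AF = 1.0 throughout, rather than the
#: summer factors or the >21-years age band the surrounding text implies.
TABLE_PRESET_FACTORS = SeasonFactors("table-preset", 0.842, 0.655)
TABLE_PRESET_PROFILE = ExposureProfile(
    skin_type="II", age=21.0, pbe=0.15, spf=1.0, duration_s=1200.0, af_override=1.0
)


def table_preset_dose(uvi: float) -> float:
    """Dose in IU for one UVI under the worked-example preset (20 min,
    skin type II, 15% body exposure, no sunscreen)."""
    return dose_from_uvi(uvi, TABLE_PRESET_FACTORS, TABLE_PRESET_PROFILE).vitd
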