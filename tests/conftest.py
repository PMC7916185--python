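from __future__ import annotations

from dataclasses import replace
from datetime import date

import pytest
from hypothesis import settings as _hyp_settings

from luxuvi.synthetic import SkyModelParams, generate

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

SITE = dict(latitude=36.85, longitude=127.15, utc_offset_hours=9.0)


@pytest.fixture(scope="session")
def default_params() -> SkyModelParams:
    return SkyModelParams()


@pytest.fixture(scope="session")
def synthetic_year(default_params):
    """One calendar year of the default calibrated sky model, 10-min cadence."""
    return generate(
        default_params, date(2018, 1, 1), date(2018, 12, 31), 10,
        SITE["latitude"], SITE["longitude"], SITE["utc_offset_hours"],
    )


@pytest.fixture(scope="session")
def noiseless_params(default_params) -> SkyModelParams:
    return replace(default_params, sigma_uvi=0.0)


@pytest.fixture(scope="session")
def noiseless_year(noiseless_params):
    """Same campaign with the UVI noise switched off (clouds remain)."""
    return generate(
        noiseless_params, date(2018, 1, 1), date(2018, 12, 31), 10,
        SITE["latitude"], SITE["longitude"], SITE["utc_offset_hours"],
    )
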