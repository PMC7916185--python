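"""Published hour-by-hour UVI / vitamin-D worked example.

One summer day and one winter day of hourly UVI readings (07:00-16:00 local)
from a reference spectroradiometer alongside the illuminance-based model's
estimates, with the vitamin-D doses the publication reports for a 20-minute
exposure (skin type II, 15% body exposure, no sunscreen).  These printed
values are inputs for reproducing the worked example; the doses are what the
dosimetry chain must recompute.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["WorkedExampleColumn", "WORKED_EXAMPLE", "HOURS"]

#: local clock hours of the ten readings
HOURS = (7, 8, 9, 10, 11, 12, 13, 14, 15, 16)


@dataclass(frozen=True)
class WorkedExampleColumn:
    """One instrument/season column: hourly UVI, printed doses, printed means."""

    label: str
    uvi: tuple[float, ...]
    vitd_iu: tuple[float, ...]
    mean_uvi: float
    mean_vitd_iu: float


WORKED_EXAMPLE = {
    "summer_reference": WorkedExampleColumn(
        label="summer, reference spectroradiometer",
        uvi=(2.03, 3.12, 4.69, 6.22, 6.95, 7.17, 6.36, 4.50, 3.00, 2.10),
        vitd_iu=(263.44, 404.71, 609.00, 806.69, 901.56, 929.58, 824.77, 584.14, 389.50, 271.77),
        mean_uvi=4.61,
        mean_vitd_iu=598.52,
    ),
    "summer_model": WorkedExampleColumn(
        label="summer, illuminance-based model",
        uvi=(1.42, 3.08, 4.78, 6.28, 7.48, 7.98, 8.03, 5.59, 3.84, 2.41),
        vitd_iu=(184.59, 400.01, 620.00, 814.58, 970.03, 1034.93, 1041.57, 724.68, 498.64, 312.06),
        mean_uvi=5.09,
        mean_vitd_iu=660.11,
    ),
    "winter_reference": WorkedExampleColumn(
        label="winter, reference spectroradiometer",
        uvi=(0.03, 0.38, 0.98, 1.27, 1.30, 1.37, 1.47, 0.94, 0.26, 0.05),
        vitd_iu=(4.45, 49.40, 126.51, 164.30, 168.59, 177.28, 191.05, 122.37, 33.52, 7.03),
        mean_uvi=0.81,
        mean_vitd_iu=104.45,
    ),
    "winter_model": WorkedExampleColumn(
        label="winter, illuminance-based model",
        uvi=(0.02, 0.44, 1.13, 1.46, 1.25, 1.41, 1.64, 0.84, 0.23, 0.05),
        vitd_iu=(2.93, 56.98, 145.95, 189.41, 162.16, 182.98, 213.08, 109.14, 29.47, 6.68),
        mean_uvi=0.85,
        mean_vitd_iu=109.88,
    ),
}
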