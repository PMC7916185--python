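"""Vitamin-D synthesis estimates for a 20-minute sun exposure.

Walks the dose chain UVI -> erythemal irradiance -> body-surface
vitamin-D-effective irradiance -> time-integrated dose -> IU, using the
published hour-by-hour winter/summer example (skin type II, 15% body
exposure, no sunscreen), and shows how skin type and sunscreen rescale it.
"""

import numpy as np

from luxuvi.dosimetry import (
    ExposureProfile,
    SEASON_FACTORS,
    TABLE_PRESET_FACTORS,
    TABLE_PRESET_PROFILE,
    dose_from_uvi,
    table_preset_dose,
)
from luxuvi.tables import HOURS, WORKED_EXAMPLE

col = WORKED_EXAMPLE["summer_reference"]
print("Summer day, reference instrument UVI -> vitamin D for 20 min exposure:")
print(" hour   UVI    computed IU   published IU")
doses = []
for hour, uvi, printed in zip(HOURS, col.uvi, col.vitd_iu):
    d = table_preset_dose(uvi)
    doses.append(d)
    print(f"  {hour:02d}   {uvi:5.2f}   {d:10.2f}   {printed:10.2f}")
print(f" mean        {np.mean(doses):10.2f}   {col.mean_vitd_iu:10.2f}")

r = dose_from_uvi(7.17, TABLE_PRESET_FACTORS, TABLE_PRESET_PROFILE)
print(
    f"\nChain at UVI 7.17: E_UV {r.euv:.4f} W/m2 -> DUV {r.duv_out:.4f} W/m2"
    f" -> VUD {r.vud:.1f} J/m2 -> {r.vitd:.1f} IU"
)

print("\nSame exposure, different profiles (UVI 7.17, summer factors):")
for label, profile in [
    ("skin II, no sunscreen", ExposureProfile(skin_type="II")),
    ("skin V,  no sunscreen", ExposureProfile(skin_type="V")),
    ("skin II, SPF transmitting 30%", ExposureProfile(skin_type="II", spf=0.3)),
    ("skin II, age 45", ExposureProfile(skin_type="II", age=45)),
]:
    d = dose_from_uvi(7.17, SEASON_FACTORS["summer"], profile).vitd
    print(f"  {label:<32} {d:8.1f} IU")
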