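"""Export a trained model to the portable format and run it standalone.

The portable container is a small JSON file (float32 weights, normalization
constants, input layout).  A numpy-free interpreter executes it from raw
sensor inputs -- illuminance, location, local time -- the way an on-device
runtime would, deriving the zenith angle and month features itself.
"""

from datetime import date, datetime, timedelta, timezone
from pathlib import Path

from luxuvi import lite
from luxuvi.dataset import InputConfig, extract, split
from luxuvi.model import MLPConfig, export_lite, train
from luxuvi.synthetic import SkyModelParams, generate

KST = timezone(timedelta(hours=9))

records = generate(SkyModelParams(seed=42), date(2018, 1, 1), date(2018, 12, 31),
                   cadence_minutes=10, latitude=36.85, longitude=127.15)
cfg = InputConfig(use_zenith=True, use_month=True)
ts = split(extract(records, cfg), seed=0)
weights, _ = train(ts, MLPConfig(n_inputs=cfg.n_features, hidden=(64, 64), epochs=60, seed=0))

path = Path("uvi.litemodel.json")
export_lite(weights, path, cfg, ts.normalization)
print(f"exported {path} ({path.stat().st_size / 1024:.1f} KiB)")

model = lite.load(path)
print("\nUVI estimates from raw (illuminance, place, time):")
for when, lux in [
    ("2018-06-15T13:00:00+09:00", 110_000.0),
    ("2018-06-15T17:00:00+09:00", 60_000.0),
    ("2018-12-15T13:00:00+09:00", 105_000.0),
    ("2018-12-15T23:00:00+09:00", 0.0),
]:
    t = datetime.fromisoformat(when)
    est = model.predict(lux, 36.85, 127.15, t)
    print(f"  {when}  {lux:>9,.0f} lux -> UVI {est:5.2f}")

print(
    "\nThe June/December rows show the month effect at similar brightness;"
    "\nthe night row returns 0 (sun below the horizon)."
)
path.unlink()
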