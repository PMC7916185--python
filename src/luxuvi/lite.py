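"""Minimal interpreter for portable weight files.

Executes the JSON weight container written by :func:`luxuvi.model.export_lite`
using only the standard library (base64/struct/math) — no numpy and no
training code — mirroring the role of an on-device inference runtime.  Given
raw sensor inputs (illuminance, location, local time) it derives the solar
zenith angle, assembles and normalizes the feature vector including the
month one-hot block, runs the dense forward pass, and clamps the UVI
estimate at zero.
"""

from __future__ import annotations

import base64
import json
import struct
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

from .model import LITE_FORMAT_VERSION, LiteFormatError
from .solar import solar_zenith

__all__ = ["LiteModel", "load", "lite_predict"]


def _read_and_check(path: Path) -> dict:
    """Parse and structurally validate a portable weight file."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LiteFormatError(f"{path}: unreadable or not JSON: {exc}") from exc
    if doc.get("format") != "luxuvi-lite":
        raise LiteFormatError(f"{path}: not a luxuvi-lite container")
    if doc.get("version") != LITE_FORMAT_VERSION:
        raise LiteFormatError(f"{path}: unsupported format version {doc.get('version')!r}")
    layers = doc.get("layers")
    if not layers:
        raise LiteFormatError(f"{path}: no layers")
    import zlib

    crc = 0
    prev_out = doc["inputs"]["n_features"]
    for i, layer in enumerate(layers):
        n_in, n_out = layer["shape"]
        wb = base64.b64decode(layer["weights_b64"])
        bb = base64.b64decode(layer["bias_b64"])
        if len(wb) != 4 * n_in * n_out or len(bb) != 4 * n_out:
            raise LiteFormatError(f"{path}: layer {i} byte count does not match shape")
        if n_in != prev_out:
            raise LiteFormatError(f"{path}: layer {i} breaks the dimension chain")
        if layer["activation"] not in ("relu", "identity"):
            raise LiteFormatError(f"{path}: layer {i} unknown activation")
        crc = zlib.crc32(bb, zlib.crc32(wb, crc))
        prev_out = n_out
    if prev_out != 1:
        raise LiteFormatError(f"{path}: final layer must have one output")
    if crc != doc.get("crc32"):
        raise LiteFormatError(f"{path}: weight checksum mismatch")
    n_cont = 1 + (1 if doc["inputs"]["use_zenith"] else 0)
    if len(doc["normalization"]) != n_cont:
        raise LiteFormatError(f"{path}: normalization constants do not match inputs")
    return doc


@dataclass
class LiteModel:
    """A loaded portable model: plain-Python layers plus feature metadata."""

    layers: list[tuple[list[list[float]], list[float], str]]  # (rows of W, bias, activation)
    use_zenith: bool
    use_month: bool
    normalization: list[tuple[float, float]]  # (offset, scale) per continuous feature
    clamp_min: float

    @property
    def n_features(self) -> int:
        return 1 + (1 if self.use_zenith else 0) + (12 if self.use_month else 0)

    def forward(self, features: Sequence[float]) -> float:
        """Raw network output for one already-normalized feature vector."""
        if len(features) != self.n_features:
            raise ValueError(f"feature dim {len(features)} != model dim {self.n_features}")
        h = list(features)
        for rows, bias, act in self.layers:
            out = []
            for j in range(len(bias)):
                s = bias[j]
                for i, hi in enumerate(h):
                    s += hi * rows[i][j]
                if act == "relu" and s < 0.0:
                    s = 0.0
                out.append(s)
            h = out
        return h[0]

    def predict_features(self, features: Sequence[float]) -> float:
        """Clamped UVI estimate from a normalized feature vector."""
        return max(self.forward(features), self.clamp_min)

    def features_from_inputs(
        self, illuminance: float, latitude: float, longitude: float, timestamp: datetime
    ) -> list[float]:
        """Build the normalized feature vector from raw sensor inputs."""
        if illuminance < 0:
            raise ValueError("illuminance must be non-negative")
        zen = solar_zenith(latitude, longitude, timestamp)
        off, scale = self.normalization[0]
        feats = [(illuminance - off) / scale]
        if self.use_zenith:
            off, scale = self.normalization[1]
            feats.append((zen - off) / scale)
        if self.use_month:
            month = timestamp.month
            feats.extend(1.0 if m == month else 0.0 for m in range(1, 13))
        return feats

    def predict(
        self, illuminance: float, latitude: float, longitude: float, timestamp: datetime
    ) -> float:
        """UVI estimate from raw inputs (illuminance in lux, aware datetime).

        Returns exactly 0 with the sun at or below the horizon: UVI vanishes
        at night, and the network was fitted on daytime records only, so its
        extrapolation there is meaningless.
        """
        if solar_zenith(latitude, longitude, timestamp) >= 90.0:
            return 0.0
        return self.predict_features(self.features_from_inputs(illuminance, latitude, longitude, timestamp))


def load(path: str | Path) -> LiteModel:
    """Load and validate a portable weight file."""
    doc = _read_and_check(Path(path))
    layers = []
    for layer in doc["layers"]:
        n_in, n_out = layer["shape"]
        flat_w = struct.unpack(f"<{n_in * n_out}f", base64.b64decode(layer["weights_b64"]))
        bias = list(struct.unpack(f"<{n_out}f", base64.b64decode(layer["bias_b64"])))
        rows = [list(flat_w[i * n_out : (i + 1) * n_out]) for i in range(n_in)]
        layers.append((rows, bias, layer["activation"]))
    return LiteModel(
        layers=layers,
        use_zenith=doc["inputs"]["use_zenith"],
        use_month=doc["inputs"]["use_month"],
        normalization=[(o, s) for o, s in doc["normalization"]],
        clamp_min=doc.get("output_clamp_min", 0.0),
    )


def lite_predict(
    lite_file: str | Path,
    illuminance: float,
    latitude: float,
    longitude: float,
    timestamp: datetime,
) -> float:
    """One-shot UVI estimate: load the container and run a forward pass."""
    return load(lite_file).predict(illuminance, latitude, longitude, timestamp)
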