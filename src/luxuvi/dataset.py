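"""Supervised training sets from light records.

Builds feature matrices for the three input configurations compared during
model selection: illuminance alone, illuminance + solar zenith angle, and
illuminance + zenith + calendar month.  The month enters as a 12-way one-hot
block so the network treats it as categorical rather than ordinal.
Continuous features are min-max normalized to [0, 1]; targets (UVI) stay in
natural units so mean absolute error is directly interpretable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lightdb import LightRecord

__all__ = ["InputConfig", "TrainingSet", "extract", "split"]

logger = logging.getLogger(__name__)

#: default physical normalization scales, used before a split refit
DEFAULT_LUX_SCALE = 120000.0
DEFAULT_ZENITH_SCALE = 90.0

SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class InputConfig:
    """Which inputs the model sees; illuminance is always included."""

    use_zenith: bool = True
    use_month: bool = True

    @property
    def n_features(self) -> int:
        return 1 + (1 if self.use_zenith else 0) + (12 if self.use_month else 0)

    @property
    def feature_names(self) -> list[str]:
        names = ["illuminance"]
        if self.use_zenith:
            names.append("zenith")
        if self.use_month:
            names += [f"month_{m:02d}" for m in range(1, 13)]
        return names

    @property
    def n_continuous(self) -> int:
        return 2 if self.use_zenith else 1


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix, UVI targets, normalization metadata and split labels."""

    features: np.ndarray  # n x d, normalized continuous block first
    targets: np.ndarray  # n UVI values, natural units
    config: InputConfig
    normalization: tuple[tuple[float, float], ...]  # (offset, scale) per continuous feature
    months: np.ndarray  # n calendar months, for stratification
    split_labels: np.ndarray  # n strings from SPLIT_NAMES
    seed: int | None = None

    def __post_init__(self) -> None:
        n, d = self.features.shape
        if d != self.config.n_features:
            raise ValueError(f"feature dim {d} != config dim {self.config.n_features}")
        if self.targets.shape != (n,) or self.months.shape != (n,) or self.split_labels.shape != (n,):
            raise ValueError("targets/months/split_labels length mismatch")

    def rows(self, label: str) -> np.ndarray:
        if label not in SPLIT_NAMES:
            raise ValueError(f"unknown split {label!r}")
        return np.flatnonzero(self.split_labels == label)

    def subset(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.rows(label)
        return self.features[idx], self.targets[idx]

    def to_csv_pair(self, stem: str | Path) -> None:
        """Write <stem>.features.csv, <stem>.targets.csv and <stem>.meta.json."""
        stem = Path(stem)
        pd.DataFrame(self.features, columns=self.config.feature_names).to_csv(
            stem.with_suffix(".features.csv"), index=False
        )
        pd.DataFrame({"uvi": self.targets, "split": self.split_labels}).to_csv(
            stem.with_suffix(".targets.csv"), index=False
        )
        meta = {
            "use_zenith": self.config.use_zenith,
            "use_month": self.config.use_month,
            "normalization": [list(p) for p in self.normalization],
            "seed": self.seed,
        }
        stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def extract(
    records: Sequence[LightRecord],
    config: InputConfig,
    lux_scale: float = DEFAULT_LUX_SCALE,
    zenith_scale: float = DEFAULT_ZENITH_SCALE,
) -> TrainingSet:
    """Assemble a training set from daytime records.

    Nighttime records (zenith >= 90 deg) are excluded and counted; records
    must have zenith attached.  Features are ordered
    ``[illuminance, zenith?, month one-hot?]`` with continuous features
    scaled by the given physical constants (an explicit training-split
    refit happens in :func:`split`).
    """
    day: list[LightRecord] = []
    dropped = 0
    for r in records:
        if r.zenith is None:
            raise ValueError("records must have zenith attached")
        if r.zenith < 90.0:
            day.append(r)
        else:
            dropped += 1
    if dropped:
        logger.info("excluded %d nighttime record(s)", dropped)
    if not day:
        raise ValueError("no daytime records to extract")

    n = len(day)
    cols = [np.array([r.illuminance for r in day]) / lux_scale]
    norms: list[tuple[float, float]] = [(0.0, lux_scale)]
    if config.use_zenith:
        cols.append(np.array([r.zenith for r in day]) / zenith_scale)
        norms.append((0.0, zenith_scale))
    months = np.array([r.timestamp.month for r in day])
    if config.use_month:
        onehot = np.zeros((n, 12))
        onehot[np.arange(n), months - 1] = 1.0
        features = np.column_stack([*cols, onehot])
    else:
        features = np.column_stack(cols)
    return TrainingSet(
        features=features,
        targets=np.array([r.uvi for r in day], dtype=float),
        config=config,
        normalization=tuple(norms),
        months=months,
        split_labels=np.full(n, "train", dtype=object),
    )


def split(
    ts: TrainingSet,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    refit_normalization: bool = True,
) -> TrainingSet:
    """Random train/val/test partition, stratified by calendar month.

    Within each month the rows are shuffled with a generator seeded from
    ``seed`` and dealt to the three splits by the given fractions, so the
    partition is reproducible and every month is represented in every
    non-empty split.  With ``refit_normalization`` the continuous features
    are re-scaled min-max to [0, 1] using the training rows only.
    """
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(ts.targets)
    labels = np.empty(n, dtype=object)
    for month in np.unique(ts.months):
        idx = np.flatnonzero(ts.months == month)
        rng.shuffle(idx)
        n_train = round(fractions[0] * len(idx))
        n_val = round(fractions[1] * len(idx))
        labels[idx[:n_train]] = "train"
        labels[idx[n_train : n_train + n_val]] = "val"
        labels[idx[n_train + n_val :]] = "test"
    out = replace(ts, split_labels=labels, seed=seed)
    if refit_normalization:
        out = _refit_minmax(out)
    return out


def _refit_minmax(ts: TrainingSet) -> TrainingSet:
    """Min-max rescale continuous features using training rows only."""
    train_idx = ts.rows("train")
    if train_idx.size == 0:
        return ts
    feats = ts.features.copy()
    norms = []
    for j, (off0, scale0) in enumerate(ts.normalization):
        raw = feats[:, j] * scale0 + off0  # undo current scaling
        lo = float(raw[train_idx].min())
        hi = float(raw[train_idx].max())
        scale = hi - lo if hi > lo else 1.0
        feats[:, j] = (raw - lo) / scale
        norms.append((lo, scale))
    return replace(ts, features=feats, normalization=tuple(norms))
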