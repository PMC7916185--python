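"""Natural-light record store: data model, CSV I/O, and summary statistics.

A :class:`LightRecord` is one timestamped sky observation — illuminance in
lux, UV index, optional colourimetric descriptors (correlated colour
temperature, CIE chromaticity, short-wavelength ratio) and the solar zenith
angle at the instant of measurement.  The analysis helpers compute the
feature correlations and per-month extremes used to choose model inputs:
monthly maxima of illuminance and of the 13:00-hour UVI, and the Pearson
correlation between illuminance and UVI over each month's daytime records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LightRecord",
    "MonthlyStats",
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "pearson",
    "monthly_stats",
    "correlation_matrix",
    "FormatError",
]

logger = logging.getLogger(__name__)

#: columns that must be present in a light-record CSV
MANDATORY_COLUMNS = ("timestamp", "illuminance_lux", "uvi")
#: optional descriptor columns, in canonical file order
OPTIONAL_COLUMNS = ("cct_k", "chroma_x", "chroma_y", "swr", "zenith_deg")

#: UVI ceiling for records taken with the sun at/below the horizon
NIGHT_UVI_MAX = 0.1


class FormatError(ValueError):
    """A light-record file is structurally invalid (e.g. missing columns)."""


@dataclass(frozen=True)
class LightRecord:
    """One timestamped natural-light observation."""

    timestamp: datetime
    illuminance: float  # lux
    uvi: float
    cct: float | None = None  # correlated colour temperature, K
    chroma_x: float | None = None
    chroma_y: float | None = None
    swr: float | None = None  # short-wavelength fraction of visible light
    zenith: float | None = None  # solar zenith angle, degrees

    def validate(self) -> str | None:
        """Return a reason string if an invariant is violated, else None."""
        if self.timestamp.tzinfo is None:
            return "timestamp lacks UTC offset"
        if not math.isfinite(self.illuminance) or self.illuminance < 0:
            return f"illuminance {self.illuminance} < 0 or non-finite"
        if not math.isfinite(self.uvi) or self.uvi < 0:
            return f"uvi {self.uvi} < 0 or non-finite"
        if self.cct is not None and self.cct <= 0:
            return f"cct {self.cct} <= 0"
        for name in ("chroma_x", "chroma_y", "swr"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                return f"{name} {v} outside [0, 1]"
        if self.zenith is not None and self.zenith >= 90.0 and self.uvi > NIGHT_UVI_MAX:
            return f"uvi {self.uvi} > {NIGHT_UVI_MAX} with sun below horizon"
        return None

    @property
    def is_daytime(self) -> bool:
        if self.zenith is None:
            raise ValueError("record has no zenith attached")
        return self.zenith < 90.0


@dataclass(frozen=True)
class MonthlyStats:
    """Per-month illuminance/UVI summary; fields are None when no data."""

    month: int
    max_illuminance: float | None
    max_uvi: float | None  # maximum over the 13:00 local hour
    pearson_r: float | None  # r(illuminance, uvi) over daytime records

    @property
    def absent(self) -> bool:
        return self.max_illuminance is None


_FIELD_BY_COLUMN = {
    "illuminance_lux": "illuminance",
    "uvi": "uvi",
    "cct_k": "cct",
    "chroma_x": "chroma_x",
    "chroma_y": "chroma_y",
    "swr": "swr",
    "zenith_deg": "zenith",
}


def records_to_frame(records: Iterable[LightRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with the canonical CSV columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "timestamp": r.timestamp,
                "illuminance_lux": r.illuminance,
                "uvi": r.uvi,
                "cct_k": r.cct,
                "chroma_x": r.chroma_x,
                "chroma_y": r.chroma_y,
                "swr": r.swr,
                "zenith_deg": r.zenith,
            }
        )
    return pd.DataFrame(rows, columns=["timestamp", *_FIELD_BY_COLUMN])


def frame_to_records(df: pd.DataFrame) -> list[LightRecord]:
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col, attr in _FIELD_BY_COLUMN.items():
            v = getattr(row, col, None)
            kwargs[attr] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        ts = row.timestamp
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts)
        elif isinstance(ts, pd.Timestamp):
            ts = ts.to_pydatetime()
        records.append(LightRecord(timestamp=ts, **kwargs))
    return records


def read_records(path: str | Path) -> list[LightRecord]:
    """Read a light-record CSV, dropping rows that violate invariants.

    Rows with negative illuminance/UVI, out-of-range descriptors, daytime-UVI
    at night, or non-increasing timestamps are rejected; the rejection count
    is logged at WARNING.  Missing mandatory columns raise :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    kept: list[LightRecord] = []
    rejected = 0
    last_ts: datetime | None = None
    for rec in frame_to_records(df):
        reason = rec.validate()
        if reason is None and last_ts is not None and rec.timestamp <= last_ts:
            reason = "timestamps not strictly increasing"
        if reason is not None:
            rejected += 1
            logger.debug("rejecting row at %s: %s", rec.timestamp, reason)
            continue
        last_ts = rec.timestamp
        kept.append(rec)
    if rejected:
        logger.warning("%s: rejected %d invalid row(s), kept %d", path, rejected, len(kept))
    return kept


def write_records(records: Sequence[LightRecord], path: str | Path) -> None:
    """Write records as CSV (ISO-8601 timestamps with offset, 6 sig. digits)."""
    df = records_to_frame(records)
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    for col in df.columns[1:]:
        df[col] = df[col].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.6g}")
    df.to_csv(path, index=False)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def monthly_stats(records: Sequence[LightRecord]) -> list[MonthlyStats]:
    """Twelve per-month summaries (January..December).

    ``max_illuminance`` is the month's maximum over all records,
    ``max_uvi`` the maximum among records whose local clock hour is 13
    (the early-afternoon peak hour), and ``pearson_r`` the illuminance-UVI
    correlation over the month's daytime (zenith < 90 deg) records.
    Months with fewer than two daytime records are marked absent.
    """
    out = []
    for month in range(1, 13):
        sub = [r for r in records if r.timestamp.month == month]
        day = [r for r in sub if r.zenith is not None and r.zenith < 90.0]
        if len(day) < 2:
            out.append(MonthlyStats(month, None, None, None))
            continue
        at13 = [r.uvi for r in day if r.timestamp.hour == 13]
        lux = [r.illuminance for r in day]
        uvi = [r.uvi for r in day]
        try:
            r_lu = pearson(lux, uvi)
        except ValueError:
            r_lu = None
        out.append(
            MonthlyStats(
                month=month,
                max_illuminance=max(r.illuminance for r in sub),
                max_uvi=max(at13) if at13 else None,
                pearson_r=r_lu,
            )
        )
    return out


def monthly_stats_frame(records: Sequence[LightRecord]) -> pd.DataFrame:
    """Monthly stats as a 12-row DataFrame, convenient for CSV export."""
    rows = [
        {
            "month": s.month,
            "max_illuminance_lux": s.max_illuminance,
            "max_uvi_13h": s.max_uvi,
            "pearson_r_lux_uvi": s.pearson_r,
        }
        for s in monthly_stats(records)
    ]
    return pd.DataFrame(rows)


#: variables entering the pairwise correlation analysis, in display order
CORRELATION_VARIABLES = ("illuminance", "cct", "chroma_x", "chroma_y", "swr", "zenith", "uvi")


def correlation_matrix(records: Sequence[LightRecord]) -> pd.DataFrame:
    """Pairwise Pearson correlations between light-record variables.

    Entries are computed over records where both variables are present;
    pairs with fewer than two joint observations or zero variance are NaN.
    The result is symmetric with a unit diagonal.
    """
    cols = {v: np.array([getattr(r, v) for r in records], dtype=object) for v in CORRELATION_VARIABLES}
    n = len(CORRELATION_VARIABLES)
    mat = np.full((n, n), np.nan)
    for i, vi in enumerate(CORRELATION_VARIABLES):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            vj = CORRELATION_VARIABLES[j]
            mask = np.array([a is not None and b is not None for a, b in zip(cols[vi], cols[vj])])
            if mask.sum() < 2:
                continue
            x = cols[vi][mask].astype(float)
            y = cols[vj][mask].astype(float)
            try:
                r = pearson(x, y)
            except ValueError:
                continue
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=CORRELATION_VARIABLES, columns=CORRELATION_VARIABLES)
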