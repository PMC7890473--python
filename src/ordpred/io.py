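"""Reading and writing timestamped price series as CSV.

Timestamps are metadata only — every computation in the package indexes by
position.  Missing sampling intervals (e.g. dropped minutes in exchange
data) are reported, never imputed: the series is treated as contiguous
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PriceSeries", "GapReport", "read_price_csv", "write_price_csv"]


@dataclass(frozen=True)
class GapReport:
    """Sampling gaps: positions where the timestamp step exceeds the modal step."""

    n_gaps: int
    locations: list[int]  # index of the observation before each gap
    missing_steps: list[int]  # whole modal steps skipped at each gap


@dataclass(frozen=True)
class PriceSeries:
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values differ in length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be non-decreasing")
        if len(self.timestamps) != self.timestamps.nunique():
            raise ValueError("timestamps contain duplicates")
        if not np.isfinite(self.values).all():
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite price at row {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def gap_report(self) -> GapReport:
        """Detect skipped sampling steps relative to the modal timestamp step."""
        if len(self) < 3:
            return GapReport(0, [], [])
        diffs = np.diff(self.timestamps.asi8)
        step = np.median(diffs)
        if step <= 0:
            return GapReport(0, [], [])
        ratio = np.round(diffs / step).astype(int)
        locs = np.flatnonzero(ratio > 1)
        return GapReport(
            n_gaps=int(locs.size),
            locations=[int(i) for i in locs],
            missing_steps=[int(ratio[i] - 1) for i in locs],
        )


def read_price_csv(
    path,
    timestamp_col: str = "timestamp",
    value_col: str = "close",
) -> PriceSeries:
    """Load a timestamped close-price CSV into a :class:`PriceSeries`.

    Raises a descriptive error for missing columns, unparseable rows or
    non-monotone timestamps.
    """
    df = pd.read_csv(path)
    for col in (timestamp_col, value_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r}; available: {list(df.columns)}"
            )
    try:
        ts = pd.to_datetime(df[timestamp_col], format="mixed")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    values = pd.to_numeric(df[value_col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        rows = ", ".join(str(int(i) + 2) for i in bad[:5])  # 1-based + header
        raise ValueError(f"{path}: non-numeric or missing price at line(s) {rows}")
    idx = pd.DatetimeIndex(ts)
    if len(idx) > 1 and not idx.is_monotonic_increasing:
        first = int(np.flatnonzero(np.diff(idx.asi8) < 0)[0])
        raise ValueError(
            f"{path}: timestamps not in increasing order at line {first + 3}"
        )
    return PriceSeries(timestamps=idx, values=values)


def write_price_csv(series: PriceSeries, path) -> None:
    """Write the schema :func:`read_price_csv` consumes (lossless round trip)."""
    pd.DataFrame(
        {"timestamp": series.timestamps, "close": series.values}
    ).to_csv(path, index=False, float_format="%.12g")


def series_from_values(values: np.ndarray, start: str = "2018-01-01", freq: str = "min") -> PriceSeries:
    """Wrap a bare value array with synthetic minute timestamps."""
    values = np.asarray(values, dtype=float)
    ts = pd.date_range(start=start, periods=values.size, freq=freq)
    return PriceSeries(timestamps=ts, values=values)
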