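"""Alignment of multi-rate sensor streams onto a common time grid.

Subsea observatories record each sensor at its own cadence (conductivity and
temperature every 5 min, current profilers every 10 min, a fluorometer once an
hour ...).  Multivariate monitoring needs all variables in one rectangular
table, so every stream is linearly interpolated onto a shared, equally spaced
grid.  Cells that cannot be interpolated honestly — outside the stream's
extent, or inside a raw-data gap wider than ``max_gap`` — are marked missing
rather than extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "AlignedTable",
    "align_streams",
    "read_aligned_table",
    "write_aligned_table",
]

logger = logging.getLogger(__name__)


@dataclass
class SensorStream:
    """A single sensor variable sampled at its own (nominal) interval.

    Parameters
    ----------
    name : str
        Variable label, unique within a deployment.
    timestamps : pandas.DatetimeIndex
        Strictly increasing sampling instants (interpreted as UTC).
    values : ndarray of float
        Raw readings in native sensor units; NaN marks an invalid reading
        (treated as if the sample were absent).
    nominal_interval : pandas.Timedelta
        The sensor's design sampling interval, e.g. ``Timedelta("5min")``.
    """

    name: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    nominal_interval: pd.Timedelta = field(default_factory=lambda: pd.Timedelta("1h"))

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        self.nominal_interval = pd.Timedelta(self.nominal_interval)
        if len(self.timestamps) != len(self.values):
            raise ValueError(
                f"stream {self.name!r}: {len(self.timestamps)} timestamps "
                f"but {len(self.values)} values"
            )
        if len(self.timestamps) == 0:
            raise ValueError(f"stream {self.name!r} is empty")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError(f"stream {self.name!r}: timestamps must be strictly increasing")
        if self.nominal_interval <= pd.Timedelta(0):
            raise ValueError(f"stream {self.name!r}: nominal_interval must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def dropna(self) -> "SensorStream":
        """Return a copy without NaN readings (used before interpolation)."""
        ok = np.isfinite(self.values)
        if ok.all():
            return self
        if not ok.any():
            raise ValueError(f"stream {self.name!r} has no finite values")
        return SensorStream(self.name, self.timestamps[ok], self.values[ok], self.nominal_interval)


class AlignedTable:
    """Equally spaced time grid x variables, with an explicit missing mask.

    Thin wrapper over a :class:`pandas.DataFrame` with a ``DatetimeIndex``;
    NaN encodes a missing cell.  This is the exchange object every downstream
    stage (PCA, monitoring, diagnostics) consumes.
    """

    def __init__(self, frame: pd.DataFrame):
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise TypeError("AlignedTable requires a DatetimeIndex")
        if frame.shape[0] == 0:
            raise ValueError("AlignedTable has zero rows")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate variable labels: {dups}")
        if not frame.index.is_monotonic_increasing:
            raise ValueError("grid timestamps must be increasing")
        self.frame = frame.astype(float)

    # -- container protocol -------------------------------------------------
    @property
    def index(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True exactly where a cell is missing."""
        return self.frame.isna().to_numpy()

    @property
    def n_obs(self) -> int:
        return self.frame.shape[0]

    @property
    def n_vars(self) -> int:
        return self.frame.shape[1]

    @property
    def grid_step(self) -> pd.Timedelta | None:
        """Grid spacing if the retained rows sit on a constant-step grid."""
        if len(self.index) < 2:
            return None
        deltas = np.diff(self.index.asi8)
        step = np.gcd.reduce(deltas)
        return pd.Timedelta(step, unit="ns")

    def window(self, start=None, end=None) -> "AlignedTable":
        """Rows with ``start <= t < end`` (closed-open)."""
        idx = self.frame.index
        keep = np.ones(len(idx), dtype=bool)
        if start is not None:
            keep &= idx >= pd.Timestamp(start)
        if end is not None:
            keep &= idx < pd.Timestamp(end)
        if not keep.any():
            raise ValueError(f"window [{start}, {end}) selects zero rows")
        return AlignedTable(self.frame.loc[keep])

    def missing_fraction(self) -> pd.Series:
        return self.frame.isna().mean()

    def __repr__(self) -> str:  # pragma: no cover
        return f"AlignedTable({self.n_obs} obs x {self.n_vars} vars)"

    def __eq__(self, other) -> bool:
        return isinstance(other, AlignedTable) and self.frame.equals(other.frame)


def _grid_anchor(t0: pd.Timestamp, step: pd.Timedelta) -> pd.Timestamp:
    """First whole multiple of ``step`` (since epoch) at or after ``t0``."""
    step_ns = step.value
    q, r = divmod(t0.value, step_ns)
    return pd.Timestamp((q + (r > 0)) * step_ns)


def align_streams(
    streams: Sequence[SensorStream],
    grid_step: str | pd.Timedelta = "1h",
    max_gap: str | pd.Timedelta = "6h",
    window: tuple | None = None,
    drop_all_missing: bool = True,
) -> AlignedTable:
    """Linearly interpolate sensor streams onto a common equally spaced grid.

    Parameters
    ----------
    streams : sequence of SensorStream
        At least one stream; labels must be unique.
    grid_step : str or Timedelta, default "1h"
        Grid spacing.  The grid is anchored at the first whole multiple of
        ``grid_step`` at or after the earliest sample of any stream, so the
        result is independent of call order.
    max_gap : str or Timedelta, default "6h"
        A grid cell whose two bracketing raw samples are further apart than
        this is marked missing instead of being bridged by interpolation.
        Must be at least ``grid_step``.
    window : (start, end), optional
        Crop the grid to ``start <= t < end`` after alignment.
    drop_all_missing : bool, default True
        Drop grid rows in which every variable is missing (interruptions
        common to all sensors carry no information).

    Returns
    -------
    AlignedTable

    Notes
    -----
    No extrapolation: grid points before a stream's first or after its last
    sample are missing for that stream.  A grid point coinciding exactly with
    a raw sample always takes that sample's value, whatever the neighbouring
    gaps.
    """
    if len(streams) == 0:
        raise ValueError("align_streams needs at least one stream")
    grid_step = pd.Timedelta(grid_step)
    max_gap = pd.Timedelta(max_gap)
    if grid_step <= pd.Timedelta(0):
        raise ValueError("grid_step must be positive")
    if max_gap < grid_step:
        raise ValueError("max_gap must be at least grid_step")
    names = [s.name for s in streams]
    if len(set(names)) != len(names):
        raise ValueError("stream labels must be unique")

    streams = [s.dropna() for s in streams]
    t_first = min(s.timestamps[0] for s in streams)
    t_last = max(s.timestamps[-1] for s in streams)
    start = _grid_anchor(t_first, grid_step)
    grid = pd.date_range(start, t_last, freq=grid_step)
    if len(grid) == 0:
        raise ValueError("grid is empty: streams span less than one grid step")

    grid_ns = grid.asi8
    columns: dict[str, np.ndarray] = {}
    for s in streams:
        ts = s.timestamps.asi8
        vals = np.interp(grid_ns, ts, s.values)
        # locate bracketing samples for the gap / extent check
        right = np.searchsorted(ts, grid_ns, side="left")
        exact = np.zeros(len(grid_ns), dtype=bool)
        inside = (right > 0) & (right < len(ts))
        exact[right < len(ts)] = ts[right[right < len(ts)]] == grid_ns[right < len(ts)]
        gap_ok = np.zeros(len(grid_ns), dtype=bool)
        idx = np.clip(right, 1, max(len(ts) - 1, 1))
        gap_ok[inside] = (ts[idx[inside]] - ts[idx[inside] - 1]) <= max_gap.value
        ok = exact | (inside & gap_ok)
        vals = np.where(ok, vals, np.nan)
        columns[s.name] = vals

    frame = pd.DataFrame(columns, index=grid)
    if window is not None:
        start_w, end_w = window
        keep = np.ones(len(frame), dtype=bool)
        if start_w is not None:
            keep &= frame.index >= pd.Timestamp(start_w)
        if end_w is not None:
            keep &= frame.index < pd.Timestamp(end_w)
        frame = frame.loc[keep]
    if drop_all_missing:
        frame = frame.loc[~frame.isna().all(axis=1)]
    if frame.shape[0] == 0:
        raise ValueError("alignment produced zero usable rows")
    table = AlignedTable(frame)
    logger.info("aligned %d streams -> %d rows x %d variables", len(streams), table.n_obs, table.n_vars)
    return table


def read_aligned_table(
    path: str | Path,
    timestamp_column: str | int = 0,
    timestamp_format: str | None = None,
) -> AlignedTable:
    """Load an aligned table from CSV or XLSX.

    The first column (or ``timestamp_column``) holds timestamps; remaining
    columns are numeric variables; empty cells become missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if isinstance(timestamp_column, int):
        ts_label = raw.columns[timestamp_column]
    else:
        ts_label = timestamp_column
        if ts_label not in raw.columns:
            raise ValueError(f"{path}: timestamp column {ts_label!r} not found")
    try:
        ts = pd.to_datetime(raw[ts_label], format=timestamp_format, utc=False)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamps in {ts_label!r}: {exc}") from exc
    data = raw.drop(columns=[ts_label]).apply(pd.to_numeric, errors="coerce")
    frame = data.set_axis(pd.DatetimeIndex(ts), axis=0)
    table = AlignedTable(frame)
    logger.info("read %s: %d rows x %d variables", path.name, table.n_obs, table.n_vars)
    return table


def write_aligned_table(table: AlignedTable, path: str | Path) -> None:
    """Write an aligned table to CSV or XLSX (missing cells written empty).

    CSV output uses RFC-4180 with "." decimals and full float repr, so a
    fixed table always serialises to identical bytes.
    """
    path = Path(path)
    frame = table.frame.copy()
    frame.index.name = "timestamp"
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame.to_excel(path)
    else:
        frame.to_csv(path, lineterminator="\n")
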