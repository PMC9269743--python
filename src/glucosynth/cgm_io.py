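"""Reading, cleaning, and reshaping of CGM traces.

A raw trace is a timestamped sequence of interstitial glucose readings
(mg/dL) at a nominal 5-minute cadence.  The pipeline regularizes the trace
onto a strict 5-minute grid, linearly interpolates short sensor dropouts
(gaps shorter than one hour), and reshapes the result into a matrix of
complete days — 288 consecutive readings per row — which is the unit every
downstream model consumes.

Glucose values are clamped to the CGM sensor reporting range [40, 400] mg/dL
so all models operate on a fixed support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 400.0
STEP = pd.Timedelta(minutes=5)
SAMPLES_PER_DAY = 288

__all__ = [
    "GLUCOSE_MIN",
    "GLUCOSE_MAX",
    "SAMPLES_PER_DAY",
    "GlucoseSeries",
    "DayMatrix",
    "read_cgm_csv",
    "write_cgm_csv",
    "interpolate_gaps",
    "to_day_matrix",
    "read_day_matrix",
    "write_day_matrix",
]


class CGMFormatError(ValueError):
    """Unparseable or structurally invalid CGM input."""


class CGMIntegrityError(ValueError):
    """Input that parses but violates a trace invariant (e.g. duplicates)."""


@dataclass
class GlucoseSeries:
    """A single patient's timestamped glucose trace.

    ``glucose`` uses NaN for missing readings.  Timestamps are strictly
    increasing but not necessarily on a regular grid until
    :meth:`on_grid` is applied.
    """

    patient_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray

    def __post_init__(self):
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.times) != len(self.glucose):
            raise ValueError("times and glucose must have equal length")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise CGMIntegrityError("timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.times)

    def on_grid(self, snap_tolerance: pd.Timedelta = pd.Timedelta(seconds=90)) -> "GlucoseSeries":
        """Return the series regularized onto a strict 5-minute grid.

        Off-grid timestamps are snapped to the nearest slot when within
        ``snap_tolerance``; otherwise the reading is discarded and its slot
        left missing (real CGM exports drift slightly; larger offsets are
        treated as unreliable).  If two readings snap to the same slot the
        first is kept.
        """
        if len(self) == 0:
            return replace(self, times=pd.DatetimeIndex([]), glucose=np.array([]))
        start = self.times[0].floor("5min")
        end = self.times[-1].ceil("5min")
        grid = pd.date_range(start, end, freq=STEP)
        values = np.full(len(grid), np.nan)
        offsets = (self.times - start) / STEP
        slots = np.round(offsets).astype(int)
        dist = np.abs(self.times - (start + slots * STEP))
        for slot, d, g in zip(slots, dist, self.glucose):
            if d <= snap_tolerance and 0 <= slot < len(grid) and np.isnan(values[slot]):
                values[slot] = g
        return GlucoseSeries(self.patient_id, grid, values)


@dataclass
class DayMatrix:
    """Complete glucose days for one patient: ``rows`` is n_days x 288.

    Every row is gap-free and within the sensor support.  ``anchor_hour``
    is the hour of day at which each row starts (0 for generative
    modelling; 17 so that one row spans both the pre-sleep feature window
    and the night to be labeled).
    """

    patient_id: str
    rows: np.ndarray
    anchor_hour: int = 0
    day_dates: list = field(default_factory=list)
    provenance: str = "real"
    n_dropped: int = 0

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.size == 0:
            self.rows = self.rows.reshape(0, SAMPLES_PER_DAY)
        if self.rows.shape[1] != SAMPLES_PER_DAY:
            raise ValueError(
                f"each day row must have {SAMPLES_PER_DAY} values, got {self.rows.shape[1]}")
        if np.isnan(self.rows).any():
            raise ValueError("day matrix rows must be complete (no missing values)")
        if not self.day_dates:
            self.day_dates = list(range(len(self.rows)))

    @property
    def n_days(self) -> int:
        return self.rows.shape[0]


def read_cgm_csv(path, patient_id: str) -> GlucoseSeries:
    """Read a ``timestamp,glucose`` CSV into a :class:`GlucoseSeries`.

    Timestamps are ISO-8601; an empty glucose cell marks a missing reading.
    Values are clamped to [40, 400] mg/dL.  Duplicate timestamps are
    rejected rather than silently merged.
    """
    df = pd.read_csv(path, dtype={"timestamp": str})
    missing_cols = {"timestamp", "glucose"} - set(df.columns)
    if missing_cols:
        raise CGMFormatError(f"missing required column(s): {sorted(missing_cols)}")
    times = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(times.isna() & df["timestamp"].notna())
    if len(bad):
        raise CGMFormatError(
            f"unparseable timestamp {df['timestamp'].iloc[bad[0]]!r} at data row {bad[0]}")
    if times.isna().any():
        raise CGMFormatError("empty timestamp cell")
    glucose = pd.to_numeric(df["glucose"], errors="coerce").to_numpy(dtype=float)
    order = np.argsort(times.to_numpy(), kind="stable")
    times = pd.DatetimeIndex(times.to_numpy()[order])
    glucose = glucose[order]
    if times.duplicated().any():
        dup = times[times.duplicated()][0]
        raise CGMIntegrityError(f"duplicate timestamp {dup}")
    glucose = np.clip(glucose, GLUCOSE_MIN, GLUCOSE_MAX)
    return GlucoseSeries(patient_id, times, glucose)


def write_cgm_csv(series: GlucoseSeries, path) -> None:
    df = pd.DataFrame({
        "timestamp": series.times.strftime("%Y-%m-%dT%H:%M:%S"),
        "glucose": series.glucose,
    })
    df.to_csv(path, index=False)


def interpolate_gaps(series: GlucoseSeries,
                     max_gap: pd.Timedelta = pd.Timedelta(hours=1)) -> GlucoseSeries:
    """Linearly fill missing runs strictly shorter than ``max_gap``.

    Short dropouts (a punctual loss of sensor signal) are recoverable by
    linear interpolation between the flanking readings; longer outages are
    left missing so the affected days can be dropped.  The operation is
    idempotent and never alters an observed value.
    """
    g = series.on_grid()
    values = g.glucose.copy()
    max_slots = int(max_gap / STEP)
    isnan = np.isnan(values)
    if not isnan.any():
        return g
    valid_idx = np.flatnonzero(~isnan)
    for left, right in zip(valid_idx[:-1], valid_idx[1:]):
        run = right - left - 1
        if 0 < run < max_slots:
            frac = np.arange(1, run + 1) / (right - left)
            values[left + 1: right] = values[left] + frac * (values[right] - values[left])
    return GlucoseSeries(g.patient_id, g.times, values)


def to_day_matrix(series: GlucoseSeries, anchor_hour: int = 0) -> DayMatrix:
    """Reshape a (gridded, interpolated) trace into complete 288-wide days.

    Each 24-hour window starting at ``anchor_hour`` becomes one row; any
    window still containing a missing value after interpolation is dropped
    whole, since the models consume only fixed-width complete rows.
    """
    g = series.on_grid()
    if len(g) == 0:
        warnings.warn("empty series: no complete days")
        return DayMatrix(series.patient_id, np.empty((0, SAMPLES_PER_DAY)),
                         anchor_hour=anchor_hour, day_dates=[])
    anchor = g.times[0].normalize() + pd.Timedelta(hours=anchor_hour)
    if anchor < g.times[0]:
        anchor += pd.Timedelta(days=1)
    start_idx = int((anchor - g.times[0]) / STEP)
    rows, dates, dropped = [], [], 0
    idx = start_idx
    while idx + SAMPLES_PER_DAY <= len(g):
        window = g.glucose[idx: idx + SAMPLES_PER_DAY]
        if np.isnan(window).any():
            dropped += 1
        else:
            rows.append(window)
            dates.append(g.times[idx].date())
        idx += SAMPLES_PER_DAY
    if not rows:
        warnings.warn(f"no complete {SAMPLES_PER_DAY}-sample day found "
                      f"({dropped} window(s) dropped)")
        return DayMatrix(series.patient_id, np.empty((0, SAMPLES_PER_DAY)),
                         anchor_hour=anchor_hour, day_dates=[], n_dropped=dropped)
    return DayMatrix(series.patient_id, np.vstack(rows), anchor_hour=anchor_hour,
                     day_dates=dates, n_dropped=dropped)


def write_day_matrix(dm: DayMatrix, path) -> None:
    """Write a day matrix as CSV: ``patient_id,date`` then 288 value columns."""
    cols = {f"g{i:03d}": dm.rows[:, i] for i in range(SAMPLES_PER_DAY)}
    df = pd.DataFrame({"patient_id": dm.patient_id,
                       "date": [str(d) for d in dm.day_dates], **cols})
    # %.17g keeps every float bit so write/read round-trips exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_day_matrix(path, anchor_hour: int = 0, provenance: str = "real") -> DayMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    value_cols = [c for c in df.columns if c.startswith("g")]
    if len(value_cols) != SAMPLES_PER_DAY:
        raise CGMFormatError(
            f"expected {SAMPLES_PER_DAY} value columns, found {len(value_cols)}")
    pid = str(df["patient_id"].iloc[0]) if len(df) else ""
    return DayMatrix(pid, df[value_cols].to_numpy(dtype=float),
                     anchor_hour=anchor_hour, day_dates=list(df["date"]),
                     provenance=provenance)
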