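"""Reading, writing and cleaning of IMU streams and coach label files.

File formats
------------
IMU CSV, one row per sample::

    t,ax,ay,az,gx,gy,gz,ox,oy,oz,rx,ry,rz

with ``t`` in seconds (3 decimal places) and the 12 sensor channels in
native units.  Labels are CSV (``t,state,note``) or JSONL with the same
fields; ``state`` is binary (0 = out of the zone, 1 = in the zone).

Cleaning reproduces the standard wearable preprocessing: duplicated
timestamps are removed (first occurrence kept) and missing samples on the
nominal 10 Hz grid are filled by per-channel linear interpolation between
the nearest observed neighbours.  No extrapolation is performed beyond
the observed span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CHANNEL_NAMES, N_CHANNELS, SAMPLE_RATE_HZ, ImuSeries, LabelEvent

IMU_COLUMNS = ("t",) + CHANNEL_NAMES


class ParseError(ValueError):
    """Raised when an input file does not match the expected schema."""


@dataclass
class CleanReport:
    """Summary of one cleaning pass."""

    duplicates_removed: int
    samples_interpolated: int
    span: float  # s, first to last observed timestamp

    def __post_init__(self):
        if self.duplicates_removed < 0 or self.samples_interpolated < 0:
            raise ValueError("counts must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


# ----------------------------------------------------------------------
def write_imu_csv(series: ImuSeries, path) -> None:
    """Write a series to CSV (t to 3 decimals, channels to 6 significant digits)."""
    with open(path, "w") as fh:
        fh.write(",".join(IMU_COLUMNS) + "\n")
        for t, row in zip(series.timestamps, series.channels):
            fh.write(f"{t:.3f}," + ",".join(f"{v:.6g}" for v in row) + "\n")


def read_imu_csv(path, player_id: str | None = None) -> ImuSeries:
    """Read an IMU CSV; raises :class:`ParseError` naming the offending row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = pd.read_csv(path, nrows=0)
    if tuple(header.columns) != IMU_COLUMNS:
        raise ParseError(
            f"{path}: expected columns {list(IMU_COLUMNS)}, found {list(header.columns)}"
        )
    try:
        df = pd.read_csv(path, dtype=float)
    except ValueError:
        # locate the offending row for the error message
        raw = pd.read_csv(path, dtype=str)
        for i, row in raw.iterrows():
            try:
                row.astype(float)
            except ValueError:
                raise ParseError(f"{path}: non-numeric value in data row {i + 1}") from None
        raise ParseError(f"{path}: non-numeric data") from None
    return ImuSeries(
        player_id=player_id or path.stem,
        timestamps=df["t"].to_numpy(),
        channels=df[list(CHANNEL_NAMES)].to_numpy(),
    )


def write_labels(events: list[LabelEvent], path) -> None:
    """Write label events as CSV (``t,state,note``) or JSONL by extension."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with open(path, "w") as fh:
            for e in events:
                fh.write(json.dumps({"t": e.timestamp, "state": e.state, "note": e.note}) + "\n")
    else:
        df = pd.DataFrame(
            {
                "t": [e.timestamp for e in events],
                "state": [e.state for e in events],
                "note": [e.note if e.note is not None else "" for e in events],
            }
        )
        df.to_csv(path, index=False, float_format="%.3f")


def read_labels(path) -> list[LabelEvent]:
    """Read label events (CSV or JSONL), sorted by timestamp.

    States are coerced to {0, 1}; anything else raises :class:`ParseError`.
    An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[dict] = []
    if path.suffix == ".jsonl":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
    else:
        if path.stat().st_size == 0:
            return []
        df = pd.read_csv(path)
        if len(df.columns) < 2 or tuple(df.columns[:2]) != ("t", "state"):
            raise ParseError(f"{path}: expected columns t,state[,note]")
        rows = df.to_dict("records")
    events = []
    for i, r in enumerate(rows):
        state = float(r["state"])
        if state not in (0.0, 1.0):
            raise ParseError(f"{path}: state outside {{0,1}} in row {i + 1}")
        note = r.get("note")
        if not isinstance(note, str) or note == "":
            note = None  # covers missing keys and NaN from pandas
        events.append(LabelEvent(float(r["t"]), int(state), note))
    events.sort(key=lambda e: e.timestamp)
    return events


# ----------------------------------------------------------------------
def clean_series(series: ImuSeries, rate_hz: float = SAMPLE_RATE_HZ) -> tuple[ImuSeries, CleanReport]:
    """Remove duplicate timestamps and fill missing grid points.

    Output timestamps form the complete ``1/rate_hz`` grid from the first
    to the last observed stamp.  Duplicate stamps collapse to the first
    occurrence; absent grid points are filled per channel by linear
    interpolation between the nearest observed neighbours.
    """
    t = np.asarray(series.timestamps, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples to clean")
    # snap to the nominal grid and sort stably (preserves first-occurrence
    # order among duplicates)
    gidx = np.round(t * rate_hz).astype(np.int64)
    order = np.argsort(gidx, kind="stable")
    gidx = gidx[order]
    X = series.channels[order]
    uniq, first = np.unique(gidx, return_index=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct timestamps")
    duplicates_removed = len(gidx) - len(uniq)
    Xu = X[first]
    grid = np.arange(uniq[0], uniq[-1] + 1)
    samples_interpolated = len(grid) - len(uniq)
    if samples_interpolated == 0 and duplicates_removed == 0 and np.array_equal(grid, gidx):
        out = ImuSeries(series.player_id, grid / rate_hz, series.channels[order])
    else:
        filled = np.empty((len(grid), N_CHANNELS))
        for c in range(N_CHANNELS):
            filled[:, c] = np.interp(grid, uniq, Xu[:, c])
        out = ImuSeries(series.player_id, grid / rate_hz, filled)
    report = CleanReport(
        duplicates_removed=int(duplicates_removed),
        samples_interpolated=int(samples_interpolated),
        span=float((uniq[-1] - uniq[0]) / rate_hz),
    )
    return out, report
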