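"""Raw 5-minute streams -> binary daily activity vectors -> sleep cycles.

A day is summarized as 48 half-hour slots.  The score of slot ``i`` is
the number of (sensor, 5-minute interval) activations whose timestamp
falls in ``[00:00 + 30 i, 00:00 + 30 (i + 1))`` local time; a slot is
active when its score reaches the activation threshold (default 4),
anything below is treated as noise.  A sleep cycle concatenates the
evening of one day (slots 40-47, 20:00-24:00) with the morning of the
next (slots 0-23, 00:00-12:00) into a 32-slot vector; the noon-20:00
window is disregarded.

Days with no readings at all are missing (device offline), not
all-inactive; cycles are only built from calendar-consecutive day pairs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

SLOTS_PER_DAY = 48
SLOT_MIN = 30
GRID_MIN = 5
INTERVALS_PER_SLOT = SLOT_MIN // GRID_MIN  # 6
CYCLE_SLOTS = 32
EVENING_START_SLOT = 40  # 20:00
MORNING_END_SLOT = 24  # noon

DEFAULT_THRESHOLD = 4

# default eligibility thresholds
MIN_DAYS = 300
MIN_SENSORS = 6
MAX_OCCUPANTS = 4


@dataclass
class DailyMatrix:
    """Date-ordered slot scores and binarized slots for one household."""

    household_id: str
    dates: list  # list[dt.date], strictly increasing
    scores: np.ndarray  # (n_days, 48) int
    slots: np.ndarray  # (n_days, 48) uint8

    @property
    def n_days(self) -> int:
        return len(self.dates)


def binarize(slot_scores, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Active slots: score >= threshold.  Monotone in every score."""
    scores = np.asarray(slot_scores)
    if (scores < 0).any():
        raise DataError("negative slot score")
    return (scores >= threshold).astype(np.uint8)


def check_eligibility(
    days_available: int,
    n_sensors: int | None,
    n_occupants: int | None,
    min_days: int = MIN_DAYS,
    min_sensors: int = MIN_SENSORS,
    max_occupants: int = MAX_OCCUPANTS,
) -> bool:
    """Inclusion rule: >= min_days of data, >= min_sensors, <= max_occupants.

    ``None`` for an unknown sensor or occupant count passes that check
    (metadata sidecar absent).
    """
    if days_available < 0 or (n_sensors is not None and n_sensors < 0):
        raise DataError("counts must be non-negative")
    if days_available < min_days:
        return False
    if n_sensors is not None and n_sensors < min_sensors:
        return False
    if n_occupants is not None and n_occupants > max_occupants:
        return False
    return True


def _validate_grid(ts: pd.Series) -> None:
    bad = (ts.dt.second != 0) | (ts.dt.minute % GRID_MIN != 0)
    if hasattr(ts.dt, "microsecond"):
        bad |= ts.dt.microsecond != 0
    if bad.any():
        first = ts[bad].iloc[0]
        raise FormatError(f"timestamp off the 5-minute grid: {first}")


def aggregate_to_slots(readings: pd.DataFrame) -> np.ndarray:
    """48 slot scores for one household-day of readings.

    Input needs columns ``timestamp`` (datetime, single calendar date)
    and ``motion``; readings absent from the grid score 0.
    """
    ts = pd.to_datetime(readings["timestamp"])
    _validate_grid(ts)
    if ts.dt.date.nunique() > 1:
        raise DataError("readings span more than one calendar date")
    slot = (ts.dt.hour * 60 + ts.dt.minute) // SLOT_MIN
    scores = np.zeros(SLOTS_PER_DAY, dtype=np.int64)
    active = readings["motion"].to_numpy().astype(np.int64)
    np.add.at(scores, slot.to_numpy(), active)
    return scores


def read_stream_csv(path) -> pd.DataFrame:
    """Read a long-format stream CSV; validates grid and motion values."""
    df = pd.read_csv(path, dtype={"household_id": str, "sensor_id": str})
    missing = set(("household_id", "timestamp", "sensor_id", "motion")) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from exc
    _validate_grid(df["timestamp"])
    if not df["motion"].isin((0, 1)).all():
        raise FormatError(f"{path}: motion must be 0 or 1")
    # clock-fold duplicates (repeated DST hour): keep the first occurrence
    df = df.drop_duplicates(subset=["household_id", "timestamp", "sensor_id"], keep="first")
    return df.reset_index(drop=True)


def daily_from_stream(df: pd.DataFrame, threshold: int = DEFAULT_THRESHOLD) -> dict[str, DailyMatrix]:
    """Per-household daily matrices from a (possibly multi-household) stream."""
    ts = pd.to_datetime(df["timestamp"])
    _validate_grid(ts)
    work = pd.DataFrame(
        {
            "household_id": df["household_id"],
            "date": ts.dt.date,
            "slot": (ts.dt.hour * 60 + ts.dt.minute) // SLOT_MIN,
            "motion": df["motion"].astype(np.int64),
        }
    )
    out: dict[str, DailyMatrix] = {}
    for hid, grp in work.groupby("household_id", sort=True):
        scores_by = grp.groupby(["date", "slot"])["motion"].sum()
        dates = sorted(grp["date"].unique())
        date_idx = {d: i for i, d in enumerate(dates)}
        scores = np.zeros((len(dates), SLOTS_PER_DAY), dtype=np.int64)
        for (d, s), v in scores_by.items():
            scores[date_idx[d], int(s)] = int(v)
        out[str(hid)] = DailyMatrix(
            household_id=str(hid),
            dates=dates,
            scores=scores,
            slots=binarize(scores, threshold),
        )
    return out


def daily_from_activation(
    household_id: str,
    dates,
    activation: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
) -> DailyMatrix:
    """Fast path from an (n_sensors, n_days*288) activation matrix.

    Equivalent to aggregating the long-format readings of the same
    matrix (tested property), but without materializing them.
    """
    n_days = len(dates)
    per_interval = activation.sum(axis=0)
    if per_interval.size != n_days * SLOTS_PER_DAY * INTERVALS_PER_SLOT:
        raise DataError("activation length does not match the date range")
    scores = per_interval.reshape(n_days, SLOTS_PER_DAY, INTERVALS_PER_SLOT).sum(axis=2)
    return DailyMatrix(
        household_id=household_id,
        dates=list(dates),
        scores=scores.astype(np.int64),
        slots=binarize(scores, threshold),
    )


def build_sleep_cycles(daily: DailyMatrix) -> tuple[list, np.ndarray, int]:
    """32-slot cycles for every pair of calendar-consecutive days.

    Returns ``(cycle_dates, cycles, n_gaps)`` where ``cycle_dates[i]`` is
    the day-0 date of cycle ``i`` and ``n_gaps`` counts skipped
    non-consecutive day pairs.
    """
    cycle_dates = []
    rows = []
    n_gaps = 0
    one = dt.timedelta(days=1)
    for i in range(daily.n_days - 1):
        if daily.dates[i + 1] - daily.dates[i] != one:
            n_gaps += 1
            continue
        rows.append(
            np.concatenate(
                [daily.slots[i, EVENING_START_SLOT:], daily.slots[i + 1, :MORNING_END_SLOT]]
            )
        )
        cycle_dates.append(daily.dates[i])
    cycles = np.array(rows, dtype=np.uint8).reshape(len(rows), CYCLE_SLOTS)
    return cycle_dates, cycles, n_gaps


# ---------------------------------------------------------------------------
# CSV round trips


def write_daily_csv(matrices, path) -> None:
    frames = []
    cols = [f"s{i:02d}" for i in range(SLOTS_PER_DAY)]
    for dm in matrices if not isinstance(matrices, DailyMatrix) else [matrices]:
        frame = pd.DataFrame(dm.slots, columns=cols)
        frame.insert(0, "date", [d.isoformat() for d in dm.dates])
        frame.insert(0, "household_id", dm.household_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_daily_csv(path) -> dict[str, DailyMatrix]:
    df = pd.read_csv(path, dtype={"household_id": str})
    cols = [f"s{i:02d}" for i in range(SLOTS_PER_DAY)]
    if set(cols) - set(df.columns):
        raise FormatError(f"{path}: expected slot columns s00..s47")
    out = {}
    for hid, grp in df.groupby("household_id", sort=True):
        grp = grp.sort_values("date")
        dates = [dt.date.fromisoformat(s) for s in grp["date"]]
        slots = grp[cols].to_numpy().astype(np.uint8)
        # scores unknown after binarization; store the binary slots as scores
        out[str(hid)] = DailyMatrix(str(hid), dates, slots.astype(np.int64), slots)
    return out


def write_cycles_csv(per_household: dict, path) -> None:
    """``per_household`` maps id -> (cycle_dates, cycles)."""
    cols = [f"c{i:02d}" for i in range(CYCLE_SLOTS)]
    frames = []
    for hid, (cycle_dates, cycles) in per_household.items():
        frame = pd.DataFrame(cycles, columns=cols)
        frame.insert(0, "cycle_date", [d.isoformat() for d in cycle_dates])
        frame.insert(0, "household_id", hid)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cycles_csv(path) -> dict[str, tuple[list, np.ndarray]]:
    df = pd.read_csv(path, dtype={"household_id": str})
    cols = [f"c{i:02d}" for i in range(CYCLE_SLOTS)]
    if set(cols) - set(df.columns):
        raise FormatError(f"{path}: expected cycle columns c00..c31")
    out = {}
    for hid, grp in df.groupby("household_id", sort=True):
        grp = grp.sort_values("cycle_date")
        dates = [dt.date.fromisoformat(s) for s in grp["cycle_date"]]
        out[str(hid)] = (dates, grp[cols].to_numpy().astype(np.uint8))
    return out
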