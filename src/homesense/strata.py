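"""Calendar stratification of household-days and sleep cycles.

Records are partitioned by weekday, by season, or by season x weekday.
Season boundaries are fixed calendar ranges: winter Jan 1 - Mar 21, spring
Mar 22 - Jun 21, summer Jun 22 - Sep 21, fall Sep 22 - Dec 21.  Dates from
Dec 22 through Dec 31 fall outside every range and are assigned to no
season; they are dropped from season-based schemes but kept in the
weekday scheme.

A sleep cycle spans two calendar days (evening of day 0, morning of
day 1).  Sleep time and sleep duration are attributed to day 0, wake-up
time to day 1, and time at home to the calendar day of the daily vector
itself; see :func:`attribute_cycle`.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

WEEKDAYS = (
    "monday",
    "tuesday",
    "wednesday",
    "thursday",
    "friday",
    "saturday",
    "sunday",
)
SEASONS = ("winter", "spring", "summer", "fall")
SCHEMES = ("overall", "weekday", "season", "season_weekday")

#: indicators whose cycle is attributed to day 0 vs day 1
DAY0_INDICATORS = frozenset({"sleep_time", "duration"})
DAY1_INDICATORS = frozenset({"wake_time"})

_ONE_DAY = dt.timedelta(days=1)


def assign_season(date: dt.date) -> str | None:
    """Season of ``date`` per the fixed calendar ranges, or ``None``.

    Dec 22-31 belongs to no range and returns ``None``.  Feb 29 falls
    inside Jan 1 - Mar 21 and is winter.
    """
    key = (date.month, date.day)
    if key <= (3, 21):
        return "winter"
    if key <= (6, 21):
        return "spring"
    if key <= (9, 21):
        return "summer"
    if key <= (12, 21):
        return "fall"
    return None


def weekday_name(date: dt.date) -> str:
    return WEEKDAYS[date.weekday()]


def stratum_label(date: dt.date, scheme: str) -> str | None:
    """Stratum label for ``date`` under ``scheme``; ``None`` = dropped."""
    if scheme == "overall":
        return "all"
    if scheme == "weekday":
        return weekday_name(date)
    if scheme == "season":
        return assign_season(date)
    if scheme == "season_weekday":
        season = assign_season(date)
        if season is None:
            return None
        return f"{season}:{weekday_name(date)}"
    raise ValueError(f"unknown scheme {scheme!r}")


def attribute_cycle(cycle_date: dt.date, indicator: str) -> dt.date:
    """Calendar date an indicator of the cycle dated ``cycle_date`` counts as.

    Sleep time and duration occur on day 0 (the cycle's own date); the
    wake-up time occurs on day 1, the following morning.
    """
    if indicator in DAY0_INDICATORS:
        return cycle_date
    if indicator in DAY1_INDICATORS:
        return cycle_date + _ONE_DAY
    raise ValueError(f"unknown cycle indicator {indicator!r}")


def partition(
    dates: Sequence[dt.date], scheme: str
) -> Mapping[str, list[int]]:
    """Group record indices by stratum label; unassigned dates are dropped."""
    groups: dict[str, list[int]] = defaultdict(list)
    for i, d in enumerate(dates):
        label = stratum_label(d, scheme)
        if label is not None:
            groups[label].append(i)
    return dict(groups)


def stratum_sort_key(label: str) -> tuple:
    """Canonical ordering: seasons in calendar order, weekdays Mon..Sun."""
    if ":" in label:
        season, wd = label.split(":", 1)
        return (SEASONS.index(season), WEEKDAYS.index(wd))
    if label in SEASONS:
        return (SEASONS.index(label),)
    if label in WEEKDAYS:
        return (WEEKDAYS.index(label),)
    return (99, label)


def sorted_labels(labels: Iterable[str]) -> list[str]:
    return sorted(labels, key=stratum_sort_key)
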