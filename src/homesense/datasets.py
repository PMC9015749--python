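"""Bundled reference summary tables.

Published per-stratum descriptive statistics (group size, mean, sample
SD) for the four household indicators, stratified by season and by
weekday.  Clock-time means are stored as minutes after midnight (a sleep
time of 10:26 PM is 1346); sleep duration and time at home are minutes
per day.  These tables are the input to the summary-statistics route of
the inferential layer and to the validation suite: the ANOVA F values
and Tukey-Kramer q statistics of the original analysis are recomputed
from them at run time.
"""

from __future__ import annotations

from .stats import GroupSummary

INDICATORS = ("sleep_time", "wake_time", "sleep_duration", "time_at_home")

# season -> (n, mean_minutes, sd_minutes); seasons in calendar order
_SEASONAL = {
    "sleep_time": {
        "winter": (466, 22 * 60 + 35, 107.11),
        "spring": (461, 22 * 60 + 32, 98.5),
        "summer": (455, 22 * 60 + 32, 108.37),
        "fall": (461, 22 * 60 + 25, 89.12),
    },
    "wake_time": {
        "winter": (466, 6 * 60 + 26, 102.75),
        "spring": (461, 6 * 60 + 22, 93.05),
        "summer": (455, 6 * 60 + 31, 84.75),
        "fall": (461, 6 * 60 + 26, 88.36),
    },
    "sleep_duration": {
        "winter": (466, 465.05, 110.65),
        "spring": (461, 466.54, 106.23),
        "summer": (455, 472.54, 109.59),
        "fall": (461, 477.83, 106.2),
    },
    "time_at_home": {
        "winter": (466, 546.43, 235.53),
        "spring": (461, 523.13, 227.56),
        "summer": (455, 486.58, 237.4),
        "fall": (461, 529.39, 226.42),
    },
}

# weekday -> (n, mean_minutes, sd_minutes); Monday..Sunday
_WEEKDAY = {
    "sleep_time": {
        "monday": (463, 22 * 60 + 26, 81.3),
        "tuesday": (459, 22 * 60 + 35, 94.53),
        "wednesday": (458, 22 * 60 + 31, 86.22),
        "thursday": (460, 22 * 60 + 33, 99.67),
        "friday": (463, 22 * 60 + 54, 89.2),
        "saturday": (464, 23 * 60 + 3, 104.04),
        "sunday": (466, 22 * 60 + 36, 85.27),
    },
    "wake_time": {
        "monday": (463, 6 * 60 + 6, 70.6),
        "tuesday": (459, 5 * 60 + 54, 74.22),
        "wednesday": (458, 6 * 60 + 3, 73.7),
        "thursday": (460, 6 * 60 + 4, 84.86),
        "friday": (463, 6 * 60 + 5, 72.76),
        "saturday": (464, 7 * 60 + 0, 101.23),
        "sunday": (466, 7 * 60 + 8, 79.51),
    },
    "sleep_duration": {
        "monday": (463, 449.1, 95.83),
        "tuesday": (459, 447.76, 97.47),
        "wednesday": (458, 449.88, 92.13),
        "thursday": (460, 449.73, 96.21),
        "friday": (463, 477.99, 110.99),
        "saturday": (464, 483.25, 111.16),
        "sunday": (466, 450.18, 89.15),
    },
    "time_at_home": {
        "monday": (463, 516.47, 216.85),
        "tuesday": (459, 486.14, 215.28),
        "wednesday": (458, 503.46, 219.69),
        "thursday": (460, 482.41, 213.16),
        "friday": (463, 498.95, 223.06),
        "saturday": (462, 533.51, 215.45),
        "sunday": (466, 576.27, 220.66),
    },
}


def _build(table: dict[str, tuple[int, float, float]]) -> list[GroupSummary]:
    return [GroupSummary(label, n, float(mean), float(sd)) for label, (n, mean, sd) in table.items()]


def seasonal_summaries(indicator: str) -> list[GroupSummary]:
    """Per-season (n, mean, sd) summaries for one indicator."""
    if indicator not in _SEASONAL:
        raise KeyError(f"unknown indicator {indicator!r}; one of {INDICATORS}")
    return _build(_SEASONAL[indicator])


def weekday_summaries(indicator: str) -> list[GroupSummary]:
    """Per-weekday (n, mean, sd) summaries for one indicator."""
    if indicator not in _WEEKDAY:
        raise KeyError(f"unknown indicator {indicator!r}; one of {INDICATORS}")
    return _build(_WEEKDAY[indicator])
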