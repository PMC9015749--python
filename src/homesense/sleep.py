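"""Sleep indicators from clustered 32-slot sleep-cycle vectors.

Times live on a 20:00-anchored axis: minute 0 is 20:00 of day 0 and
minute 960 is noon of day 1.  Within a cluster pattern the sleep block
is the longest maximal run of inactive slots that is terminated by a
subsequent activation — the deactivation marks the sleep time, the
activation the wake-up time.  A run still open at the end of the window
has no wake-up and the pattern is invalid (household likely away).
Household-level indicators are weighted averages over valid cluster
patterns, weights renormalized after dropping invalid ones.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from datetime import timedelta

import numpy as np

from .clustering import ClusterPattern, cluster_patterns, fit_vector_clusters
from .errors import DataError
from .preprocess import CYCLE_SLOTS, SLOT_MIN
from .strata import stratum_label

#: minutes on the anchored axis per cycle window
CYCLE_SPAN_MIN = CYCLE_SLOTS * SLOT_MIN  # 960
#: anchored-axis offset of midnight (20:00 -> 24:00)
MIDNIGHT_OFFSET_MIN = 4 * 60

DEFAULT_K_MAX = 6
DEFAULT_MIN_CYCLES = 10


@dataclass(frozen=True)
class SleepIndicators:
    """Sleep time, wake-up time (anchored minutes) and duration (minutes)."""

    sleep_time: float
    wake_time: float
    duration: float


def fit_cycle_clusters(
    cycles: np.ndarray,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    min_cycles: int = DEFAULT_MIN_CYCLES,
):
    """BIC-selected Gaussian mixture over 32-slot cycle vectors.

    ``None`` signals too few cycles; the household is excluded from the
    stratum rather than raising.
    """
    cycles = np.asarray(cycles)
    if cycles.ndim != 2 or cycles.shape[1] != CYCLE_SLOTS:
        raise DataError(f"cycles must be (n, {CYCLE_SLOTS})")
    return fit_vector_clusters(cycles, k_max=k_max, seed=seed, min_records=min_cycles)


def detect_sleep_interval(pattern) -> SleepIndicators | None:
    """Longest terminated inactive run of a 32-slot pattern.

    Among maximal runs of consecutive inactive slots that are followed
    by at least one active slot, the longest wins (ties: earliest
    start).  Sleep time is the run's first slot, wake-up the first
    active slot after it, both as minutes on the anchored axis.  Returns
    ``None`` when no qualifying run exists (all active, all inactive, or
    only a trailing unterminated run).
    """
    slots = np.asarray(pattern).ravel()
    if slots.size != CYCLE_SLOTS:
        raise DataError(f"pattern must have {CYCLE_SLOTS} slots, got {slots.size}")
    best_start, best_len = -1, 0
    run_start = None
    for j in range(CYCLE_SLOTS):
        if slots[j] == 0:
            if run_start is None:
                run_start = j
        else:
            if run_start is not None:
                length = j - run_start
                if length > best_len:  # strict: ties keep the earliest run
                    best_start, best_len = run_start, length
                run_start = None
    # a run still open at slot 31 has no terminating activation: ignored
    if best_len == 0:
        return None
    sleep = SLOT_MIN * best_start
    wake = SLOT_MIN * (best_start + best_len)
    return SleepIndicators(float(sleep), float(wake), float(wake - sleep))


def weighted_indicators(
    items: list[tuple[SleepIndicators | None, float]],
) -> SleepIndicators | None:
    """Weight-renormalized average over valid cluster indicators.

    ``items`` pairs each cluster's indicators (``None`` if invalid) with
    its weight.  Returns ``None`` when no cluster is valid.
    """
    valid = [(ind, w) for ind, w in items if ind is not None]
    total = sum(w for _, w in valid)
    if not valid or total <= 0:
        return None
    sleep = sum(ind.sleep_time * w for ind, w in valid) / total
    wake = sum(ind.wake_time * w for ind, w in valid) / total
    return SleepIndicators(sleep, wake, wake - sleep)


def pattern_indicators(patterns: list[ClusterPattern]) -> SleepIndicators | None:
    """Detect-and-average over a household-stratum's cluster patterns."""
    return weighted_indicators([(detect_sleep_interval(p.slots), p.weight) for p in patterns])


def sleep_time_clock_min(anchored: float) -> float:
    """Anchored minutes -> minutes after midnight of day 0 (may exceed 1440)."""
    return anchored + 20 * 60


def wake_time_clock_min(anchored: float) -> float:
    """Anchored minutes -> minutes after midnight of day 1."""
    return anchored - MIDNIGHT_OFFSET_MIN


def household_sleep_rows(
    household_id: str,
    cycle_dates,
    cycles: np.ndarray,
    scheme: str,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    min_cycles: int = DEFAULT_MIN_CYCLES,
) -> tuple[list[dict], list[str]]:
    """Per-stratum weighted sleep indicators for one household.

    Sleep time and duration are stratified by the cycle's own (day 0)
    date; wake-up time by the following (day 1) date.  Each stratum's
    cycle subset is clustered separately; fits are cached so the two
    attributions reuse a fit when their subsets coincide.
    """
    one = timedelta(days=1)
    groups_day0: dict[str, list[int]] = defaultdict(list)
    groups_day1: dict[str, list[int]] = defaultdict(list)
    for i, d in enumerate(cycle_dates):
        lab0 = stratum_label(d, scheme)
        lab1 = stratum_label(d + one, scheme)
        if lab0 is not None:
            groups_day0[lab0].append(i)
        if lab1 is not None:
            groups_day1[lab1].append(i)

    fit_cache: dict[tuple, list[ClusterPattern] | None] = {}

    def patterns_for(indices: list[int]) -> list[ClusterPattern] | None:
        key = tuple(indices)
        if key not in fit_cache:
            sub = cycles[list(indices)]
            model = fit_cycle_clusters(sub, k_max=k_max, seed=seed, min_cycles=min_cycles)
            fit_cache[key] = None if model is None else cluster_patterns(sub, model)
        return fit_cache[key]

    rows: list[dict] = []
    log: list[str] = []
    for indicator, groups in (("sleep", groups_day0), ("wake", groups_day1)):
        for stratum, indices in groups.items():
            patterns = patterns_for(indices)
            if patterns is None:
                log.append(
                    f"household={household_id} stratum={stratum} indicator={indicator} "
                    f"status=excluded reason=insufficient_cycles n={len(indices)}"
                )
                continue
            result = pattern_indicators(patterns)
            if result is None:
                log.append(
                    f"household={household_id} stratum={stratum} indicator={indicator} "
                    f"status=excluded reason=no_valid_pattern"
                )
                continue
            if indicator == "sleep":
                rows.append(
                    {"household_id": household_id, "stratum": stratum, "indicator": "sleep_time", "value": result.sleep_time}
                )
                rows.append(
                    {"household_id": household_id, "stratum": stratum, "indicator": "duration", "value": result.duration}
                )
            else:
                rows.append(
                    {"household_id": household_id, "stratum": stratum, "indicator": "wake_time", "value": result.wake_time}
                )
    return rows, log
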