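"""Daily time spent at home from clustered 48-slot daily vectors.

Uses the same cluster-then-pattern machinery as sleep inference, on the
full-day vectors.  A cluster pattern's value is 30 minutes per active
slot — sensor-observed active time at home, which deliberately excludes
the (sensor-inactive) sleeping hours; household values are the weighted
average over cluster patterns.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .clustering import ClusterPattern, cluster_patterns, fit_vector_clusters
from .errors import DataError
from .preprocess import SLOTS_PER_DAY, SLOT_MIN
from .sleep import DEFAULT_K_MAX, DEFAULT_MIN_CYCLES
from .strata import stratum_label


def fit_daily_clusters(
    daily_vectors: np.ndarray,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    min_days: int = DEFAULT_MIN_CYCLES,
):
    """BIC-selected mixture on 48-slot daily vectors (``None`` = too few)."""
    daily_vectors = np.asarray(daily_vectors)
    if daily_vectors.ndim != 2 or daily_vectors.shape[1] != SLOTS_PER_DAY:
        raise DataError(f"daily vectors must be (n, {SLOTS_PER_DAY})")
    return fit_vector_clusters(daily_vectors, k_max=k_max, seed=seed, min_records=min_days)


def time_at_home(pattern) -> float:
    """Minutes at home of one 48-slot pattern: 30 x active slot count."""
    slots = np.asarray(pattern).ravel()
    if slots.size != SLOTS_PER_DAY:
        raise DataError(f"pattern must have {SLOTS_PER_DAY} slots, got {slots.size}")
    return float(SLOT_MIN * int((slots != 0).sum()))


def weighted_home_time(patterns: list[ClusterPattern]) -> float:
    """Weight-renormalized mean of per-cluster minutes at home."""
    if not patterns:
        raise DataError("need >= 1 cluster pattern")
    total = sum(p.weight for p in patterns)
    return sum(time_at_home(p.slots) * p.weight for p in patterns) / total


def household_home_rows(
    household_id: str,
    dates,
    daily_slots: np.ndarray,
    scheme: str,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    min_days: int = DEFAULT_MIN_CYCLES,
) -> tuple[list[dict], list[str]]:
    """Per-stratum weighted minutes at home for one household.

    Days are stratified by their own calendar date.
    """
    groups: dict[str, list[int]] = defaultdict(list)
    for i, d in enumerate(dates):
        lab = stratum_label(d, scheme)
        if lab is not None:
            groups[lab].append(i)
    rows: list[dict] = []
    log: list[str] = []
    for stratum, indices in groups.items():
        sub = daily_slots[indices]
        model = fit_daily_clusters(sub, k_max=k_max, seed=seed, min_days=min_days)
        if model is None:
            log.append(
                f"household={household_id} stratum={stratum} indicator=home "
                f"status=excluded reason=insufficient_days n={len(indices)}"
            )
            continue
        minutes = weighted_home_time(cluster_patterns(sub, model))
        rows.append(
            {
                "household_id": household_id,
                "stratum": stratum,
                "indicator": "minutes_at_home",
                "value": minutes,
            }
        )
    return rows, log
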