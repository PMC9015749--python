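"""Independent oracles shared across test modules."""

import numpy as np


def oracle_sleep_interval(slots):
    """O(n^2) enumeration of all maximal terminated inactive runs.

    Returns (sleep, wake, duration) in minutes, or None when no inactive
    run is followed by an activation.
    """
    n = len(slots)
    candidates = []
    for start in range(n):
        if slots[start] != 0 or (start > 0 and slots[start - 1] == 0):
            continue  # not the beginning of a maximal run
        end = start
        while end + 1 < n and slots[end + 1] == 0:
            end += 1
        if end + 1 < n and slots[end + 1] == 1:  # terminated by an activation
            candidates.append((start, end - start + 1))
    if not candidates:
        return None
    best_start, best_len = max(candidates, key=lambda c: (c[1], -c[0]))
    return 30.0 * best_start, 30.0 * (best_start + best_len), 30.0 * best_len


def realize_summary(n: int, mean: float, sd: float, rng) -> np.ndarray:
    """Raw values with exactly the requested n, mean and sample SD."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
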