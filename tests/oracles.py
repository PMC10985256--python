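"""Independent reference implementations used only as test oracles.

These are deliberately written with different algorithmic structure from the
package (interval enumeration with prefix sums, plain per-epoch Python
loops, run-length encoding via groupby) so agreement is informative.
"""

from __future__ import annotations

import math
from itertools import groupby

import numpy as np


def choi_wear_oracle(
    counts: np.ndarray, window: int = 90, tol: int = 2, flank: int = 30
) -> np.ndarray:
    """Brute-force non-wear scan: enumerate all candidate intervals.

    An epoch is non-wear iff it lies in some interval [i, j] (both zero
    epochs) of length >= ``window`` containing at most ``tol`` non-zero
    epochs, all of which sit in spike runs flanked on both sides by >=
    ``flank`` consecutive zero epochs.  Returns wear flags (True = worn).
    """
    counts = np.asarray(counts)
    n = counts.size
    zero = counts == 0
    nz = ~zero

    # per-epoch flag: non-zero epoch belongs to an adequately flanked spike
    flanked = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if nz[i]:
            j = i
            while j < n and nz[j]:
                j += 1
            before = i >= flank and bool(zero[i - flank : i].all())
            after = j + flank <= n and bool(zero[j : j + flank].all())
            if before and after:
                flanked[i:j] = True
            i = j
        else:
            i += 1

    nz_cum = np.concatenate([[0], np.cumsum(nz)])
    bad_cum = np.concatenate([[0], np.cumsum(nz & ~flanked)])
    nonwear = np.zeros(n, dtype=bool)
    zero_idx = np.flatnonzero(zero)
    for i in zero_idx:
        ends = zero_idx[zero_idx >= i + window - 1]
        if ends.size == 0:
            continue
        good = (bad_cum[ends + 1] - bad_cum[i] == 0) & (nz_cum[ends + 1] - nz_cum[i] <= tol)
        if good.any():
            nonwear[i : ends[good].max() + 1] = True
    return ~nonwear


def windowed_sums_oracle(values: np.ndarray, width: int) -> np.ndarray:
    """Plain-loop windowed sums for aggregation checks."""
    values = np.asarray(values)
    out = []
    for start in range(0, values.size, width):
        out.append(int(sum(int(v) for v in values[start : start + width])))
    return np.array(out, dtype=np.int64)


def day_summary_oracle(
    axis1, axis2, axis3, steps, wear,
    sed_max=99, light_max=1951, moderate_max=5724,
    min_wear_minutes=480, bout_min=10,
):
    """Per-epoch tally of all measures for a 60-s series starting at local
    midnight: valid days, intensity percentages, VM3, MET rate, steps/min
    and strict (zero-tolerance) bout count.

    Returns a dict, or None when no epoch survives the wear-day rule.
    """
    n = len(axis1)
    day_of = [i // 1440 for i in range(n)]
    wear_minutes: dict[int, int] = {}
    for i in range(n):
        if wear[i]:
            wear_minutes[day_of[i]] = wear_minutes.get(day_of[i], 0) + 1
    valid = {d for d, m in wear_minutes.items() if m >= min_wear_minutes}

    counts = {"sed": 0, "light": 0, "mvpa": 0}
    vm_sum = 0.0
    met_sum = 0.0
    step_sum = 0
    n_mask = 0
    mvpa_run = 0
    bouts = 0
    for i in range(n):
        in_mask = wear[i] and day_of[i] in valid
        cpm = axis1[i]
        is_mvpa = in_mask and cpm > light_max
        if is_mvpa:
            mvpa_run += 1
        else:
            if mvpa_run >= bout_min:
                bouts += 1
            mvpa_run = 0
        if not in_mask:
            continue
        n_mask += 1
        if cpm <= sed_max:
            counts["sed"] += 1
        elif cpm <= light_max:
            counts["light"] += 1
        else:
            counts["mvpa"] += 1
        vm_sum += math.sqrt(axis1[i] ** 2 + axis2[i] ** 2 + axis3[i] ** 2)
        met_sum += 1.439008 + 0.000795 * cpm if cpm > light_max else 1.0
        step_sum += steps[i]
    if mvpa_run >= bout_min:
        bouts += 1
    if n_mask == 0:
        return None
    return {
        "pct_sedentary": 100.0 * counts["sed"] / n_mask,
        "pct_light": 100.0 * counts["light"] / n_mask,
        "pct_mvpa": 100.0 * counts["mvpa"] / n_mask,
        "vm3": vm_sum / n_mask,
        "met_rate": met_sum / n_mask,
        "steps_per_min": step_sum / n_mask,
        "n_bouts": bouts,
        "wear_minutes": n_mask,
    }


def bout_count_rle(flags) -> int:
    """Strict bout count: runs of True of length >= 10 via run-length encoding."""
    return sum(1 for val, grp in groupby(flags) if val and sum(1 for _ in grp) >= 10)
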