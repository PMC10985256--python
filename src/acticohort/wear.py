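"""Non-wear detection and wear-day validation.

Non-wear is flagged with the Choi count-based algorithm: an epoch is
non-wear iff it lies inside an interval of at least ``min_nonwear_window``
minutes that starts and ends on zero-count epochs, contains at most
``spike_tolerance`` minutes of non-zero counts, and in which every non-zero
spike is flanked on both sides by at least ``spike_flank_window`` minutes of
consecutive zero counts.  The published defaults (90 / 2 / 30 min on the
vertical axis) are used; runs are evaluated on the whole recording and may
span midnight, flags are only afterwards cut into calendar days.

A self-reported wear diary can only *remove* wear time (force epochs outside
the reported worn intervals to non-wear), never add it back.  Days with less
than ``min_wear_hours`` (default 8 h) of wear are excluded from analysis.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np

from .epochs import DiaryLog, EpochSeries

__all__ = [
    "ChoiParams",
    "WearDaySet",
    "detect_nonwear_choi",
    "apply_diary_correction",
    "valid_wear_days",
    "flag_wear",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChoiParams:
    """Parameters of the zero-run non-wear classifier (minutes)."""

    min_nonwear_window: int = 90
    spike_tolerance: int = 2
    spike_flank_window: int = 30
    axis: str = "axis1"

    def __post_init__(self) -> None:
        if min(self.min_nonwear_window, self.spike_tolerance, self.spike_flank_window) <= 0:
            raise ValueError("all Choi windows must be positive")
        if self.spike_tolerance >= self.min_nonwear_window:
            raise ValueError("spike_tolerance must be smaller than the non-wear window")
        if self.axis not in ("axis1", "vector_magnitude"):
            raise ValueError(f"unknown axis {self.axis!r}")


def _choi_counts(series: EpochSeries, params: ChoiParams) -> np.ndarray:
    if params.axis == "axis1":
        return series.axis1.astype(float)
    return series.vector_magnitude()


def detect_nonwear_choi(series: EpochSeries, params: ChoiParams | None = None) -> np.ndarray:
    """Return per-epoch wear flags (``True`` = worn) for a 60-s epoch series.

    A series shorter than one non-wear window is returned all-wear with a
    logged warning.
    """
    params = params or ChoiParams()
    if series.epoch_length != 60:
        raise ValueError("Choi non-wear detection expects 60-s epochs")
    n = len(series)
    window = params.min_nonwear_window
    if n < window:
        logger.warning(
            "series %s shorter than one non-wear window (%d < %d min); flagged all-wear",
            series.subject_id, n, window,
        )
        return np.ones(n, dtype=bool)

    counts = _choi_counts(series, params)
    zero = counts == 0
    nonzero = ~zero

    # Maximal runs of non-zero epochs, and whether each is an absorbable
    # spike: flanked on both sides by >= spike_flank_window zero epochs.
    padded = np.concatenate(([False], nonzero, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    zpad = np.concatenate(([False], zero, [False]))
    zstarts = np.flatnonzero(zpad[1:] & ~zpad[:-1])
    zends = np.flatnonzero(~zpad[1:] & zpad[:-1])
    zero_run_len_ending_at = {e: e - s for s, e in zip(zstarts, zends)}
    zero_run_len_starting_at = {s: e - s for s, e in zip(zstarts, zends)}

    absorbable = np.zeros(n, dtype=bool)
    flank = params.spike_flank_window
    for s, e in zip(starts, ends):
        before = zero_run_len_ending_at.get(s, 0)
        after = zero_run_len_starting_at.get(e, 0)
        if before >= flank and after >= flank:
            absorbable[s:e] = True
    bad = nonzero & ~absorbable

    # For every zero epoch i, the furthest zero epoch j such that [i, j]
    # contains no non-absorbable spike and at most spike_tolerance non-zero
    # epochs.  Both limits are monotone in i, so searchsorted suffices.
    zero_idx = np.flatnonzero(zero)
    bad_idx = np.flatnonzero(bad)
    nz_idx = np.flatnonzero(nonzero)

    def _next_index(idx_arr: np.ndarray, pos: np.ndarray) -> np.ndarray:
        if idx_arr.size == 0:
            return np.full(pos.shape, n, dtype=np.int64)
        clipped = np.clip(pos, 0, idx_arr.size - 1)
        return np.where(pos < idx_arr.size, idx_arr[clipped], n)

    bad_bound = _next_index(bad_idx, np.searchsorted(bad_idx, zero_idx))
    tol_bound = _next_index(nz_idx, np.searchsorted(nz_idx, zero_idx) + params.spike_tolerance)
    j_limit = np.minimum(bad_bound, tol_bound) - 1  # inclusive epoch bound

    # largest zero index <= j_limit
    jmax = zero_idx[np.searchsorted(zero_idx, j_limit, side="right") - 1]
    qualifies = (jmax - zero_idx + 1) >= window

    nonwear = np.zeros(n, dtype=bool)
    if qualifies.any():
        # union of qualifying intervals via a difference array
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, zero_idx[qualifies], 1)
        np.add.at(diff, jmax[qualifies] + 1, -1)
        nonwear = np.cumsum(diff[:-1]) > 0
    return ~nonwear


def apply_diary_correction(
    series: EpochSeries, flags: np.ndarray, diary: DiaryLog | None
) -> np.ndarray:
    """Intersect algorithmic wear flags with diary-reported worn intervals.

    Epochs outside the diary's worn intervals are forced to non-wear; inside
    them the algorithmic flags are kept unchanged.  ``diary=None`` leaves the
    flags untouched.  The operation is idempotent and never adds wear time.
    """
    flags = np.asarray(flags, dtype=bool)
    if diary is None:
        return flags.copy()
    return flags & diary.worn_mask(series.timestamps)


@dataclass
class WearDaySet:
    """Per-calendar-day wear minutes and the valid-day rule outcome."""

    wear_minutes: dict[dt.date, float]
    min_wear_hours: float = 8.0

    def is_valid(self, day: dt.date) -> bool:
        return self.wear_minutes.get(day, 0.0) >= self.min_wear_hours * 60.0

    @property
    def valid_days(self) -> list[dt.date]:
        return sorted(d for d in self.wear_minutes if self.is_valid(d))

    @property
    def n_valid(self) -> int:
        return len(self.valid_days)

    @property
    def total_wear_minutes(self) -> float:
        return float(sum(self.wear_minutes[d] for d in self.valid_days))


def valid_wear_days(
    series: EpochSeries, min_wear_hours: float = 8.0, flags: np.ndarray | None = None
) -> WearDaySet:
    """Tally wear minutes per calendar day and apply the minimum-wear rule.

    ``flags`` defaults to ``series.wear`` (which must then be present).  A
    day is valid iff its wear time is at least ``min_wear_hours`` (>=, so an
    exact 8-h day counts).
    """
    if flags is None:
        flags = series.wear
    if flags is None:
        raise ValueError("wear flags absent: run detect_nonwear_choi first")
    flags = np.asarray(flags, dtype=bool)
    minutes_per_epoch = series.epoch_length / 60.0
    days = series.timestamps.date
    tally: dict[dt.date, float] = {}
    for day, worn in zip(days, flags):
        tally[day] = tally.get(day, 0.0) + (minutes_per_epoch if worn else 0.0)
    return WearDaySet(tally, float(min_wear_hours))


def flag_wear(
    series: EpochSeries,
    params: ChoiParams | None = None,
    diary: DiaryLog | None = None,
) -> EpochSeries:
    """Convenience wrapper: Choi detection + diary correction, returning a
    copy of the series with its ``wear`` attribute populated."""
    flags = detect_nonwear_choi(series, params)
    flags = apply_diary_correction(series, flags, diary)
    return series.with_wear(flags)
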