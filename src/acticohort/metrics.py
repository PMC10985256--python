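"""The seven digital activity measures computed over valid wear time.

All measures share one analysis mask: epochs that are flagged as worn *and*
fall on a valid wear day (>= 8 h wear by default).  Intensity is classified
from vertical-axis (axis1) counts per minute with the Freedson adult
cut-points (sedentary <= 99 CPM, light 100-1951, moderate 1952-5724,
vigorous >= 5725); the same cut-points are applied at waist and wrist, and
wrist values are interpreted per placement rather than pooled.

Energy expenditure is summarized as a MET rate: epochs above the moderate
threshold use the Freedson walking/running regression
``METs = 1.439008 + 0.000795 x CPM`` and all lighter epochs are floored at
the 1-MET resting rate (1 MET = 3.5 mL O2 / kg / min).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .epochs import EpochSeries
from .wear import valid_wear_days

__all__ = [
    "CutPoints",
    "IntensityLevel",
    "ActivitySummary",
    "MEASURES",
    "classify_intensity",
    "activity_percentages",
    "vm3_mean",
    "met_rate",
    "count_bouts",
    "steps_per_minute",
    "summarize_subject",
]

#: Canonical measure names, in reporting order.
MEASURES = (
    "met_rate",
    "n_bouts",
    "pct_sedentary",
    "pct_light",
    "pct_mvpa",
    "vm3",
    "steps_per_min",
)

MET_INTERCEPT = 1.439008
MET_SLOPE = 0.000795
MET_FLOOR = 1.0


class IntensityLevel(IntEnum):
    SEDENTARY = 0
    LIGHT = 1
    MODERATE = 2
    VIGOROUS = 3


@dataclass(frozen=True)
class CutPoints:
    """Vertical-axis CPM thresholds; bins are ``[0, sed]``, ``(sed, light]``,
    ``(light, moderate]``, ``(moderate, inf)``."""

    sedentary_max: float = 99.0
    light_max: float = 1951.0
    moderate_max: float = 5724.0

    def __post_init__(self) -> None:
        if not (0 <= self.sedentary_max < self.light_max < self.moderate_max):
            raise ValueError("cut-points must be strictly increasing")


FREEDSON_ADULT = CutPoints()


def classify_intensity(cpm_axis1, cutpoints: CutPoints = FREEDSON_ADULT) -> np.ndarray:
    """Classify vertical-axis CPM values into intensity levels (vectorized).

    Returns an integer array of :class:`IntensityLevel` codes (scalar input
    gives a scalar level).
    """
    cpm = np.asarray(cpm_axis1, dtype=float)
    if cpm.size and np.min(cpm) < 0:
        raise ValueError("CPM values must be non-negative")
    codes = (
        (cpm > cutpoints.sedentary_max).astype(np.int8)
        + (cpm > cutpoints.light_max)
        + (cpm > cutpoints.moderate_max)
    )
    if np.isscalar(cpm_axis1):
        return IntensityLevel(int(codes))
    return codes


def _cpm(series: EpochSeries) -> np.ndarray:
    """Per-epoch counts expressed per minute (epochs are usually 60 s)."""
    return series.axis1.astype(float) * (60.0 / series.epoch_length)


def analysis_mask(
    series: EpochSeries,
    min_wear_hours: float = 8.0,
    day_filter: set[dt.date] | None = None,
) -> np.ndarray:
    """Boolean mask of epochs entering the measures: worn, on a valid day,
    optionally restricted to a subset of calendar days."""
    if series.wear is None:
        raise ValueError("wear flags absent: run wear detection first")
    wds = valid_wear_days(series, min_wear_hours)
    keep_days = set(wds.valid_days)
    if day_filter is not None:
        keep_days &= set(day_filter)
    days = series.timestamps.date
    in_day = np.fromiter((d in keep_days for d in days), dtype=bool, count=len(series))
    return series.wear & in_day


def _require_mask(mask: np.ndarray) -> None:
    if not mask.any():
        raise ValueError("no valid wear epochs: measures are undefined")


def activity_percentages(
    series: EpochSeries,
    cutpoints: CutPoints = FREEDSON_ADULT,
    mask: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Percentages of wear time in sedentary, light and MVPA intensity.

    Moderate and vigorous epochs are pooled into MVPA; the three percentages
    sum to 100 exactly (denominator = wear epochs of valid days).
    """
    mask = analysis_mask(series) if mask is None else mask
    _require_mask(mask)
    levels = classify_intensity(_cpm(series)[mask], cutpoints)
    n = levels.size
    pct_sed = 100.0 * np.count_nonzero(levels == IntensityLevel.SEDENTARY) / n
    pct_light = 100.0 * np.count_nonzero(levels == IntensityLevel.LIGHT) / n
    pct_mvpa = 100.0 * np.count_nonzero(levels >= IntensityLevel.MODERATE) / n
    return pct_sed, pct_light, pct_mvpa


def vm3_mean(series: EpochSeries, mask: np.ndarray | None = None) -> float:
    """Mean over wear epochs of the 3-axis vector magnitude, in CPM."""
    mask = analysis_mask(series) if mask is None else mask
    _require_mask(mask)
    vm = series.vector_magnitude() * (60.0 / series.epoch_length)
    return float(vm[mask].mean())


def met_rate(
    series: EpochSeries,
    cutpoints: CutPoints = FREEDSON_ADULT,
    mask: np.ndarray | None = None,
) -> float:
    """Mean per-epoch MET estimate over wear time.

    Epochs at or below the light/moderate boundary contribute the 1-MET
    resting floor; above it the count regression applies, so the summary is
    always >= 1 and non-decreasing in axis1 counts.
    """
    mask = analysis_mask(series) if mask is None else mask
    _require_mask(mask)
    cpm = _cpm(series)[mask]
    mets = np.where(cpm > cutpoints.light_max, MET_INTERCEPT + MET_SLOPE * cpm, MET_FLOOR)
    return float(mets.mean())


def count_bouts(
    series: EpochSeries,
    cutpoints: CutPoints = FREEDSON_ADULT,
    min_duration: int = 10,
    drop_tolerance: int = 0,
    mask: np.ndarray | None = None,
) -> int:
    """Number of sustained moderate-or-vigorous activity bouts.

    A bout is a maximal run of consecutive wear epochs at moderate-or-higher
    intensity lasting at least ``min_duration`` minutes.  With
    ``drop_tolerance`` > 0, up to that many sub-threshold wear minutes may be
    absorbed inside a bout without splitting it (the absorbed minutes count
    toward the bout's duration); excluded epochs always split.
    """
    if series.epoch_length != 60:
        raise ValueError("bout counting expects 60-s epochs")
    mask = analysis_mask(series) if mask is None else mask
    levels = classify_intensity(_cpm(series), cutpoints)
    mvpa = (levels >= IntensityLevel.MODERATE) & mask

    n_bouts = 0
    i, n = 0, len(series)
    while i < n:
        if not mvpa[i]:
            i += 1
            continue
        # start of a candidate bout at i
        length = 0
        budget = drop_tolerance
        j = i
        last_mvpa = i
        while j < n:
            if mvpa[j]:
                last_mvpa = j
                j += 1
                continue
            if not mask[j]:
                break  # non-wear / invalid day: hard break
            # sub-threshold wear gap: absorb if a further in-bout MVPA epoch
            # exists within the remaining budget
            g = j
            while g < n and mask[g] and not mvpa[g]:
                g += 1
            gap = g - j
            if g < n and mvpa[g] and gap <= budget:
                budget -= gap
                j = g
            else:
                break
        length = last_mvpa - i + 1
        if length >= min_duration:
            n_bouts += 1
        i = max(j, last_mvpa + 1)
    return n_bouts


def steps_per_minute(series: EpochSeries, mask: np.ndarray | None = None) -> float:
    """Total steps divided by total wear minutes over valid days."""
    mask = analysis_mask(series) if mask is None else mask
    _require_mask(mask)
    wear_minutes = mask.sum() * series.epoch_length / 60.0
    return float(series.steps[mask].sum() / wear_minutes)


@dataclass
class ActivitySummary:
    """The seven digital measures plus wear bookkeeping for one series."""

    subject_id: str
    placement: str
    visit: str
    met_rate: float
    n_bouts: int
    pct_sedentary: float
    pct_light: float
    pct_mvpa: float
    vm3: float
    steps_per_min: float
    wear_days: int
    wear_minutes: float

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "placement": self.placement,
            "visit": self.visit,
            **{m: getattr(self, m) for m in MEASURES},
            "wear_days": self.wear_days,
            "wear_minutes": self.wear_minutes,
        }

    def __getitem__(self, measure: str) -> float:
        if measure not in MEASURES:
            raise KeyError(measure)
        return getattr(self, measure)


def summarize_subject(
    series: EpochSeries,
    cutpoints: CutPoints = FREEDSON_ADULT,
    min_wear_hours: float = 8.0,
    bout_min_duration: int = 10,
    bout_drop_tolerance: int = 0,
    day_filter: set[dt.date] | None = None,
) -> ActivitySummary:
    """Compute all seven measures from one shared wear mask.

    ``day_filter`` restricts the valid days entering the summary (used for
    odd/even weekday reliability splits).
    """
    mask = analysis_mask(series, min_wear_hours, day_filter)
    _require_mask(mask)
    wds = valid_wear_days(series, min_wear_hours)
    days = wds.valid_days if day_filter is None else sorted(set(wds.valid_days) & set(day_filter))
    pct_sed, pct_light, pct_mvpa = activity_percentages(series, cutpoints, mask=mask)
    return ActivitySummary(
        subject_id=series.subject_id,
        placement=series.placement,
        visit=series.visit,
        met_rate=met_rate(series, cutpoints, mask=mask),
        n_bouts=count_bouts(series, cutpoints, bout_min_duration, bout_drop_tolerance, mask=mask),
        pct_sedentary=pct_sed,
        pct_light=pct_light,
        pct_mvpa=pct_mvpa,
        vm3=vm3_mean(series, mask=mask),
        steps_per_min=steps_per_minute(series, mask=mask),
        wear_days=len(days),
        wear_minutes=float(mask.sum() * series.epoch_length / 60.0),
    )
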