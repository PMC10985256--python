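"""Epoch-level activity-count containers and plain-text file I/O.

The interchange unit is an :class:`EpochSeries`: one subject x placement x
visit recording of triaxial accelerometer counts summarized into fixed-length
epochs (60 s by default), plus device-estimated steps.  Files are plain CSV
with a small ``Key: value`` metadata header block, modelled on ActiLife CSV
exports; binary device containers are deliberately unsupported.

Timestamps are local wall-clock with no time-zone arithmetic; calendar days
run from local midnight, matching diary-based wear protocols.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "DiaryLog",
    "SubjectRecord",
    "read_epoch_csv",
    "write_epoch_csv",
    "aggregate_epochs",
    "read_diary_csv",
    "write_diary_csv",
    "read_clinical_table",
    "write_clinical_table",
]

PLACEMENTS = ("waist", "wrist")
VISITS = ("baseline", "followup")
GROUPS = ("FRDA", "CTR")

_HEADER_RULE = "-" * 50


def _as_count_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(np.asarray(arr, dtype=float))
        if not np.allclose(arr, rounded, atol=1e-9, equal_nan=False):
            raise ValueError(f"{name} contains non-integer counts")
        arr = rounded
    arr = arr.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise ValueError(f"{name} contains negative counts")
    return arr


@dataclass
class EpochSeries:
    """One subject x placement x visit series of fixed-length count epochs.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    placement : {"waist", "wrist"}
        Body site of the sensor.
    visit : {"baseline", "followup"}
        Study visit label.
    start_time : pandas.Timestamp
        Wall-clock time of the first epoch.
    axis1, axis2, axis3 : ndarray of int
        Per-epoch activity counts; ``axis1`` is the vertical axis.
    steps : ndarray of int
        Device-estimated steps per epoch.
    epoch_length : int
        Epoch duration in seconds (default 60).  Must divide 60 or be a
        multiple of 60.
    wear : ndarray of bool, optional
        Per-epoch wear flag; absent until non-wear detection has run.
    """

    subject_id: str
    placement: str
    visit: str
    start_time: pd.Timestamp
    axis1: np.ndarray
    axis2: np.ndarray
    axis3: np.ndarray
    steps: np.ndarray
    epoch_length: int = 60
    wear: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit {self.visit!r}")
        self.start_time = pd.Timestamp(self.start_time)
        ep = int(self.epoch_length)
        if ep <= 0 or (60 % ep != 0 and ep % 60 != 0):
            raise ValueError("epoch_length must divide 60 s or be a multiple of 60 s")
        self.epoch_length = ep
        self.axis1 = _as_count_array(self.axis1, "axis1")
        self.axis2 = _as_count_array(self.axis2, "axis2")
        self.axis3 = _as_count_array(self.axis3, "axis3")
        self.steps = _as_count_array(self.steps, "steps")
        n = self.axis1.size
        for name in ("axis2", "axis3", "steps"):
            if getattr(self, name).size != n:
                raise ValueError("count arrays must have equal length")
        if self.wear is not None:
            self.wear = np.asarray(self.wear, dtype=bool)
            if self.wear.size != n:
                raise ValueError("wear flags must match series length")

    def __len__(self) -> int:
        return int(self.axis1.size)

    @property
    def n_epochs(self) -> int:
        return len(self)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(seconds=self.epoch_length)
        )

    @property
    def dates(self) -> np.ndarray:
        """Calendar date (from local midnight) of each epoch."""
        return self.timestamps.normalize().values

    def vector_magnitude(self) -> np.ndarray:
        """Per-epoch Euclidean norm of the three axis counts."""
        return np.sqrt(
            self.axis1.astype(float) ** 2
            + self.axis2.astype(float) ** 2
            + self.axis3.astype(float) ** 2
        )

    def with_wear(self, wear: np.ndarray) -> "EpochSeries":
        return replace(self, wear=np.asarray(wear, dtype=bool))

    def __eq__(self, other) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, EpochSeries):
            return NotImplemented
        same_wear = (
            (self.wear is None and other.wear is None)
            or (
                self.wear is not None
                and other.wear is not None
                and np.array_equal(self.wear, other.wear)
            )
        )
        return (
            self.subject_id == other.subject_id
            and self.placement == other.placement
            and self.visit == other.visit
            and self.start_time == other.start_time
            and self.epoch_length == other.epoch_length
            and np.array_equal(self.axis1, other.axis1)
            and np.array_equal(self.axis2, other.axis2)
            and np.array_equal(self.axis3, other.axis3)
            and np.array_equal(self.steps, other.steps)
            and same_wear
        )


@dataclass
class DiaryLog:
    """Self-reported worn intervals for one subject.

    ``intervals`` are half-open ``[on, off)`` timestamp pairs; free-text
    activity notes from the paper diary are not represented because they do
    not enter any computation.
    """

    subject_id: str
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted(
            (pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.intervals
        )
        for (a, b) in iv:
            if b <= a:
                raise ValueError(f"empty or inverted diary interval {a} .. {b}")
        for (_, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("diary intervals overlap")
        self.intervals = iv

    def worn_mask(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        mask = np.zeros(len(timestamps), dtype=bool)
        for on, off in self.intervals:
            mask |= (timestamps >= on) & (timestamps < off)
        return mask


@dataclass
class SubjectRecord:
    """Identity, group and clinical scores for one subject at one visit.

    Missing values (e.g. an 8-m walk test the subject could not complete,
    or GAA sizes for controls) are carried as ``nan``, never imputed.
    """

    subject_id: str
    visit: str
    group: str
    sex: str
    age: float
    bmi: float
    sara: float
    sara_gait: float
    mfars: float
    fars_e: float
    adl: float
    ccfs: float
    t8mwt: float = np.nan
    gaa1: float = np.nan
    gaa2: float = np.nan
    age_at_onset: float = np.nan
    disease_duration: float = np.nan

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit {self.visit!r}")


# ---------------------------------------------------------------------------
# Epoch CSV I/O
# ---------------------------------------------------------------------------

def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write an epoch series as a metadata-header CSV readable by
    :func:`read_epoch_csv`."""
    path = Path(path)
    start = series.start_time
    lines = [
        _HEADER_RULE,
        f"Subject: {series.subject_id}",
        f"Placement: {series.placement}",
        f"Visit: {series.visit}",
        f"Start Date: {start.strftime('%Y-%m-%d')}",
        f"Start Time: {start.strftime('%H:%M:%S')}",
        f"Epoch Length (s): {series.epoch_length}",
        _HEADER_RULE,
        "Date,Time,Axis1,Axis2,Axis3,Steps",
    ]
    ts = series.timestamps
    rows = [
        f"{t.strftime('%Y-%m-%d')},{t.strftime('%H:%M:%S')},{a1},{a2},{a3},{s}"
        for t, a1, a2, a3, s in zip(ts, series.axis1, series.axis2, series.axis3, series.steps)
    ]
    path.write_text("\n".join(lines + rows) + "\n", encoding="utf-8")


def _parse_header(lines: list[str], path) -> tuple[dict, int]:
    if not lines or not lines[0].startswith("---"):
        raise ValueError(f"{path}: line 1: expected metadata header rule")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("---"):
            return meta, i + 1
        if ":" not in line:
            raise ValueError(f"{path}: line {i + 1}: malformed header line {line!r}")
        key, _, value = line.partition(":")
        meta[key.strip()] = value.strip()
        i += 1
    raise ValueError(f"{path}: unterminated metadata header")


def read_epoch_csv(
    path,
    dialect: str = "acticohort",
    *,
    subject_id: str | None = None,
    placement: str | None = None,
    visit: str | None = None,
    pad_gaps: bool = False,
) -> EpochSeries:
    """Read an epoch-count CSV export.

    The file must start with a ``Key: value`` metadata block between two
    dashed rule lines, followed by a column header.  ``Date``/``Time``
    columns are optional; when absent, timestamps are reconstructed from the
    header start time.  With ``pad_gaps=True`` missing epochs inside the
    recording span are re-indexed and filled with zero counts; otherwise a
    non-contiguous file is an error.
    """
    if dialect != "acticohort":
        raise ValueError(f"unsupported epoch CSV dialect {dialect!r}")
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, body_start = _parse_header(lines, path)

    sid = subject_id or meta.get("Subject")
    plc = placement or meta.get("Placement")
    vis = visit or meta.get("Visit", "baseline")
    if sid is None or plc is None:
        raise ValueError(f"{path}: subject/placement neither in header nor arguments")
    try:
        start = pd.Timestamp(f"{meta['Start Date']} {meta['Start Time']}")
        epoch_length = int(meta.get("Epoch Length (s)", "60"))
    except KeyError as exc:
        raise ValueError(f"{path}: header missing {exc}") from exc

    if body_start >= len(lines):
        raise ValueError(f"{path}: missing column header line")
    columns = [c.strip() for c in lines[body_start].split(",")]
    data_lines = [ln for ln in lines[body_start + 1 :] if ln.strip()]
    if data_lines:
        from io import StringIO

        df = pd.read_csv(StringIO("\n".join(data_lines)), names=columns)
    else:
        df = pd.DataFrame(columns=columns)

    for col in ("Axis1", "Axis2", "Axis3", "Steps"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")

    if "Date" in df.columns and "Time" in df.columns and len(df):
        ts = pd.to_datetime(df["Date"].astype(str) + " " + df["Time"].astype(str))
        start = ts.iloc[0]
        deltas = (ts - start).dt.total_seconds().to_numpy()
        expected = np.arange(len(df)) * epoch_length
        if not np.array_equal(deltas, expected):
            if not pad_gaps:
                raise ValueError(f"{path}: epochs are not contiguous (pass pad_gaps=True to re-index)")
            if np.any(np.diff(deltas) <= 0) or np.any(np.mod(deltas, epoch_length)):
                raise ValueError(f"{path}: timestamps not aligned to the epoch grid")
            idx = (deltas // epoch_length).astype(int)
            full = np.zeros((int(idx[-1]) + 1, 4), dtype=np.int64)
            full[idx] = df[["Axis1", "Axis2", "Axis3", "Steps"]].to_numpy(dtype=np.int64)
            df = pd.DataFrame(full, columns=["Axis1", "Axis2", "Axis3", "Steps"])

    return EpochSeries(
        subject_id=sid,
        placement=plc,
        visit=vis,
        start_time=start,
        axis1=df["Axis1"].to_numpy(),
        axis2=df["Axis2"].to_numpy(),
        axis3=df["Axis3"].to_numpy(),
        steps=df["Steps"].to_numpy(),
        epoch_length=epoch_length,
    )


def aggregate_epochs(series: EpochSeries, target_epoch_length: int) -> EpochSeries:
    """Sum counts and steps into longer epochs (e.g. 1 s -> 60 s).

    ``target_epoch_length`` must be an integer multiple of the source epoch
    length and must tile the series exactly.  Totals are conserved exactly.
    """
    target = int(target_epoch_length)
    if target % series.epoch_length != 0:
        raise ValueError(
            f"target epoch {target}s is not a multiple of source epoch {series.epoch_length}s"
        )
    factor = target // series.epoch_length
    if factor == 1:
        return replace(series, wear=None)
    n = len(series)
    if n % factor != 0:
        raise ValueError(f"series length {n} is not divisible by aggregation factor {factor}")

    def _sum(a: np.ndarray) -> np.ndarray:
        return a.reshape(-1, factor).sum(axis=1)

    return EpochSeries(
        subject_id=series.subject_id,
        placement=series.placement,
        visit=series.visit,
        start_time=series.start_time,
        axis1=_sum(series.axis1),
        axis2=_sum(series.axis2),
        axis3=_sum(series.axis3),
        steps=_sum(series.steps),
        epoch_length=target,
    )


# ---------------------------------------------------------------------------
# Diary and clinical tables
# ---------------------------------------------------------------------------

_DIARY_COLUMNS = ["subject_id", "date", "on_time", "off_time"]


def write_diary_csv(diaries: list[DiaryLog], path) -> None:
    rows = []
    for d in diaries:
        for on, off in d.intervals:
            rows.append(
                {
                    "subject_id": d.subject_id,
                    "date": on.strftime("%Y-%m-%d"),
                    "on_time": on.strftime("%H:%M:%S"),
                    "off_time": off.strftime("%H:%M:%S") if off.date() == on.date() else "24:00:00",
                }
            )
    pd.DataFrame(rows, columns=_DIARY_COLUMNS).to_csv(path, index=False)


def read_diary_csv(path) -> dict[str, DiaryLog]:
    """Read a wear diary CSV (subject_id, date, on_time, off_time) into
    per-subject :class:`DiaryLog` objects.  ``off_time`` of ``24:00:00``
    denotes end of day."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"diary CSV missing columns: {missing}")
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        day = pd.Timestamp(row["date"])
        on = day + pd.Timedelta(row["on_time"])
        if row["off_time"].startswith("24:"):
            off = day + pd.Timedelta(days=1)
        else:
            off = day + pd.Timedelta(row["off_time"])
        out.setdefault(str(row["subject_id"]), []).append((on, off))
    return {sid: DiaryLog(sid, iv) for sid, iv in out.items()}


_CLINICAL_COLUMNS = [
    "subject_id", "visit", "group", "sex", "age", "bmi",
    "sara", "sara_gait", "mfars", "fars_e", "adl", "ccfs", "t8mwt",
    "gaa1", "gaa2", "age_at_onset", "disease_duration",
]


def write_clinical_table(records: list[SubjectRecord], path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _CLINICAL_COLUMNS} for r in records])
    df.to_csv(path, index=False)


def read_clinical_table(path) -> list[SubjectRecord]:
    """Read a clinical CSV (one row per subject x visit) into typed records.

    Raises on unknown group labels and duplicated subject x visit rows;
    missing score cells stay ``nan``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV missing columns: {missing}")
    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        bad = df.loc[dup, ["subject_id", "visit"]].iloc[0]
        raise ValueError(f"duplicated subject x visit row: {tuple(bad)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _CLINICAL_COLUMNS}
        kwargs["subject_id"] = str(kwargs["subject_id"])
        kwargs["sex"] = str(kwargs["sex"])
        records.append(SubjectRecord(**kwargs))
    return records
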