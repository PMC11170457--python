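"""Minute-epoch actigraphy I/O, noon-to-noon day segmentation, inclusion filters.

The on-disk dialect is a long CSV with columns ``subject,timestamp,count``
and an optional ``wear`` column (0/1).  Timestamps are naive local time at
one-minute resolution.  Days run noon-to-noon so that a night's sleep is
never split across two analysis days; a day is *valid* when it is fully
covered by the recording and has strictly more than 16 hours (960 minutes)
of wear.  Subjects enter the analysis with at least ``min_valid_days``
(default 7) valid days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
#: wear minutes must strictly exceed this for a valid day (16 h)
WEAR_VALID_MIN = 960


@dataclass
class EpochSeries:
    """A contiguous minute-level count/wear stream for one subject."""

    subject_id: str
    start: pd.Timestamp
    counts: np.ndarray
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.counts.shape != self.wear.shape or self.counts.ndim != 1:
            raise ValueError("counts and wear must be 1-D arrays of equal length")
        if np.any(self.counts < 0):
            raise ValueError(f"negative count in series for subject {self.subject_id}")
        self.start = pd.Timestamp(self.start).floor("min")

    @property
    def n_minutes(self) -> int:
        return self.counts.size

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_minutes, freq="min")

    def clock_hours(self) -> np.ndarray:
        """Clock time in hours [0, 24) of every epoch."""
        start_min = self.start.hour * 60 + self.start.minute
        return ((start_min + np.arange(self.n_minutes)) % MINUTES_PER_DAY) / 60.0


@dataclass
class DayWindow:
    """One noon-to-noon 1440-minute window of a subject's series."""

    subject_id: str
    day_index: int
    window_start: pd.Timestamp
    start_idx: int  # slice bounds into the EpochSeries (clipped to extent)
    stop_idx: int
    wear_minutes: int
    complete: bool  # fully covered by the recording
    valid: bool  # complete and wear_minutes > 960


def read_epochs(path) -> list[EpochSeries]:
    """Read an epoch CSV into one :class:`EpochSeries` per subject.

    Interior gaps in a subject's minute grid are filled with ``count=0,
    wear=False``.  A missing ``wear`` column is inferred from count
    missingness.  Unparseable timestamps, negative counts and duplicated
    minutes are rejected with the offending row number (1-based, counting
    the header).
    """
    df = pd.read_csv(path)
    required = {"subject", "timestamp", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"epoch CSV must have columns {sorted(required)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = np.flatnonzero(ts.isna() & df["timestamp"].notna())
    if bad.size:
        raise ValueError(f"unparseable timestamp at row {bad[0] + 2}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    neg = np.flatnonzero(counts < 0)
    if neg.size:
        raise ValueError(f"negative count at row {neg[0] + 2}")
    if "wear" in df.columns:
        wear = df["wear"].fillna(0).astype(float) > 0
    else:
        wear = counts.notna()
    df = pd.DataFrame(
        {"subject": df["subject"].astype(str), "ts": ts.dt.floor("min"),
         "count": counts.fillna(0.0), "wear": wear, "row": np.arange(len(df)) + 2}
    )
    out: list[EpochSeries] = []
    for sid, g in df.groupby("subject", sort=True):
        g = g.sort_values("ts", kind="stable")
        dup = g["ts"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicated minute for subject {sid} at row {int(g['row'][dup].iloc[0])}"
            )
        start, end = g["ts"].iloc[0], g["ts"].iloc[-1]
        n = int((end - start).total_seconds() // 60) + 1
        counts_full = np.zeros(n)
        wear_full = np.zeros(n, dtype=bool)
        idx = ((g["ts"] - start).dt.total_seconds() // 60).astype(int).to_numpy()
        counts_full[idx] = g["count"].to_numpy()
        wear_full[idx] = g["wear"].to_numpy()
        out.append(EpochSeries(sid, start, counts_full, wear_full))
    return out


def write_epochs(series: list[EpochSeries], path) -> None:
    """Write series back to the epoch CSV dialect (inverse of read_epochs)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {"subject": s.subject_id,
                 "timestamp": s.timestamps().strftime("%Y-%m-%dT%H:%M"),
                 "count": s.counts, "wear": s.wear.astype(int)}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read the subject covariate table.

    Columns: ``subject,age,sex,bmi,group,anxiety,sud[,medication]`` with
    ``sex`` in {female, male} and ``group`` in {none, current, remitted}.
    """
    df = pd.read_csv(path)
    required = {"subject", "age", "sex", "bmi", "group", "anxiety", "sud"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate CSV missing columns {sorted(missing)}")
    df = df.copy()
    df["subject"] = df["subject"].astype(str)
    if df["subject"].duplicated().any():
        raise ValueError("covariate CSV has duplicated subjects")
    bad_sex = set(df["sex"].unique()) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"unknown sex values {sorted(bad_sex)}")
    bad_grp = set(df["group"].unique()) - {"none", "current", "remitted"}
    if bad_grp:
        raise ValueError(f"unknown group values {sorted(bad_grp)}")
    for col in ("anxiety", "sud", "medication"):
        if col in df.columns:
            df[col] = df[col].astype(float) > 0
    return df.set_index("subject")


def _first_noon_at_or_before(ts: pd.Timestamp) -> pd.Timestamp:
    noon = ts.normalize() + pd.Timedelta(hours=12)
    return noon if noon <= ts else noon - pd.Timedelta(days=1)


def segment_days(series: EpochSeries) -> list[DayWindow]:
    """Partition a series into noon-to-noon :class:`DayWindow` objects.

    Windows tile the series without overlap; leading/trailing windows that
    are not fully covered by the recording are marked incomplete (hence
    invalid) but still own their minutes.
    """
    if series.n_minutes == 0:
        raise ValueError("empty series")
    first_noon = _first_noon_at_or_before(series.start)
    off0 = int((series.start - first_noon).total_seconds() // 60)
    n = series.n_minutes
    n_windows = int(np.ceil((off0 + n) / MINUTES_PER_DAY))
    windows = []
    for i in range(n_windows):
        lo = i * MINUTES_PER_DAY - off0
        hi = lo + MINUTES_PER_DAY
        start_idx, stop_idx = max(lo, 0), min(hi, n)
        complete = lo >= 0 and hi <= n
        wear_minutes = int(series.wear[start_idx:stop_idx].sum())
        windows.append(
            DayWindow(
                subject_id=series.subject_id,
                day_index=i,
                window_start=first_noon + pd.Timedelta(days=i),
                start_idx=start_idx,
                stop_idx=stop_idx,
                wear_minutes=wear_minutes,
                complete=complete,
                valid=complete and wear_minutes > WEAR_VALID_MIN,
            )
        )
    return windows


def day_grid(series: EpochSeries, window: DayWindow) -> tuple[np.ndarray, np.ndarray]:
    """Counts and wear of a window on a fixed 1440-minute noon-to-noon grid.

    Minutes outside the recording are padded with ``count=0, wear=False``.
    """
    counts = np.zeros(MINUTES_PER_DAY)
    wear = np.zeros(MINUTES_PER_DAY, dtype=bool)
    pad = int((series.start + pd.Timedelta(minutes=window.start_idx)
               - window.window_start).total_seconds() // 60)
    m = window.stop_idx - window.start_idx
    counts[pad:pad + m] = series.counts[window.start_idx:window.stop_idx]
    wear[pad:pad + m] = series.wear[window.start_idx:window.stop_idx]
    return counts, wear


def apply_inclusion(
    windows_by_subject: dict[str, list[DayWindow]], min_valid_days: int = 7
) -> tuple[list[str], dict[str, int]]:
    """Drop subjects with fewer than ``min_valid_days`` valid days.

    Returns the included subject ids (input order) and per-subject valid-day
    counts for every subject.  Raises if nobody survives the filter.
    """
    counts = {
        sid: sum(w.valid for w in ws) for sid, ws in windows_by_subject.items()
    }
    included = [sid for sid, c in counts.items() if c >= min_valid_days]
    if not included:
        raise ValueError(
            f"no subject has >= {min_valid_days} valid days; cohort is empty"
        )
    return included, counts
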