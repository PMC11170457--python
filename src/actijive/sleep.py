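"""Nightly sleep-period detection and sleep-domain features.

The seven sleep features are per-subject averages over valid nights of:
onset, wakeup and midpoint clock hours, sleep duration (hours actually
asleep), efficiency (sleep time / sleep-period time), NWB (number of wake
bouts of at least 5 minutes inside the sleep period) and NSB (number of
maximal blocks of sleep minutes inside the period).

Detection is a count-based heuristic on the noon-to-noon day grid: counts
are median-smoothed, thresholded into rest/active, rest-dominated stretches
are located with a wide majority filter, and the sleep period is the longest
such stretch (at least ``min_period`` minutes), trimmed to its first and
last below-threshold minute.  Within the period the minute-level sleep flag
is simply ``count < theta_sleep``.  Precomputed per-night annotations (e.g.
GGIR summary output) can be ingested instead of running detection.

All onset/wakeup arithmetic uses a continuous noon-to-noon axis (12-36 h)
so post-midnight onsets average correctly; reported values are mod 24.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d


@dataclass
class SleepRecord:
    """One night's sleep period on the 12-36 h noon-to-noon axis."""

    subject_id: str
    day_index: int
    onset: float  # hours, 12 <= onset < wakeup <= 36
    wakeup: float
    sleep_flags: np.ndarray | None = None  # per-minute within [onset, wakeup)
    efficiency_hint: float | None = None  # used when flags are unavailable

    def __post_init__(self) -> None:
        if not (12.0 <= self.onset < self.wakeup <= 36.0):
            raise ValueError(
                f"sleep period [{self.onset}, {self.wakeup}] outside the 12-36 h axis"
            )
        if self.sleep_flags is not None:
            self.sleep_flags = np.asarray(self.sleep_flags, dtype=bool)
            expect = int(round((self.wakeup - self.onset) * 60))
            if self.sleep_flags.size != expect:
                raise ValueError("sleep_flags length does not match the period")


@dataclass
class SleepFeatures:
    """Per-subject sleep features averaged across valid nights."""

    subject_id: str
    onset: float  # reported mod 24
    wakeup: float
    midpoint: float
    duration: float
    efficiency: float
    nwb: float
    nsb: float
    n_nights: int

    def as_dict(self) -> dict[str, float]:
        return {
            "Onset": self.onset, "Wakeup": self.wakeup, "Duration": self.duration,
            "Midpoint": self.midpoint, "Efficiency": self.efficiency,
            "NWB": self.nwb, "NSB": self.nsb,
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of maximal True runs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_sleep_period(
    counts: np.ndarray,
    wear: np.ndarray | None = None,
    *,
    theta_sleep: float = 10.0,
    smooth_width: int = 11,
    block_width: int = 61,
    min_period: int = 180,
    subject_id: str = "",
    day_index: int = 0,
) -> SleepRecord | None:
    """Detect the main sleep period on one noon-to-noon 1440-minute grid.

    Returns ``None`` (night missing) when no rest-dominated block of at
    least ``min_period`` minutes exists.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 1440:
        raise ValueError("need a full 1440-minute day grid")
    if theta_sleep <= 0:
        raise ValueError("theta_sleep must be positive")
    wear = np.ones_like(counts, bool) if wear is None else np.asarray(wear, bool)
    smoothed = median_filter(counts, size=smooth_width, mode="nearest")
    rest = (smoothed < theta_sleep) & wear
    frac = uniform_filter1d(rest.astype(float), size=block_width, mode="nearest")
    block = frac > 0.5
    candidates = [r for r in _runs(block) if r[1] - r[0] >= min_period]
    if not candidates:
        return None
    lo, hi = max(candidates, key=lambda r: r[1] - r[0])
    inside = np.flatnonzero(rest[lo:hi]) + lo
    if inside.size == 0:
        return None
    onset_idx, wake_idx = int(inside[0]), int(inside[-1]) + 1
    if wake_idx - onset_idx < min_period:
        return None
    flags = (counts[onset_idx:wake_idx] < theta_sleep) & wear[onset_idx:wake_idx]
    return SleepRecord(
        subject_id=subject_id,
        day_index=day_index,
        onset=12.0 + onset_idx / 60.0,
        wakeup=12.0 + wake_idx / 60.0,
        sleep_flags=flags,
    )


def night_summary(
    rec: SleepRecord, *, wake_bout_min: int = 5, nsb_any_wake: bool = True
) -> dict[str, float]:
    """Single-night features from one :class:`SleepRecord`.

    ``nsb_any_wake`` counts a new sleep block after any wake minute; the
    alternative only splits blocks at wake runs of at least
    ``wake_bout_min`` minutes.
    """
    period = rec.wakeup - rec.onset
    if period <= 0:
        raise ValueError("zero-length sleep period")
    if rec.sleep_flags is None:
        eff = 1.0 if rec.efficiency_hint is None else float(rec.efficiency_hint)
        duration = eff * period
        nwb = nsb = np.nan
    else:
        flags = rec.sleep_flags
        sleep_min = int(flags.sum())
        if sleep_min == 0:
            raise ValueError("sleep period contains no sleep minutes")
        duration = sleep_min / 60.0
        eff = sleep_min / flags.size  # minute ratio: exact in [0, 1]
        wake_runs = _runs(~flags)
        nwb = sum(1 for s, e in wake_runs if e - s >= wake_bout_min)
        if nsb_any_wake:
            nsb = len(_runs(flags))
        else:
            long_wake = [(s, e) for s, e in wake_runs if e - s >= wake_bout_min]
            nsb = len(long_wake) + 1
    return {
        "onset": rec.onset,
        "wakeup": rec.wakeup,
        "midpoint": rec.onset + period / 2.0,
        "duration": duration,
        "efficiency": eff,
        "nwb": float(nwb),
        "nsb": float(nsb),
    }


def sleep_summary(
    records: list[SleepRecord | None],
    *,
    subject_id: str | None = None,
    wake_bout_min: int = 5,
    nsb_any_wake: bool = True,
) -> SleepFeatures:
    """Average per-night features across non-missing nights of one subject."""
    nights = [r for r in records if r is not None]
    if not nights:
        raise ValueError("no non-missing nights")
    rows = [night_summary(r, wake_bout_min=wake_bout_min, nsb_any_wake=nsb_any_wake)
            for r in nights]
    df = pd.DataFrame(rows)
    mean = df.mean()  # axis values averaged before wrapping
    return SleepFeatures(
        subject_id=subject_id if subject_id is not None else nights[0].subject_id,
        onset=float(mean["onset"] % 24.0),
        wakeup=float(mean["wakeup"] % 24.0),
        midpoint=float(mean["midpoint"] % 24.0),
        duration=float(mean["duration"]),
        efficiency=float(mean["efficiency"]),
        nwb=float(df["nwb"].mean()),
        nsb=float(df["nsb"].mean()),
        n_nights=len(nights),
    )


def _hhmm_to_axis(value: str) -> float:
    hh, mm = str(value).split(":")
    h = int(hh) + int(mm) / 60.0
    return h + 24.0 if h < 12.0 else h


def read_sleep_annotations(path) -> pd.DataFrame:
    """Read a per-night annotation CSV: ``subject,date,onset_hhmm,wakeup_hhmm[,efficiency]``."""
    df = pd.read_csv(path)
    required = {"subject", "date", "onset_hhmm", "wakeup_hhmm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    df = df.copy()
    df["subject"] = df["subject"].astype(str)
    return df


def records_from_annotations(
    annotations: pd.DataFrame, subject_id: str
) -> list[SleepRecord]:
    """Build :class:`SleepRecord` objects (without flags) from annotations."""
    sub = annotations[annotations["subject"] == subject_id]
    records = []
    for day_index, (_, row) in enumerate(sub.iterrows()):
        onset = _hhmm_to_axis(row["onset_hhmm"])
        wakeup = _hhmm_to_axis(row["wakeup_hhmm"])
        if wakeup <= onset:
            wakeup += 24.0
        eff = float(row["efficiency"]) if "efficiency" in row and pd.notna(
            row.get("efficiency")) else None
        records.append(
            SleepRecord(subject_id, day_index, onset, min(wakeup, 36.0),
                        sleep_flags=None, efficiency_hint=eff)
        )
    return records
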