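"""Feature assembly: per-subject extraction of the SL / PA / CR blocks.

Turns a collection of minute-epoch series into the subjects x 28 feature
table with named blocks: 7 sleep (SL), 7 physical-activity (PA) and 14
circadian-rhythm (CR) features, each averaged over valid noon-to-noon days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activity, circadian, epoch, sleep

SL_FEATURES = ["Onset", "Wakeup", "Duration", "Midpoint", "Efficiency", "NWB", "NSB"]
PA_FEATURES = ["TAC", "TLAC", "TST", "LiPA", "MVPA", "SATP", "ASTP"]
CR_FEATURES = ["fPC1", "fPC2", "fPC3", "fPC4", "RA", "IV", "IS",
               "Mesor", "Amp", "Acro", "L5", "M10", "L5Time", "M10Time"]
BLOCKS = {"SL": SL_FEATURES, "PA": PA_FEATURES, "CR": CR_FEATURES}
ALL_FEATURES = SL_FEATURES + PA_FEATURES + CR_FEATURES


@dataclass
class FeatureConfig:
    """Tunable parameters of the extraction pipeline."""

    min_valid_days: int = 7
    theta_sleep: float = 10.0  # counts/min below which a minute can be sleep
    smooth_width: int = 11  # running-median width for rest detection (min)
    block_width: int = 61  # majority-filter width for rest-dominated blocks
    min_period: int = 180  # minimum sleep-period length (min)
    wake_bout_min: int = 5
    nsb_any_wake: bool = True
    theta_sed: float = 50.0  # counts/min sedentary/light boundary
    theta_mvpa: float = 1000.0  # counts/min light/MVPA boundary
    fragmentation_wake_only: bool = False  # restrict SATP/ASTP to wake time
    min_worn_per_hour: int = 30  # hourly bin retained when this many minutes worn
    fpca_k: int = 4
    fpca_smooth: int = 21


@dataclass
class FeatureBlocks:
    """Subjects x features matrix partitioned into named blocks."""

    data: pd.DataFrame
    blocks: dict[str, list[str]] = field(default_factory=lambda: dict(BLOCKS))

    def matrix(self, name: str) -> pd.DataFrame:
        return self.data[self.blocks[name]]

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)


def _subject_sleep(series, windows, cfg, annotations):
    if annotations is not None:
        recs = sleep.records_from_annotations(annotations, series.subject_id)
    else:
        recs = []
        for w in windows:
            counts, wear = epoch.day_grid(series, w)
            recs.append(
                sleep.detect_sleep_period(
                    counts, wear, theta_sleep=cfg.theta_sleep,
                    smooth_width=cfg.smooth_width, block_width=cfg.block_width,
                    min_period=cfg.min_period, subject_id=series.subject_id,
                    day_index=w.day_index)
            )
    recs_by_day = {r.day_index: r for r in recs if r is not None}
    try:
        feats = sleep.sleep_summary(
            list(recs_by_day.values()), subject_id=series.subject_id,
            wake_bout_min=cfg.wake_bout_min, nsb_any_wake=cfg.nsb_any_wake
        ).as_dict()
    except ValueError:
        feats = {k: np.nan for k in SL_FEATURES}
    return feats, recs_by_day


def _wake_mask_for_window(rec) -> np.ndarray:
    """1440-minute mask of minutes outside the night's sleep period."""
    mask = np.ones(1440, dtype=bool)
    if rec is not None:
        lo = int(round((rec.onset - 12.0) * 60))
        hi = int(round((rec.wakeup - 12.0) * 60))
        mask[lo:hi] = False
    return mask


def _subject_pa(series, windows, cfg, sleep_records):
    rows = []
    for w in windows:
        counts, wear = epoch.day_grid(series, w)
        include = None
        if cfg.fragmentation_wake_only:
            include = _wake_mask_for_window(sleep_records.get(w.day_index))
        rows.append(activity.pa_day_features(
            counts, wear, theta_sed=cfg.theta_sed, theta_mvpa=cfg.theta_mvpa,
            frag_include=include))
    df = pd.DataFrame(rows)
    return {k: float(df[k].mean(skipna=True)) for k in PA_FEATURES}


def _subject_cr_parts(series, windows, cfg):
    """Cosinor, IV/IS and diurnal profiles (count & log scale) for a subject."""
    start_min = series.start.hour * 60 + series.start.minute
    idx = np.concatenate([np.arange(w.start_idx, w.stop_idx) for w in windows])
    wear = series.wear[idx]
    counts = series.counts[idx]
    global_min = start_min + idx  # minutes since midnight of the start day
    worn_counts = counts[wear]
    worn_t = (global_min[wear] % 1440) / 60.0
    if worn_counts.size >= 1440:
        mesor, amp, acro = circadian.cosinor_fit(worn_t, worn_counts)
    else:
        mesor = amp = acro = np.nan
    # hourly bins for IV/IS
    hour_id = global_min // 60
    sums = np.bincount(hour_id[wear], weights=worn_counts)
    nmin = np.bincount(hour_id[wear])
    keep = np.flatnonzero(nmin >= cfg.min_worn_per_hour)
    hourly = sums[keep] / nmin[keep]
    clock_hour = keep % 24
    if hourly.size >= 48:
        iv, is_ = circadian.iv_is(hourly, clock_hour)
    else:
        iv = is_ = np.nan
    # diurnal profiles per clock minute
    clock_min = global_min % 1440
    cm = clock_min[wear]
    csum = np.bincount(cm, weights=worn_counts, minlength=1440)
    lsum = np.bincount(cm, weights=np.log1p(worn_counts), minlength=1440)
    cn = np.bincount(cm, minlength=1440)
    with np.errstate(invalid="ignore"):
        count_prof = np.where(cn > 0, csum / np.maximum(cn, 1), np.nan)
        log_prof = np.where(cn > 0, lsum / np.maximum(cn, 1), np.nan)
    for prof in (count_prof, log_prof):
        missing = np.isnan(prof)
        if missing.any():
            prof[missing] = np.nanmean(prof) if not missing.all() else 0.0
    return {"Mesor": mesor, "Amp": amp, "Acro": acro, "IV": iv, "IS": is_}, \
        count_prof, log_prof


def extract_features(
    series_list: list[epoch.EpochSeries],
    config: FeatureConfig | None = None,
    *,
    sleep_annotations: pd.DataFrame | None = None,
) -> tuple[FeatureBlocks, dict]:
    """Full feature extraction: segmentation, inclusion, SL/PA/CR features.

    Returns the :class:`FeatureBlocks` table (included subjects only) and a
    metadata dict with per-subject valid-day counts, exclusions, and the
    fPCA component curves / variance shares.
    """
    cfg = config or FeatureConfig()
    windows_by_subject = {s.subject_id: epoch.segment_days(s) for s in series_list}
    included, day_counts = epoch.apply_inclusion(
        {sid: [w for w in ws] for sid, ws in windows_by_subject.items()},
        min_valid_days=cfg.min_valid_days,
    )
    series_by_id = {s.subject_id: s for s in series_list}
    rows, log_profiles, count_profiles = {}, [], []
    for sid in included:
        series = series_by_id[sid]
        valid = [w for w in windows_by_subject[sid] if w.valid]
        sl, sleep_records = _subject_sleep(series, valid, cfg, sleep_annotations)
        pa = _subject_pa(series, valid, cfg, sleep_records)
        cr, count_prof, log_prof = _subject_cr_parts(series, valid, cfg)
        cr.update(circadian.l5_m10(count_prof))
        rows[sid] = {**sl, **pa, **cr}
        log_profiles.append(log_prof)
        count_profiles.append(count_prof)
    df = pd.DataFrame.from_dict(rows, orient="index")
    scores, comps, shares = circadian.diurnal_fpca(
        np.vstack(log_profiles), k=cfg.fpca_k, smooth_width=cfg.fpca_smooth)
    for j in range(cfg.fpca_k):
        df[f"fPC{j + 1}"] = scores[:, j]
    df = df[ALL_FEATURES]
    df.index.name = "subject"
    meta = {
        "n_valid_days": {sid: day_counts[sid] for sid in included},
        "excluded": sorted(set(day_counts) - set(included)),
        "fpca_components": comps,
        "fpca_shares": shares,
    }
    return FeatureBlocks(df), meta


def write_features(blocks: FeatureBlocks, path, *, centered_times: bool = True) -> None:
    """Write the feature table as CSV; optionally append cohort-centered
    L5Time/M10Time columns (hours minus cohort mean)."""
    df = blocks.data.copy()
    if centered_times:
        for col in ("L5Time", "M10Time"):
            df[f"{col}_centered"] = df[col] - df[col].mean()
    df.to_csv(path)
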